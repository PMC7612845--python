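"""Medullary/extramedullary identity scoring and classification.

Two reference HSC/MPP poles (medullary = bone-marrow-type, extramedullary
= spleen-type) are compared by Wilcoxon rank-sum differential expression;
the top differentially expressed genes per direction form a paired identity
signature.  Each cell is then scored for both halves, the scores are
converted to fractional ranks within the scored cohort, and their ratio
R = rank(medullary score) / rank(extramedullary score) classifies cells and
samples: median R above 1 indicates medullary identity, below 1
extramedullary.

Fractional ranks (rather than the raw score ratio) make R strictly
positive and scale-free, and give the threshold at exactly 1 the meaning
"equal standing of the two scores within the cohort".  The raw-score
ratio, shifted to be positive, is available behind ``method='raw'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import ValidationError, derive_seed, logger
from .io import GeneSetCollection, NormalizedMatrix
from .signatures import score_signature

__all__ = [
    "IdentitySignature",
    "IdentityResult",
    "wilcoxon_de",
    "derive_identity_signature",
    "compute_identity_ratio",
    "classify_identity",
]


@dataclass
class IdentitySignature:
    """Paired medullary/extramedullary gene lists with their derivation
    parameters."""

    med_genes: list[str]
    extramed_genes: list[str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.med_genes or not self.extramed_genes:
            raise ValidationError("both signature halves must be nonempty")
        if set(self.med_genes) & set(self.extramed_genes):
            raise ValidationError("med and extramed gene lists must be disjoint")

    def to_collection(self) -> GeneSetCollection:
        return GeneSetCollection(
            sets={"MED": list(self.med_genes), "EXTRAMED": list(self.extramed_genes)},
            descriptions={"MED": "medullary (BM-type) identity genes",
                          "EXTRAMED": "extramedullary (SPL-type) identity genes"},
        )

    @classmethod
    def from_collection(cls, collection: GeneSetCollection) -> "IdentitySignature":
        return cls(med_genes=list(collection["MED"]),
                   extramed_genes=list(collection["EXTRAMED"]))


@dataclass
class IdentityResult:
    """Per-cell identity ratios and the per-sample summary."""

    per_cell: pd.DataFrame  # cell_id, score_med, score_extramed, rank_med, rank_extramed, ratio
    median_ratio: float
    ci_low: float
    ci_high: float
    n_cells: int


def wilcoxon_de(
    matrix: NormalizedMatrix,
    cells_a: list[str],
    cells_b: list[str],
    min_cells: int = 3,
) -> pd.DataFrame:
    """Per-gene two-sided Wilcoxon rank-sum test between two cell groups.

    Group sizes above 20 use the tie-corrected normal approximation;
    smaller tie-free comparisons use the exact null distribution.  The
    fold change is log2((mean expm1 A + 1) / (mean expm1 B + 1)), FDR is
    Benjamini-Hochberg across all tested genes.  Genes that are all-zero
    (or constant) across both groups get p = 1, fc = 0.
    """
    set_a, set_b = set(cells_a), set(cells_b)
    if set_a & set_b:
        raise ValidationError("cell groups must be disjoint")
    if len(cells_a) < min_cells or len(cells_b) < min_cells:
        raise ValidationError(f"both groups need >= {min_cells} cells")
    cell_pos = {c: i for i, c in enumerate(matrix.cell_ids)}
    missing = [c for c in list(cells_a) + list(cells_b) if c not in cell_pos]
    if missing:
        raise ValidationError(f"cells not in matrix: {missing[:10]}")
    ia = np.array([cell_pos[c] for c in cells_a])
    ib = np.array([cell_pos[c] for c in cells_b])
    X = matrix.values.tocsc()
    A = X[:, ia].toarray()
    B = X[:, ib].toarray()

    mean_a = np.expm1(A).mean(axis=1)
    mean_b = np.expm1(B).mean(axis=1)
    log2_fc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    constant = (A.min(axis=1) == A.max(axis=1)) & (B.min(axis=1) == B.max(axis=1)) \
        & (A[:, 0] == B[:, 0])

    use_exact = max(len(ia), len(ib)) <= 20
    pvals = np.ones(A.shape[0])
    if use_exact:
        for g in range(A.shape[0]):
            if constant[g]:
                continue
            ties = len(np.unique(np.concatenate([A[g], B[g]]))) < len(ia) + len(ib)
            method = "asymptotic" if ties else "exact"
            pvals[g] = stats.mannwhitneyu(A[g], B[g], alternative="two-sided",
                                          method=method).pvalue
    else:
        res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                 method="asymptotic", axis=1)
        pvals = np.asarray(res.pvalue)
        pvals[constant] = 1.0
    pvals = np.clip(np.nan_to_num(pvals, nan=1.0), 0.0, 1.0)
    log2_fc = np.where(constant, 0.0, log2_fc)

    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene": matrix.gene_ids,
        "log2_fc": log2_fc,
        "p": pvals,
        "fdr": fdr,
        "direction": np.where(log2_fc >= 0, "up_in_A", "up_in_B"),
    })


def derive_identity_signature(
    de: pd.DataFrame,
    n_top: int = 50,
    fdr_cut: float = 0.05,
    lfc_cut: float = 0.2,
) -> IdentitySignature:
    """Top differentially expressed genes per direction as the signature.

    Group A is the medullary pole by convention: genes up in A become
    med_genes, genes up in B extramed_genes, each ranked by |log2 fold
    change| and truncated to ``n_top``.  Fewer than 5 passing genes in
    either direction is an error (thresholds too strict for the data).
    """
    passing = de[(de["fdr"] < fdr_cut) & (de["log2_fc"].abs() > lfc_cut)]
    up_a = passing[passing["log2_fc"] > 0].sort_values("log2_fc", ascending=False, kind="stable")
    up_b = passing[passing["log2_fc"] < 0].sort_values("log2_fc", ascending=True, kind="stable")
    if len(up_a) < 5 or len(up_b) < 5:
        raise ValidationError(
            f"only {len(up_a)} med / {len(up_b)} extramed genes pass "
            f"fdr<{fdr_cut}, |lfc|>{lfc_cut}; lower the thresholds"
        )
    return IdentitySignature(
        med_genes=up_a["gene"].head(n_top).tolist(),
        extramed_genes=up_b["gene"].head(n_top).tolist(),
        params={"n_top": n_top, "fdr_cut": fdr_cut, "lfc_cut": lfc_cut},
    )


def _fractional_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks scaled to (0, 1]."""
    return stats.rankdata(x, method="average") / len(x)


def compute_identity_ratio(
    matrix: NormalizedMatrix,
    signature: IdentitySignature,
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    n_boot: int = 1000,
    method: str = "rank",
) -> IdentityResult:
    """Score both signature halves and form the per-cell identity ratio.

    ``method='rank'`` (default): each score vector is converted to
    fractional ranks over the scored cells and R = rank_med/rank_extramed.
    ``method='raw'``: both score vectors are shifted by a common constant
    to be strictly positive and divided directly.  The per-sample summary
    is the median R with a seeded bootstrap 95% CI.
    """
    score_med = score_signature(matrix, signature.med_genes, n_bins, n_ctrl, seed, "MED")
    score_ext = score_signature(matrix, signature.extramed_genes, n_bins, n_ctrl, seed, "EXTRAMED")
    n = len(score_med)
    if method == "rank":
        r_med = _fractional_ranks(score_med)
        r_ext = _fractional_ranks(score_ext)
    elif method == "raw":
        shift = min(score_med.min(), score_ext.min())
        offset = -shift + 1e-9 if shift <= 0 else 0.0
        r_med = score_med + offset
        r_ext = score_ext + offset
    else:
        raise ValidationError(f"unknown method {method!r}")
    ratio = r_med / r_ext

    rng = np.random.default_rng(derive_seed(seed, "identity-bootstrap"))
    boots = np.median(ratio[rng.integers(0, n, size=(n_boot, n))], axis=1)
    lo, hi = np.quantile(boots, [0.025, 0.975])
    return IdentityResult(
        per_cell=pd.DataFrame({
            "cell_id": matrix.cell_ids,
            "score_med": score_med,
            "score_extramed": score_ext,
            "rank_med": r_med,
            "rank_extramed": r_ext,
            "ratio": ratio,
        }),
        median_ratio=float(np.median(ratio)),
        ci_low=float(lo),
        ci_high=float(hi),
        n_cells=n,
    )


def identity_by_sample(
    matrix: NormalizedMatrix,
    signature: IdentitySignature,
    sample_of: dict[str, str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
    n_boot: int = 1000,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Per-sample identity summaries over one shared scoring cohort.

    Scores and fractional ranks are computed once over all cells of the
    matrix (the cohort), as identity comparisons are only meaningful
    relative to a common landscape; each sample (per ``sample_of``,
    cell_id -> sample label) is then summarized by its median ratio with a
    seeded bootstrap CI and classified by the threshold-at-1 rule.
    """
    full = compute_identity_ratio(matrix, signature, n_bins, n_ctrl, seed, n_boot=2)
    per_cell = full.per_cell
    per_cell["sample"] = per_cell["cell_id"].map(sample_of)
    rows = []
    for sample, sub in per_cell.groupby("sample", observed=True):
        ratio = sub["ratio"].to_numpy()
        n = len(ratio)
        rng = np.random.default_rng(derive_seed(seed, "identity-bootstrap", str(sample)))
        boots = np.median(ratio[rng.integers(0, n, size=(n_boot, n))], axis=1)
        lo, hi = np.quantile(boots, [0.025, 0.975])
        res = IdentityResult(per_cell=sub, median_ratio=float(np.median(ratio)),
                             ci_low=float(lo), ci_high=float(hi), n_cells=n)
        rows.append({"sample": sample, "n_cells": n,
                     "median_ratio": res.median_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high,
                     "label": classify_identity(res, min_cells=min_cells)})
    return pd.DataFrame(rows)


def classify_identity(result: IdentityResult, min_cells: int = 20) -> str:
    """Label a sample medullary / extramedullary / indeterminate.

    Medullary when the median ratio exceeds 1 with a bootstrap CI excluding
    1; extramedullary for the mirror case; otherwise (including samples
    with too few cells) indeterminate.
    """
    if result.n_cells < min_cells:
        logger.warning("classify_identity: only %d cells (< %d), indeterminate",
                       result.n_cells, min_cells)
        return "indeterminate"
    if result.median_ratio > 1 and result.ci_low > 1:
        return "medullary"
    if result.median_ratio < 1 and result.ci_high < 1:
        return "extramedullary"
    return "indeterminate"
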