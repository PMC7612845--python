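"""Pre-ranked gene-set enrichment analysis.

The classical weighted Kolmogorov-Smirnov-like running-sum statistic: walk
down a ranked gene list; at a set gene ("hit") add |metric|^p normalized by
the summed hit weights, at a miss subtract 1/(N - N_hits).  The enrichment
score (ES) is the signed maximum deviation of the running sum.  The null
is gene-label permutation (set membership reassigned uniformly at random),
as the pre-ranked setting dictates; NES normalizes by the mean |null ES|
of matching sign and the FDR is the standard NES-ratio estimate across
sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._utils import ValidationError, derive_seed, logger
from .io import GeneSetCollection

__all__ = ["RankedList", "GseaResult", "enrichment_score", "preranked_gsea"]


@dataclass
class RankedList:
    """Genes with a real ranking metric, stored in descending metric order."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list has duplicate genes")
        if not np.all(np.isfinite(self.metric)):
            raise ValidationError("ranking metric must be finite")
        order = np.argsort(-self.metric, kind="stable")
        self.genes = [self.genes[i] for i in order]
        self.metric = self.metric[order]

    @classmethod
    def from_series(cls, s: pd.Series) -> "RankedList":
        return cls(genes=list(s.index.astype(str)), metric=s.to_numpy(dtype=float))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    name: str
    es: float
    nes: float
    p_perm: float
    fdr: float
    leading_edge: list[str]
    n_hits: int


def _running_sum(weights: np.ndarray, hit_mask: np.ndarray) -> np.ndarray:
    """Running sum of the weighted KS walk for one 0/1 hit mask."""
    n = len(hit_mask)
    n_hits = int(hit_mask.sum())
    hit_w = np.where(hit_mask, weights, 0.0)
    total = hit_w.sum()
    p_hit = np.cumsum(hit_w) / total if total > 0 else np.cumsum(hit_mask) / max(n_hits, 1)
    if n_hits == n:  # saturated set: pure monotone rise, ES = 1
        return p_hit
    p_miss = np.cumsum(~hit_mask) / (n - n_hits)
    return p_hit - p_miss


def enrichment_score(
    ranked: RankedList,
    gene_set: list[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """ES and the full running sum for one gene set.

    The set must overlap the list and be strictly smaller than it.
    """
    positions = {g: i for i, g in enumerate(ranked.genes)}
    hits = [positions[g] for g in gene_set if g in positions]
    if not hits:
        raise ValidationError("gene set has no overlap with the ranked list")
    hit_mask = np.zeros(len(ranked), dtype=bool)
    hit_mask[hits] = True
    weights = np.abs(ranked.metric) ** weight
    running = _running_sum(weights, hit_mask)
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _null_es(
    weights: np.ndarray,
    set_size: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """Null ES distribution for random sets of a given size.

    Under gene-label permutation the null depends only on the set size, so
    it is computed once per size and shared across sets.
    """
    n = len(weights)
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random size-`set_size` subsets via partial argsort of random keys
        keys = rng.random((m, n))
        idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
        hit = np.zeros((m, n), dtype=bool)
        np.put_along_axis(hit, idx, True, axis=1)
        hit_w = np.where(hit, weights[None, :], 0.0)
        totals = hit_w.sum(axis=1, keepdims=True)
        p_hit = np.cumsum(hit_w, axis=1) / totals
        p_miss = np.cumsum(~hit, axis=1) / (n - set_size)
        running = p_hit - p_miss
        pos = np.argmax(np.abs(running), axis=1)
        out[done:done + m] = running[np.arange(m), pos]
        done += m
    return out


def preranked_gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight: float = 1.0,
) -> pd.DataFrame:
    """Run pre-ranked GSEA for every set in a collection.

    Returns a DataFrame with columns name, es, nes, p_perm, fdr, n_hits,
    leading_edge.  p_perm = (1 + #{same-sign null ES at least as extreme})
    / (n_perm + 1); FDR is the NES-ratio estimate pooling same-sign nulls
    across sets, clipped to [0, 1].  Sets without overlap are skipped with
    a warning.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    rng = np.random.default_rng(derive_seed(seed, "gsea"))
    weights = np.abs(ranked.metric) ** weight
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    nulls_by_set: list[np.ndarray] = []
    for name, genes in collection:
        try:
            es, running = enrichment_score(ranked, genes, weight)
        except ValidationError as exc:
            logger.warning("GSEA: skipping set %r: %s", name, exc)
            continue
        positions = {g: i for i, g in enumerate(ranked.genes)}
        hits = sorted(positions[g] for g in genes if g in positions)
        m = len(hits)
        if m >= len(ranked):  # saturated set: no permutation null exists
            rows.append({"name": name, "es": es, "nes": np.nan, "p_perm": 1.0,
                         "n_hits": m, "leading_edge": list(ranked.genes)})
            nulls_by_set.append(np.empty(0))
            continue
        if m not in null_cache:
            null_cache[m] = _null_es(weights, m, n_perm, rng)
        null = null_cache[m]
        # two-sided permutation p on |ES|; NES normalizes within the
        # matching-sign half of the null
        extreme = int((np.abs(null) >= abs(es)).sum())
        p_perm = (1 + extreme) / (n_perm + 1)
        same_sign = null >= 0 if es >= 0 else null < 0
        null_ss = null[same_sign]
        denom = np.abs(null_ss).mean() if null_ss.size else np.abs(null).mean()
        nes = es / denom if denom > 0 else np.nan

        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = [ranked.genes[i] for i in hits if i <= peak]
        else:
            leading = [ranked.genes[i] for i in hits if i >= peak]
        rows.append({"name": name, "es": es, "nes": nes, "p_perm": p_perm,
                     "n_hits": m, "leading_edge": leading})
        # same-sign normalized null NES pool for the FDR estimate
        pos_mean = np.abs(null[null >= 0]).mean() if (null >= 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        null_nes = np.where(null >= 0, null / pos_mean, null / neg_mean)
        nulls_by_set.append(null_nes[np.isfinite(null_nes)])

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    pooled = np.concatenate(nulls_by_set)
    obs = result["nes"].to_numpy()
    fdr = np.empty(len(result))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            fdr[i] = 1.0
            continue
        if nes >= 0:
            num_pool = pooled[pooled >= 0]
            obs_pool = obs[np.isfinite(obs) & (obs >= 0)]
        else:
            num_pool = pooled[pooled < 0]
            obs_pool = obs[np.isfinite(obs) & (obs < 0)]
        num = (np.abs(num_pool) >= abs(nes)).mean() if num_pool.size else 1.0
        den = (np.abs(obs_pool) >= abs(nes)).mean() if obs_pool.size else 1.0
        fdr[i] = min(1.0, num / den) if den > 0 else 1.0
    result["fdr"] = fdr
    return result[["name", "es", "nes", "p_perm", "fdr", "n_hits", "leading_edge"]]
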