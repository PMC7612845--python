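"""Tissue-level HSPC composition statistics.

Per-(donor, tissue) cluster or group fractions, early/late progenitor
ratios, S-G2-M cycling fractions, and the exact two-sided binomial test
used to compare cycling between tissues.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import ValidationError

__all__ = [
    "cluster_fractions",
    "group_ratio",
    "cycling_fractions",
    "compare_cycling_binomial",
]


def cluster_fractions(
    cells: pd.DataFrame,
    group_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cluster (or group) cell fractions per (donor, tissue).

    With *group_map*, clusters are aggregated into groups; the map must
    cover every cluster present.  Returns columns donor_id, tissue,
    cluster, n_cells, fraction; fractions sum to 1 within each
    (donor, tissue).
    """
    if cells["cluster"].isna().any():
        raise ValidationError("every cell needs a cluster label")
    work = cells[["donor_id", "tissue", "cluster"]].copy()
    if group_map is not None:
        unmapped = sorted(set(work["cluster"]) - set(group_map))
        if unmapped:
            raise ValidationError(f"group_map does not cover clusters: {unmapped}")
        work["cluster"] = work["cluster"].map(group_map)
    counts = (
        work.groupby(["donor_id", "tissue", "cluster"], observed=True)
        .size()
        .rename("n_cells")
        .reset_index()
    )
    totals = counts.groupby(["donor_id", "tissue"], observed=True)["n_cells"].transform("sum")
    counts["fraction"] = counts["n_cells"] / totals
    return counts


def group_ratio(
    composition: pd.DataFrame,
    numerator_groups: list[str],
    denominator_groups: list[str],
) -> pd.DataFrame:
    """Ratio of summed numerator to summed denominator fractions per
    (donor, tissue).  A zero denominator with a positive numerator gives an
    infinite, flagged ratio.  Numerator and denominator must be disjoint.
    """
    overlap = set(numerator_groups) & set(denominator_groups)
    if overlap:
        raise ValidationError(f"numerator/denominator overlap: {sorted(overlap)}")

    def _one(sub: pd.DataFrame) -> pd.Series:
        num = sub.loc[sub["cluster"].isin(numerator_groups), "fraction"].sum()
        den = sub.loc[sub["cluster"].isin(denominator_groups), "fraction"].sum()
        if den == 0:
            return pd.Series({"ratio": 0.0 if num == 0 else math.inf,
                              "degenerate": True})
        return pd.Series({"ratio": num / den, "degenerate": False})

    out = (
        composition.groupby(["donor_id", "tissue"], observed=True)
        .apply(_one, include_groups=False)
        .reset_index()
    )
    out["degenerate"] = out["degenerate"].astype(bool)
    return out


def cycling_fractions(cells: pd.DataFrame) -> pd.DataFrame:
    """S-G2-M fraction per (donor, tissue, cluster).

    Every cell must carry a phase in {G1, S, G2M}.  Empty groups cannot
    occur by construction; groups report n_total, n_sg2m and the fraction.
    """
    if cells["phase"].isna().any():
        bad = cells.loc[cells["phase"].isna(), "cell_id"].tolist()[:10]
        raise ValidationError(f"cells without phase assignment: {bad}")
    unknown = sorted(set(cells["phase"]) - {"G1", "S", "G2M"})
    if unknown:
        raise ValidationError(f"unknown phases: {unknown}")
    work = cells[["donor_id", "tissue", "cluster", "phase"]].copy()
    work["is_sg2m"] = work["phase"].isin(["S", "G2M"])
    out = (
        work.groupby(["donor_id", "tissue", "cluster"], observed=True)
        .agg(n_total=("is_sg2m", "size"), n_sg2m=("is_sg2m", "sum"))
        .reset_index()
    )
    out["fraction_sg2m"] = np.where(out["n_total"] > 0, out["n_sg2m"] / out["n_total"], 0.0)
    return out


def compare_cycling_binomial(x_a: int, n_a: int, x_b: int, n_b: int) -> float:
    """Two-sided exact binomial test of tissue B's cycling count against
    tissue A's pooled fraction.

    The null proportion is p0 = x_a / n_a; the two-sided p-value sums the
    probabilities of all outcomes no more likely than the observed one
    (the "minlike" rule).  Degenerate p0 in {0, 1} yields an exact 0/1
    p-value from the point-mass null.
    """
    for x, n in ((x_a, n_a), (x_b, n_b)):
        if not (0 <= x <= n):
            raise ValidationError(f"need 0 <= x <= n, got x={x}, n={n}")
    if n_a <= 0:
        raise ValidationError("reference tissue must have n_a > 0")
    p0 = x_a / n_a
    if p0 == 0.0:
        return 1.0 if x_b == 0 else 0.0
    if p0 == 1.0:
        return 1.0 if x_b == n_b else 0.0
    return float(stats.binomtest(x_b, n_b, p0, alternative="two-sided").pvalue)
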