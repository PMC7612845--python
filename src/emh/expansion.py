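"""Lower-bound branch-expansion model of differentiating divisions.

Along an ordered differentiation branch with per-stage cell counts N_s and
S-G2-M ("active") fractions f_s, the active cells A_s = N_s * f_s are the
only cells assumed to divide, and every division is taken to be symmetric
and differentiating (both daughters move to the next stage).  The
amplification needed to produce stage s+1 from the active cells of stage s
is then

    a_s = max(1, N_{s+1} / max(A_s, 1)),      d_s = log2(a_s),

with total differentiating divisions D = sum_s d_s.  The two floors encode
the lower-bound reading: at least one active cell per stage, and shrinking
stages contribute zero divisions rather than negative ones.  D depends
only on the stage-abundance ratios, so relative abundances suffice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ValidationError

__all__ = [
    "BranchModel",
    "ExpansionResult",
    "build_branch_model",
    "estimate_expansion",
    "normalize_output",
]


@dataclass
class BranchModel:
    """Ordered stages of one branch with abundances and active fractions.

    ``cycling_source`` records where f_s came from (e.g. transcriptional
    phase assignment vs an external Ki-67-style measurement).
    """

    branch_name: str
    stages: list[str]
    n_cells: np.ndarray
    cycling_fraction: np.ndarray
    cycling_source: str = "transcriptional"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.n_cells = np.asarray(self.n_cells, dtype=float)
        self.cycling_fraction = np.asarray(self.cycling_fraction, dtype=float)
        if len(self.stages) < 2:
            raise ValidationError("a branch needs at least 2 stages")
        if not (len(self.stages) == len(self.n_cells) == len(self.cycling_fraction)):
            raise ValidationError("stages, counts and fractions must have equal length")
        if (self.n_cells < 0).any():
            raise ValidationError("stage counts must be >= 0")
        if ((self.cycling_fraction < 0) | (self.cycling_fraction > 1)).any():
            raise ValidationError("cycling fractions must be in [0, 1]")

    @property
    def active_cells(self) -> np.ndarray:
        return self.n_cells * self.cycling_fraction


@dataclass
class ExpansionResult:
    """Per-transition amplifications and divisions plus cumulative output."""

    branch_name: str
    stages: list[str]
    amplification: np.ndarray  # a_s per transition, length S-1
    divisions: np.ndarray      # d_s = log2(a_s)
    cumulative_output: np.ndarray  # O_s, length S, O_1 = 1
    total_divisions: float
    flags: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "transition": [f"{a}->{b}" for a, b in zip(self.stages[:-1], self.stages[1:])],
            "amplification": self.amplification,
            "divisions": self.divisions,
        })


def build_branch_model(
    cells: pd.DataFrame,
    branch_spec: list[tuple[str, set[str]]],
    branch_name: str = "branch",
) -> dict[tuple[str, str], BranchModel]:
    """Count stage abundances and cycling fractions per (donor, tissue).

    ``branch_spec`` is an ordered list of (stage name, cluster set); the
    cluster sets must be disjoint.  Cells in listed clusters must have a
    phase; the S-G2-M fraction per stage becomes f_s.  Empty stages get
    N_s = 0 and a flag.
    """
    seen: set[str] = set()
    for stage, members in branch_spec:
        overlap = seen & set(members)
        if overlap:
            raise ValidationError(f"clusters in multiple stages: {sorted(overlap)}")
        seen |= set(members)
    stage_names = [s for s, _ in branch_spec]
    relevant = cells[cells["cluster"].isin(seen)]
    if relevant["phase"].isna().any():
        bad = relevant.loc[relevant["phase"].isna(), "cell_id"].tolist()[:10]
        raise ValidationError(f"branch cells without phase: {bad}")

    models: dict[tuple[str, str], BranchModel] = {}
    for (donor, tissue), sub in relevant.groupby(["donor_id", "tissue"], observed=True):
        N, f, flags = [], [], []
        for stage, members in branch_spec:
            grp = sub[sub["cluster"].isin(members)]
            n = len(grp)
            N.append(n)
            f.append(float(grp["phase"].isin(["S", "G2M"]).mean()) if n else 0.0)
            if n == 0:
                flags.append(f"stage {stage}: no cells")
        models[(donor, tissue)] = BranchModel(
            branch_name=branch_name, stages=stage_names,
            n_cells=np.array(N, dtype=float), cycling_fraction=np.array(f),
            flags=flags,
        )
    return models


def estimate_expansion(model: BranchModel) -> ExpansionResult:
    """Lower-bound amplification and divisions along the branch.

    a_s = max(1, N_{s+1} / max(A_s, 1)); d_s = log2(a_s); O_1 = 1 and
    O_{s+1} = O_s * a_s; D = sum(d_s).  Degenerate transitions (no active
    cells, or a shrinking stage) are floored and flagged, never errors.
    """
    N = model.n_cells
    A = model.active_cells
    flags = list(model.flags)
    amp = np.empty(len(N) - 1)
    for s in range(len(N) - 1):
        floor_a = max(A[s], 1.0)
        if A[s] < 1.0:
            flags.append(f"transition {model.stages[s]}->{model.stages[s+1]}: "
                         f"active cells {A[s]:.3g} floored to 1")
        a = N[s + 1] / floor_a
        if a < 1.0:
            flags.append(f"transition {model.stages[s]}->{model.stages[s+1]}: "
                         "shrinking stage, amplification floored to 1")
            a = 1.0
        amp[s] = a
    divisions = np.log2(amp)
    output = np.concatenate([[1.0], np.cumprod(amp)])
    return ExpansionResult(
        branch_name=model.branch_name,
        stages=list(model.stages),
        amplification=amp,
        divisions=divisions,
        cumulative_output=output,
        total_divisions=float(divisions.sum()),
        flags=flags,
    )


def normalize_output(
    results: dict[str, ExpansionResult],
    reference_condition: str,
) -> pd.DataFrame:
    """Cumulative outputs of several conditions side by side.

    All conditions must share the same stage list.  The reference condition
    also contributes the theoretical exponential curve 2^(cumulative
    divisions) that an ideal doubling cascade would follow.
    """
    if reference_condition not in results:
        raise ValidationError(f"unknown reference condition {reference_condition!r}")
    ref = results[reference_condition]
    frames = []
    for name, res in results.items():
        if res.stages != ref.stages:
            raise ValidationError(
                f"condition {name!r} has stages {res.stages}, reference has {ref.stages}"
            )
        frames.append(pd.DataFrame({
            "condition": name,
            "stage": res.stages,
            "output": res.cumulative_output,
        }))
    theory = np.concatenate([[1.0], 2.0 ** np.cumsum(ref.divisions)])
    frames.append(pd.DataFrame({
        "condition": f"theoretical({reference_condition})",
        "stage": ref.stages,
        "output": theory,
    }))
    return pd.concat(frames, ignore_index=True)
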