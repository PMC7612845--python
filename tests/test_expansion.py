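"""Branch-expansion estimator: worked fixtures, floors, recovery."""

import numpy as np
import pandas as pd
import pytest

from emh import ValidationError
from emh.expansion import (
    BranchModel,
    build_branch_model,
    estimate_expansion,
    normalize_output,
)
from emh.simulate import simulate_branch_counts

MEMB_FIXTURE = dict(n_cells=[1000, 2000, 4000, 8000], cycling_fraction=[0.5] * 4)
MY_FIXTURE = dict(n_cells=[1000, 4000], cycling_fraction=[0.5, 0.5])


def make_model(n_cells, cycling_fraction, name="branch"):
    return BranchModel(branch_name=name,
                       stages=[f"s{i}" for i in range(len(n_cells))],
                       n_cells=np.array(n_cells, dtype=float),
                       cycling_fraction=np.array(cycling_fraction, dtype=float))


class TestBuildBranchModel:
    def _cells(self):
        rows = []
        for cluster, phase, n in [("E1", "S", 30), ("E1", "G1", 70),
                                  ("E2", "G1", 300)]:
            rows += [{"cell_id": f"{cluster}_{phase}_{i}", "donor_id": "D1",
                      "tissue": "BM", "cluster": cluster, "phase": phase}
                     for i in range(n)]
        return pd.DataFrame(rows)

    def test_direct_counts_and_fractions(self):
        models = build_branch_model(self._cells(), [("early", {"E1"}), ("late", {"E2"})])
        model = models[("D1", "BM")]
        np.testing.assert_array_equal(model.n_cells, [100, 300])
        np.testing.assert_allclose(model.cycling_fraction, [0.3, 0.0])

    def test_empty_stage_flagged(self):
        models = build_branch_model(self._cells(), [("early", {"E1"}), ("ghost", {"E9"})])
        model = models[("D1", "BM")]
        assert model.n_cells[1] == 0
        assert any("no cells" in f for f in model.flags)

    def test_cell_order_invariance(self):
        cells = self._cells()
        shuffled = cells.sample(frac=1.0, random_state=1)
        a = build_branch_model(cells, [("early", {"E1"}), ("late", {"E2"})])[("D1", "BM")]
        b = build_branch_model(shuffled, [("early", {"E1"}), ("late", {"E2"})])[("D1", "BM")]
        np.testing.assert_array_equal(a.n_cells, b.n_cells)
        np.testing.assert_array_equal(a.cycling_fraction, b.cycling_fraction)

    def test_overlapping_stages_rejected(self):
        with pytest.raises(ValidationError, match="multiple stages"):
            build_branch_model(self._cells(), [("a", {"E1"}), ("b", {"E1", "E2"})])


class TestEstimateExpansion:
    def test_memb_fixture_six_divisions(self):
        """Exponential doubling branch with half the cells active at each
        stage: amplification 4 per transition, 6 divisions in total."""
        res = estimate_expansion(make_model(**MEMB_FIXTURE))
        np.testing.assert_allclose(res.amplification, [4.0, 4.0, 4.0])
        np.testing.assert_allclose(res.divisions, [2.0, 2.0, 2.0])
        assert res.total_divisions == pytest.approx(6.0)

    def test_my_fixture_three_divisions(self):
        res = estimate_expansion(make_model(**MY_FIXTURE))
        np.testing.assert_allclose(res.amplification, [8.0])
        assert res.total_divisions == pytest.approx(3.0)

    def test_shrinking_stage_floors_to_zero(self):
        res = estimate_expansion(make_model([1000, 500], [1.0, 1.0]))
        assert res.amplification[0] == 1.0
        assert res.total_divisions == 0.0
        assert any("shrinking" in f for f in res.flags)

    def test_no_active_cells_floored_to_one(self):
        res = estimate_expansion(make_model([10, 80], [0.0, 0.5]))
        # A_1 = 0 floored to 1: amplification 80, flagged
        assert res.amplification[0] == pytest.approx(80.0)
        assert any("floored to 1" in f for f in res.flags)

    def test_scale_invariance(self):
        a = estimate_expansion(make_model([100, 200, 400], [0.5, 0.5, 0.5]))
        b = estimate_expansion(make_model([1000, 2000, 4000], [0.5, 0.5, 0.5]))
        assert a.total_divisions == pytest.approx(b.total_divisions)

    def test_divisions_decrease_with_cycling_fraction(self):
        base = [1000, 2000, 4000, 8000]
        totals = [estimate_expansion(make_model(base, [f] * 4)).total_divisions
                  for f in (0.2, 0.4, 0.6, 0.8, 1.0)]
        assert all(x >= y for x, y in zip(totals, totals[1:]))

    def test_cumulative_output_monotone(self):
        res = estimate_expansion(make_model(**MEMB_FIXTURE))
        assert np.all(np.diff(res.cumulative_output) >= 0)
        np.testing.assert_allclose(res.cumulative_output, [1, 4, 16, 64])

    def test_recovery_from_multinomial_samples(self):
        """Sampling 50,000 cells from the doubling branch recovers the
        6-division estimate to within 0.1 on average across 100 seeds
        (per-seed multinomial noise has sd ~0.04, so individual seeds can
        stray slightly beyond)."""
        errors = []
        for seed in range(100):
            obs = simulate_branch_counts(MEMB_FIXTURE["n_cells"],
                                         MEMB_FIXTURE["cycling_fraction"],
                                         n_sample=50_000, seed=seed)
            model = make_model(obs.n_cells, obs.cycling_fraction)
            errors.append(abs(estimate_expansion(model).total_divisions - 6.0))
        assert np.mean(errors) < 0.1


class TestNormalizeOutput:
    def test_identical_conditions_identical_curves(self):
        res = {c: estimate_expansion(make_model(**MEMB_FIXTURE)) for c in ("BM", "ref")}
        table = normalize_output(res, "ref")
        bm = table[table["condition"] == "BM"]["output"].to_numpy()
        ref = table[table["condition"] == "ref"]["output"].to_numpy()
        np.testing.assert_array_equal(bm, ref)

    def test_no_expansion_curve_is_flat(self):
        res = {"flat": estimate_expansion(make_model([500, 400, 300], [1.0, 1.0, 1.0])),
               "ref": estimate_expansion(make_model(**{"n_cells": [500, 1000, 2000],
                                                       "cycling_fraction": [0.5] * 3}))}
        table = normalize_output(res, "ref")
        flat = table[table["condition"] == "flat"]["output"]
        np.testing.assert_array_equal(flat, 1.0)

    def test_stress_condition_raises_final_output(self):
        """A stress-erythropoiesis-like condition with a doubled terminal
        amplification ends higher than control while a control branch with
        the same early transitions is unchanged."""
        control = estimate_expansion(make_model([1000, 2000, 4000], [0.5] * 3))
        stress = estimate_expansion(make_model([1000, 2000, 8000], [0.5] * 3))
        table = normalize_output({"control": control, "stress": stress}, "control")
        final = table.groupby("condition")["output"].last()
        assert final["stress"] > final["control"]
        theory = table[table["condition"] == "theoretical(control)"]["output"].to_numpy()
        np.testing.assert_allclose(theory, control.cumulative_output)

    def test_mismatched_stages_rejected(self):
        res = {"a": estimate_expansion(make_model(**MEMB_FIXTURE)),
               "b": estimate_expansion(make_model(**MY_FIXTURE))}
        with pytest.raises(ValidationError, match="stages"):
            normalize_output(res, "a")
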