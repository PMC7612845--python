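"""Differential expression, identity signature derivation and the
rank-ratio classifier."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import dense_normalized
from emh import ValidationError
from emh.identity import (
    IdentityResult,
    IdentitySignature,
    classify_identity,
    compute_identity_ratio,
    derive_identity_signature,
    identity_by_sample,
    wilcoxon_de,
)
from emh.io import concat_counts, normalize
from emh.simulate import (
    EXTRAMED_GENES,
    MED_GENES,
    identity_test_config,
    identity_training_config,
    simulate_dataset,
)


def _train_signature(seed=7, **kwargs):
    ds = simulate_dataset(identity_training_config(seed=seed, **kwargs))
    norm = normalize(ds.counts)
    cells_a = ds.cells.loc[ds.cells["tissue"] == "BM", "cell_id"].tolist()
    cells_b = ds.cells.loc[ds.cells["tissue"] == "SPL", "cell_id"].tolist()
    de = wilcoxon_de(norm, cells_a, cells_b)
    return de, derive_identity_signature(de)


class TestWilcoxonDe:
    def test_null_groups_pass_nothing(self, rng):
        # two groups drawn from the same distribution: no FDR hits
        values = rng.gamma(1.0, 1.0, size=(200, 40)).round(2)
        norm = dense_normalized(values)
        de = wilcoxon_de(norm, norm.cell_ids[:20], norm.cell_ids[20:])
        assert (de["fdr"] < 0.05).sum() == 0

    def test_planted_fold_change_detected(self):
        """A gene shifted x4 in group A is flagged at FDR < 0.05 with the
        right direction on a 200 v 200 negative-binomial simulation."""
        rng = np.random.default_rng(3)
        mu = np.full((50, 400), 2.0)
        mu[7, :200] *= 4.0
        counts = rng.poisson(rng.gamma(2.0, mu / 2.0))
        norm = dense_normalized(np.log1p(counts))
        de = wilcoxon_de(norm, norm.cell_ids[:200], norm.cell_ids[200:])
        row = de.iloc[7]
        assert row["fdr"] < 0.05
        assert row["direction"] == "up_in_A"
        assert (de.drop(index=7)["fdr"] < 0.05).sum() == 0

    def test_exact_small_sample_matches_enumeration(self):
        """5v5 tie-free comparison equals the exact rank-sum permutation
        enumeration."""
        a = np.array([1.3, 2.1, 4.4, 5.0, 6.2])
        b = np.array([0.2, 0.9, 2.8, 3.3, 3.9])
        values = np.vstack([np.concatenate([a, b])])
        norm = dense_normalized(values)
        de = wilcoxon_de(norm, norm.cell_ids[:5], norm.cell_ids[5:], min_cells=3)

        combined = np.concatenate([a, b])
        u_obs = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        mu = len(a) * len(b) / 2
        u_all = [
            sum((combined[i] > y) + 0.5 * (combined[i] == y)
                for i in idx for y in np.delete(combined, list(idx)))
            for idx in itertools.combinations(range(10), 5)
        ]
        p_exact = np.mean([abs(u - mu) >= abs(u_obs - mu) for u in u_all])
        assert de["p"].iloc[0] == pytest.approx(p_exact, rel=1e-9)

    def test_overlapping_groups_rejected(self, rng):
        norm = dense_normalized(rng.gamma(1.0, 1.0, size=(5, 10)))
        with pytest.raises(ValidationError, match="disjoint"):
            wilcoxon_de(norm, norm.cell_ids[:5], norm.cell_ids[4:])

    def test_all_zero_gene_is_null(self, rng):
        values = rng.gamma(1.0, 1.0, size=(5, 30))
        values[2] = 0.0
        norm = dense_normalized(values)
        de = wilcoxon_de(norm, norm.cell_ids[:15], norm.cell_ids[15:])
        assert de["p"].iloc[2] == 1.0
        assert de["log2_fc"].iloc[2] == 0.0

    def test_bh_fdr_matches_step_up_oracle(self, rng):
        """BH column agrees with a from-scratch step-up implementation on
        random p-vectors."""
        def bh(p):
            n = len(p)
            order = np.argsort(p)
            adj = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                adj[i] = running
            return adj

        for _ in range(20):
            values = rng.gamma(1.0, 1.0, size=(50, 50)).round(2)
            norm = dense_normalized(values)
            de = wilcoxon_de(norm, norm.cell_ids[:25], norm.cell_ids[25:])
            np.testing.assert_allclose(de["fdr"], bh(de["p"].to_numpy()), atol=1e-12)


class TestDeriveSignature:
    def test_direct_selection(self):
        n = 300
        de = pd.DataFrame({
            "gene": [f"g{i}" for i in range(n)],
            "log2_fc": np.concatenate([np.linspace(0.3, 2, 100),
                                       -np.linspace(0.3, 2, 100),
                                       np.zeros(100)]),
            "p": [1e-4] * 200 + [0.9] * 100,
            "fdr": [1e-3] * 200 + [0.95] * 100,
        })
        de["direction"] = np.where(de["log2_fc"] >= 0, "up_in_A", "up_in_B")
        sig = derive_identity_signature(de, n_top=50)
        assert len(sig.med_genes) == 50 and len(sig.extramed_genes) == 50
        assert sig.med_genes[0] == "g99"  # largest positive fold change first
        assert sig.extramed_genes[0] == "g199"

    def test_all_null_table_errors(self):
        de = pd.DataFrame({"gene": ["a", "b"], "log2_fc": [0.01, -0.01],
                           "p": [0.9, 0.8], "fdr": [0.9, 0.9],
                           "direction": ["up_in_A", "up_in_B"]})
        with pytest.raises(ValidationError, match="lower the thresholds"):
            derive_identity_signature(de)

    def test_planted_programs_recovered(self):
        """>= 80% of the 50-gene planted programs are recovered in the
        correct direction when training on the simulated poles."""
        _, sig = _train_signature(seed=7)
        gene_ids = identity_training_config().gene_ids()
        med_truth = {gene_ids[i] for i in MED_GENES}
        ext_truth = {gene_ids[i] for i in EXTRAMED_GENES}
        assert len(set(sig.med_genes) & med_truth) >= 40
        assert len(set(sig.extramed_genes) & ext_truth) >= 40

    def test_halves_must_be_disjoint(self):
        with pytest.raises(ValidationError, match="disjoint"):
            IdentitySignature(med_genes=["a", "b"], extramed_genes=["b", "c"])


class TestIdentityRatio:
    def test_identical_cells_have_unit_ratio(self):
        # every cell identical: all ranks tie at the midpoint, R = 1 exactly
        values = np.tile(np.linspace(0.1, 3.0, 40)[:, None], (1, 25))
        norm = dense_normalized(values)
        sig = IdentitySignature(med_genes=["g0", "g1"], extramed_genes=["g2", "g3"])
        res = compute_identity_ratio(norm, sig, n_bins=1, n_ctrl=5, seed=0)
        np.testing.assert_allclose(res.per_cell["ratio"], 1.0)
        assert res.median_ratio == pytest.approx(1.0)

    def test_swapping_halves_inverts_ratio(self, rng):
        values = rng.gamma(1.0, 1.0, size=(60, 30))
        norm = dense_normalized(values)
        sig = IdentitySignature(med_genes=["g0", "g1", "g2"],
                                extramed_genes=["g3", "g4", "g5"])
        swapped = IdentitySignature(med_genes=sig.extramed_genes,
                                    extramed_genes=sig.med_genes)
        a = compute_identity_ratio(norm, sig, n_bins=1, n_ctrl=10, seed=4)
        b = compute_identity_ratio(norm, swapped, n_bins=1, n_ctrl=10, seed=4)
        np.testing.assert_allclose(a.per_cell["ratio"] * b.per_cell["ratio"], 1.0,
                                   atol=1e-12)

    def test_raw_method_also_inverts(self, rng):
        values = rng.gamma(1.0, 1.0, size=(60, 30))
        norm = dense_normalized(values)
        sig = IdentitySignature(med_genes=["g0", "g1", "g2"],
                                extramed_genes=["g3", "g4", "g5"])
        swapped = IdentitySignature(med_genes=sig.extramed_genes,
                                    extramed_genes=sig.med_genes)
        a = compute_identity_ratio(norm, sig, n_bins=1, n_ctrl=10, seed=4, method="raw")
        b = compute_identity_ratio(norm, swapped, n_bins=1, n_ctrl=10, seed=4, method="raw")
        np.testing.assert_allclose(a.per_cell["ratio"] * b.per_cell["ratio"], 1.0,
                                   rtol=1e-9)


class TestClassification:
    def _result(self, ratios):
        ratios = np.asarray(ratios, dtype=float)
        return IdentityResult(
            per_cell=pd.DataFrame({"cell_id": range(len(ratios)), "ratio": ratios}),
            median_ratio=float(np.median(ratios)),
            ci_low=float(np.quantile(ratios, 0.025)),
            ci_high=float(np.quantile(ratios, 0.975)),
            n_cells=len(ratios),
        )

    def test_unit_ratios_indeterminate(self):
        assert classify_identity(self._result([1.0] * 30)) == "indeterminate"

    def test_confident_medullary(self):
        res = IdentityResult(per_cell=pd.DataFrame(), median_ratio=1.4,
                             ci_low=1.2, ci_high=1.6, n_cells=100)
        assert classify_identity(res) == "medullary"

    def test_ci_spanning_one_indeterminate(self):
        res = IdentityResult(per_cell=pd.DataFrame(), median_ratio=0.7,
                             ci_low=0.5, ci_high=1.1, n_cells=100)
        assert classify_identity(res) == "indeterminate"

    def test_too_few_cells_indeterminate(self):
        res = IdentityResult(per_cell=pd.DataFrame(), median_ratio=1.5,
                             ci_low=1.3, ci_high=1.7, n_cells=10)
        assert classify_identity(res) == "indeterminate"


class TestEndToEnd:
    def test_held_out_samples_classified_correctly(self):
        """Signatures trained on simulated poles classify held-out
        medullary, extramedullary and mobilized-PB-like (extramedullary
        program) samples correctly across seeds."""
        correct = 0
        total = 0
        for seed in range(10):
            _, sig = _train_signature(seed=100 + seed, n_per_pole=300)
            samples = {
                "BM-like": ("med", "BM", "medullary"),
                "SPL-like": ("extramed", "SPL", "extramedullary"),
                "PB-like": ("extramed", "PB", "extramedullary"),
            }
            datasets = {
                name: simulate_dataset(identity_test_config(
                    program, n_cells=300, seed=200 + 10 * seed + i, tissue=tissue))
                for i, (name, (program, tissue, _)) in enumerate(samples.items())
            }
            combo = concat_counts([d.counts for d in datasets.values()])
            sample_of = {c: name for name, d in datasets.items() for c in d.counts.cell_ids}
            summary = identity_by_sample(normalize(combo), sig, sample_of, seed=seed)
            for name, (_, _, want) in samples.items():
                got = summary.loc[summary["sample"] == name, "label"].iloc[0]
                correct += got == want
                total += 1
        assert correct / total >= 0.95

    def test_direction_of_median_ratios(self):
        """Medullary-program cells score median ratio > 1, extramedullary
        < 1, in a shared cohort (threshold-at-1 rule)."""
        _, sig = _train_signature(seed=7)
        med = simulate_dataset(identity_test_config("med", seed=11))
        ext = simulate_dataset(identity_test_config("extramed", seed=13, tissue="SPL"))
        combo = concat_counts([med.counts, ext.counts])
        sample_of = {c: "med" for c in med.counts.cell_ids}
        sample_of |= {c: "ext" for c in ext.counts.cell_ids}
        summary = identity_by_sample(normalize(combo), sig, sample_of, seed=1)
        med_ratio = summary.loc[summary["sample"] == "med", "median_ratio"].iloc[0]
        ext_ratio = summary.loc[summary["sample"] == "ext", "median_ratio"].iloc[0]
        assert med_ratio > 1.0
        assert ext_ratio < 1.0
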