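import json

import numpy as np
import pytest

from omdr import (
    DatasetError,
    GenotypeCellCounts,
    SimulationConfig,
    binarize_phenotype,
    builtin_model,
    estimated_or,
    hwe_genotype_freqs,
    implied_prevalences,
    load_model_spec,
    null_model,
    penetrance_from_ors,
    simulate_dataset,
    simulate_replicates,
)
from omdr.simulate import cell_hwe_probs, ors_from_penetrance, replicate_rng


class TestHWE:
    def test_maf_half(self):
        np.testing.assert_allclose(hwe_genotype_freqs(0.5), [0.25, 0.5, 0.25])

    def test_maf_point_three(self):
        np.testing.assert_allclose(hwe_genotype_freqs(0.3), [0.49, 0.42, 0.09])

    def test_sums_to_one(self):
        for q in (0.01, 0.17, 0.43, 0.5):
            assert hwe_genotype_freqs(q).sum() == pytest.approx(1.0, abs=1e-15)

    def test_range_validation(self):
        for q in (0.0, 0.6, -0.1):
            with pytest.raises(DatasetError):
                hwe_genotype_freqs(q)


class TestPenetranceFromORs:
    def test_null_identity(self):
        prev = np.array([0.3, 0.4, 0.3])
        pen = penetrance_from_ors(np.ones((9, 3)), prev)
        np.testing.assert_allclose(pen, np.tile(prev, (9, 1)))

    def test_hand_normalised_row(self):
        pen = penetrance_from_ors(np.array([[1.0, 2.0, 1.0]]), [0.3, 0.4, 0.3])
        np.testing.assert_allclose(pen[0], [0.3 / 1.4, 0.8 / 1.4, 0.3 / 1.4])
        np.testing.assert_allclose(pen[0], [0.214286, 0.571429, 0.214286], atol=1e-6)

    def test_negative_or_rejected(self):
        with pytest.raises(DatasetError):
            penetrance_from_ors(np.array([[1.0, -2.0]]), [0.5, 0.5])

    def test_or_roundtrip_inverse(self, rng):
        ors = np.hstack([np.ones((9, 1)), rng.uniform(0.2, 5, size=(9, 2))])
        pen = penetrance_from_ors(ors, [0.3, 0.4, 0.3])
        np.testing.assert_allclose(ors_from_penetrance(pen, [0.3, 0.4, 0.3]), ors)

    def test_expected_counts_recover_ors(self):
        """Applying the odds-ratio estimator to EXPECTED cell counts under
        (HWE genotype frequencies x penetrances) is consistent with the
        generator: it recovers the odds ratios taken against the realized
        class marginals (which the estimator's denominator uses), and for
        the null model it recovers the input table of ones exactly."""
        model = builtin_model("strong_checkerboard")
        cellp = cell_hwe_probs(model)
        expected = 1e7 * cellp[:, None] * model.penetrance
        cc = GenotypeCellCounts(expected, expected.sum(axis=0), (0, 1))
        marginal = implied_prevalences(model)
        want = ors_from_penetrance(model.penetrance, marginal)
        for i in range(9):
            for j in (2, 3):
                assert estimated_or(cc, i, j) == pytest.approx(want[i, j - 1], rel=1e-9)

        nm = null_model()
        expected = 1e7 * cell_hwe_probs(nm)[:, None] * nm.penetrance
        cc = GenotypeCellCounts(expected, expected.sum(axis=0), (0, 1))
        for i in range(9):
            for j in (1, 2, 3):
                assert estimated_or(cc, i, j) == pytest.approx(1.0, rel=1e-12)


class TestSimulateDataset:
    def test_same_seed_identical(self):
        m = builtin_model("demo_moderate")
        cfg = SimulationConfig(n_samples=50, n_snps=6, seed=5)
        a = simulate_dataset(m, cfg, 11)
        b = simulate_dataset(m, cfg, 11)
        assert a == b

    def test_causal_cell_fractions_converge_to_penetrance(self):
        """Law of large numbers: within each causal genotype cell the class
        fractions approach the penetrance row.  27 fractions are checked at
        once, so the per-comparison bound is 4 binomial SEs (family-wise
        error ~0.2% by Bonferroni, vs ~7% if each used 3 SEs)."""
        m = builtin_model("strong_checkerboard")
        cfg = SimulationConfig(n_samples=40_000, n_snps=3, seed=0)
        ds = simulate_dataset(m, cfg, 123)
        cells = ds.genotypes[:, 0] + 3 * ds.genotypes[:, 1]
        for i in range(9):
            mask = cells == i
            n_cell = mask.sum()
            frac = np.bincount(ds.phenotype[mask], minlength=4)[1:] / n_cell
            tol = 4 * np.sqrt(m.penetrance[i] * (1 - m.penetrance[i]) / n_cell)
            assert (np.abs(frac - m.penetrance[i]) < np.maximum(tol, 1e-3)).all()

    def test_noncausal_snps_independent_of_phenotype(self):
        m = builtin_model("strong_checkerboard")
        cfg = SimulationConfig(n_samples=30_000, n_snps=4, seed=0, noncausal_maf=0.3)
        ds = simulate_dataset(m, cfg, 9)
        g = ds.genotypes[:, 3]
        freqs = np.bincount(g, minlength=3) / len(g)
        np.testing.assert_allclose(freqs, hwe_genotype_freqs(0.3), atol=0.01)
        # correlation with phenotype ~ 0
        assert abs(np.corrcoef(g, ds.phenotype)[0, 1]) < 3 / np.sqrt(len(g))


class TestReplicates:
    def test_streams_are_distinct(self):
        m = null_model()
        cfg = SimulationConfig(n_samples=30, n_snps=4, n_replicates=5, seed=2)
        reps = list(simulate_replicates(m, cfg))
        assert len(reps) == 5
        for i in range(5):
            for j in range(i + 1, 5):
                assert reps[i] != reps[j]

    def test_single_replicate_regenerable(self):
        m = null_model()
        cfg = SimulationConfig(n_samples=40, n_snps=5, n_replicates=8, seed=99)
        stream = list(simulate_replicates(m, cfg))
        alone = simulate_dataset(m, cfg, replicate_rng(99, 7))
        assert alone == stream[7]


class TestNullModel:
    def test_implied_prevalences_exact(self):
        m = null_model()
        np.testing.assert_allclose(implied_prevalences(m), [0.3, 0.4, 0.3], atol=1e-12)

    def test_class_proportions_and_case_prevalence(self):
        """Large-sample calibration: simulated class fractions match the
        target prevalences and binarizing classes 1-2 vs 3 gives a case
        prevalence of 0.3, each within 3 binomial standard errors."""
        m = null_model()
        cfg = SimulationConfig(n_samples=10_000, n_snps=5, seed=0)
        ds = simulate_dataset(m, cfg, 2026)
        frac = ds.class_counts() / ds.n_samples
        target = np.array([0.3, 0.4, 0.3])
        se = np.sqrt(target * (1 - target) / ds.n_samples)
        assert (np.abs(frac - target) < 3 * se).all()
        case = (binarize_phenotype(ds, 2).phenotype == 2).mean()
        assert abs(case - 0.3) < 3 * np.sqrt(0.3 * 0.7 / ds.n_samples)


class TestModelSpecs:
    def test_builtin_null_rows_equal_prevalences(self):
        m = builtin_model("null_3class")
        np.testing.assert_allclose(m.penetrance, np.tile([0.3, 0.4, 0.3], (9, 1)))

    def test_cross_representation_consistency(self, tmp_path):
        """The same model given as ORs and as explicit penetrances loads to
        identical tables."""
        m = builtin_model("demo_moderate")
        spec = {
            "classes": 3,
            "prevalences": [0.3, 0.4, 0.3],
            "mafs": [0.3, 0.5],
            "genotype_rows": [
                {
                    "genotype": [i % 3, i // 3],
                    "penetrance": m.penetrance[i % 3 + 3 * (i // 3)].tolist(),
                }
                for i in range(9)
            ],
        }
        path = tmp_path / "m.json"
        path.write_text(json.dumps(spec))
        m2 = load_model_spec(path)
        np.testing.assert_allclose(m2.penetrance, m.penetrance, atol=1e-12)

    def test_missing_row_named_in_error(self, tmp_path):
        spec = {
            "classes": 3,
            "prevalences": [0.3, 0.4, 0.3],
            "mafs": [0.3, 0.5],
            "genotype_rows": [
                {"genotype": [0, 0], "or": [1, 1, 1]},
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(spec))
        with pytest.raises(DatasetError, match="missing OR row"):
            load_model_spec(path)

    def test_bad_penetrance_row_sum_rejected(self, tmp_path):
        spec = {
            "classes": 2,
            "prevalences": [0.5, 0.5],
            "mafs": [0.3],
            "genotype_rows": [
                {"genotype": [g], "penetrance": [0.6, 0.6]} for g in (0, 1, 2)
            ],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(spec))
        with pytest.raises(DatasetError, match="sum to 1"):
            load_model_spec(path)

    def test_unknown_builtin(self):
        with pytest.raises(DatasetError, match="no built-in"):
            builtin_model("nope")
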