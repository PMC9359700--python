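import numpy as np
import pandas as pd
import pytest

from polycage.diffexp import (
    DeSettings,
    de_test,
    dtu_test,
    estimate_dispersions,
    sample_pca,
    size_factors,
)

COND = pd.Series({"wt1": "WT", "wt2": "WT", "t1": "TCL1", "t2": "TCL1"})


def nb(rng, mean, dispersion, size):
    n = 1.0 / dispersion
    return rng.negative_binomial(n, n / (n + np.asarray(mean, dtype=float)), size=size)


def null_counts(rng, n_units=500, mean=100.0, dispersion=0.1):
    means = np.exp(rng.normal(np.log(mean), 0.7, size=n_units))
    return pd.DataFrame({s: nb(rng, means, dispersion, n_units) for s in COND.index})


class TestDispersions:
    def test_identical_counts_hit_the_floor(self):
        counts = pd.DataFrame({s: [50, 80, 10] for s in COND.index})
        disp = estimate_dispersions(counts, COND, shrink_weight=0.0)
        assert np.allclose(disp, 1e-8)

    def test_poisson_counts_give_near_zero_dispersion(self, rng):
        counts = pd.DataFrame(
            {s: rng.poisson(200.0, size=500) for s in COND.index}
        )
        disp = estimate_dispersions(counts, COND)
        assert np.median(disp) < 0.02

    def test_common_dispersion_recovered_within_fifty_percent(self, rng):
        truth = 0.2
        counts = pd.DataFrame(
            {s: nb(rng, np.full(500, 300.0), truth, 500) for s in COND.index}
        )
        disp = estimate_dispersions(counts, COND, shrink_weight=1.0)
        common = float(disp.iloc[0])
        assert 0.5 * truth < common < 1.5 * truth

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame({"wt1": [1], "t1": [2]})
        with pytest.raises(ValueError):
            estimate_dispersions(counts, pd.Series({"wt1": "WT", "t1": "TCL1"}))


class TestDeTest:
    def test_identical_groups_give_null_result(self):
        counts = pd.DataFrame(
            {"wt1": [100, 7], "wt2": [50, 9], "t1": [100, 7], "t2": [50, 9]}
        )
        res = de_test(counts, COND)
        assert np.allclose(res["log2_fc"], 0.0)
        assert (res["p_value"] > 0.9).all()
        assert (res["status"] == "unchanged").all()

    def test_label_swap_negates_every_log_fc(self, rng):
        counts = null_counts(rng, n_units=200)
        res = de_test(counts, COND)
        swapped = COND.map({"WT": "TCL1", "TCL1": "WT"})
        res_swapped = de_test(counts, swapped)
        np.testing.assert_allclose(
            res["log2_fc"].to_numpy(), -res_swapped["log2_fc"].to_numpy(), atol=1e-12
        )
        np.testing.assert_allclose(
            res["p_value"].to_numpy(), res_swapped["p_value"].to_numpy(), atol=1e-12
        )

    def test_all_zero_units_excluded(self):
        counts = pd.DataFrame(
            {"wt1": [10, 0], "wt2": [12, 0], "t1": [9, 0], "t2": [11, 0]}
        )
        res = de_test(counts, COND)
        assert len(res) == 1

    def test_fdr_bounds_and_monotonicity(self, rng):
        counts = null_counts(rng, n_units=300)
        res = de_test(counts, COND).sort_values("p_value")
        assert (res["fdr"] >= res["p_value"] - 1e-12).all()
        assert (res["fdr"] <= 1.0).all()


class TestDtuTest:
    def _gene_counts(self, rng, shift=None, n_genes=30, mean=400.0):
        """Two-TSS genes; ``shift`` multiplies TSS b in the TCL1 samples."""
        rows, genes = [], {}
        for g in range(n_genes):
            for tss in ("a", "b"):
                unit = f"g{g}_{tss}"
                genes[unit] = f"g{g}"
                mult = shift if (shift and tss == "b") else 1.0
                rows.append(
                    {
                        "wt1": nb(rng, mean, 0.05, 1)[0],
                        "wt2": nb(rng, mean, 0.05, 1)[0],
                        "t1": nb(rng, mean * mult, 0.05, 1)[0],
                        "t2": nb(rng, mean * mult, 0.05, 1)[0],
                    }
                )
        counts = pd.DataFrame(rows, index=list(genes))
        return counts, pd.Series(genes)

    def test_shared_condition_factor_gives_zero_shift(self, rng):
        counts, genes = self._gene_counts(rng, n_genes=10)
        doubled = counts.copy()
        doubled[["t1", "t2"]] = (doubled[["t1", "t2"]] * 4).astype(int)
        res = dtu_test(doubled, genes, COND)
        # both TSSs move 2 log2 units together: no differential usage
        # (residual shifts are sampling noise, well below the planted scale)
        assert res["atss_log2_fc"].abs().max() < 1.0
        assert (res["fdr"] > 0.05).all()

    def test_planted_usage_shift_detected_with_direction(self, rng):
        counts, genes = self._gene_counts(rng, shift=9.0, n_genes=20)
        res = dtu_test(counts, genes, COND)
        planted = res[res["cluster_id"].str.endswith("_b")]
        sig = planted[planted["fdr"] < 0.05]
        assert len(sig) >= 0.9 * len(planted)
        assert (sig["direction"] == "up").all()

    def test_single_tss_genes_skipped(self, rng):
        counts = pd.DataFrame(
            {"wt1": [10], "wt2": [12], "t1": [9], "t2": [11]}, index=["g0_a"]
        )
        res = dtu_test(counts, pd.Series({"g0_a": "g0"}), COND)
        assert len(res) == 0


class TestSamplePca:
    def test_single_axis_of_variation_on_pc1(self):
        base = np.ones((4, 6))
        t = np.array([0.0, 1.0, 2.0, 3.0])[:, None]
        direction = np.array([[1.0, -1, 0.5, 0, 2, -0.5]])
        mat = pd.DataFrame(base + t * direction)
        coords, var = sample_pca(mat, log_transform=False)
        assert var.iloc[0] == pytest.approx(1.0)

    def test_variance_fractions_non_increasing_and_sum_to_one(self, rng):
        mat = pd.DataFrame(rng.normal(size=(5, 8)))
        _, var = sample_pca(mat, log_transform=False)
        assert np.all(np.diff(var.to_numpy()) <= 1e-12)
        assert var.sum() == pytest.approx(1.0)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        mat = pd.DataFrame(rng.normal(size=(4, 6)))
        coords, var = sample_pca(mat, log_transform=False)
        X = mat.to_numpy() - mat.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        evals = evals[::-1]
        evecs = evecs[:, ::-1]
        np.testing.assert_allclose(
            var.to_numpy(), (evals / evals.sum())[: len(var)], atol=1e-9
        )
        oracle = X @ evecs[:, : coords.shape[1]]
        # eigenvector sign is arbitrary: compare per-component magnitudes
        np.testing.assert_allclose(
            np.abs(coords.to_numpy()), np.abs(oracle), atol=1e-8
        )

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sample_pca(pd.DataFrame(np.ones((4, 5))), log_transform=False)


class TestSizeFactors:
    def test_equal_libraries_give_unit_factors(self):
        counts = pd.DataFrame({s: [10, 20, 30] for s in COND.index})
        np.testing.assert_allclose(size_factors(counts), 1.0)

    def test_doubled_library_detected(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)
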