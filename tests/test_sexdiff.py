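import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sexcov import SimConfig, ValidationError, simulate_cohort
from sexcov.qc import ResidualTable, residualize_age
from sexcov.sexdiff import (compare_mean_correlations, edge_vector,
                            empirical_pvalues, exhaustive_null, fdr_bh,
                            permutation_null, run_sexdiff,
                            sex_correlation_matrices, sexdiff_matrix,
                            strength_vs_difference)

from conftest import make_cohort


def _residuals(cols: dict, sex: list[str]) -> ResidualTable:
    df = pd.DataFrame(cols)
    df.index = [f"s{i}" for i in range(len(df))]
    s = pd.Series(sex, index=df.index)
    return ResidualTable(residuals=df, sex=s,
                         age=pd.Series(np.zeros(len(df)), index=df.index))


class TestCorrelationMatrices:
    def test_duplicated_region_perfect_correlation(self):
        x = [1.0, 2.0, 4.0, 1.5, 2.5, 3.5]
        res = _residuals({"a": x, "b": x, "c": [0.0, 1.0, -1.0, 2.0, 0.5, -0.5]},
                         ["female"] * 3 + ["male"] * 3)
        rf, rm = sex_correlation_matrices(res)
        assert rf.loc["a", "b"] == pytest.approx(1.0)
        assert rm.loc["a", "b"] == pytest.approx(1.0)

    def test_negated_region_anticorrelation(self):
        x = np.array([1.0, 2.0, 4.0, 1.5, 2.5, 3.5])
        res = _residuals({"a": x, "b": -x}, ["female"] * 3 + ["male"] * 3)
        rf, rm = sex_correlation_matrices(res)
        assert rf.loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_pearson_value(self):
        res = _residuals({"x": [1.0, 2.0, 3.0, 0.0, 1.0, 2.0],
                          "y": [1.0, 2.0, 4.0, 0.0, -1.0, 1.0]},
                         ["female"] * 3 + ["male"] * 3)
        rf, _ = sex_correlation_matrices(res)
        assert rf.loc["x", "y"] == pytest.approx(0.981981, abs=1e-5)

    def test_zero_variance_region_named(self):
        res = _residuals({"a": [1.0] * 6, "b": [0, 1, 2, 3, 4, 5.0]},
                         ["female"] * 3 + ["male"] * 3)
        with pytest.raises(ValidationError, match="a"):
            sex_correlation_matrices(res)


class TestDifferenceMatrix:
    def test_identical_groups_zero(self):
        r = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        d = sexdiff_matrix(r, r)
        assert (d.to_numpy() == 0).all()

    def test_direct_subtraction_male_minus_female(self):
        idx = ["a", "b"]
        rf = pd.DataFrame([[1.0, 0.8], [0.8, 1.0]], index=idx, columns=idx)
        rm = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=idx, columns=idx)
        d = sexdiff_matrix(rf, rm, "male_minus_female")
        assert d.loc["a", "b"] == pytest.approx(-0.3)
        d2 = sexdiff_matrix(rf, rm, "female_minus_male")
        assert d2.loc["a", "b"] == pytest.approx(0.3)

    def test_swapping_sexes_negates(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 4))
        r1 = pd.DataFrame((m + m.T) / 8, index=list("abcd"), columns=list("abcd"))
        r2 = r1 * 0.5
        d = sexdiff_matrix(r1, r2)
        d_swapped = sexdiff_matrix(r2, r1)
        np.testing.assert_array_equal(d.to_numpy(), -d_swapped.to_numpy())

    def test_shape_mismatch(self):
        r3 = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        r2 = pd.DataFrame(np.eye(2), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValidationError):
            sexdiff_matrix(r3, r2)


class TestEmpiricalP:
    def test_zero_observed_gives_one(self):
        null = np.random.default_rng(0).normal(size=(99, 3))
        p = empirical_pvalues(np.zeros(3), null)
        np.testing.assert_array_equal(p, 1.0)

    def test_floor_of_estimator(self):
        null = np.random.default_rng(0).normal(size=(999, 2))
        obs = np.abs(null).max(axis=0) + 1.0
        p = empirical_pvalues(obs, null)
        np.testing.assert_allclose(p, 1.0 / 1000)

    def test_direct_count(self):
        null = np.array([[-0.2], [0.1], [0.3]])
        p = empirical_pvalues(np.array([0.25]), null)
        assert p[0] == pytest.approx((1 + 1) / 4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(1, 200), st.integers(0, 2**31 - 1))
    def test_bounds_property(self, n_perm, seed):
        rng = np.random.default_rng(seed)
        null = rng.normal(size=(n_perm, 4))
        p = empirical_pvalues(rng.normal(size=4), null)
        assert (p >= 1.0 / (n_perm + 1)).all()
        assert (p <= 1.0).all()


class TestFdrBH:
    def test_hand_example(self):
        q, sig = fdr_bh(np.array([0.01, 0.02, 0.03]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])
        assert sig.all()

    def test_all_ones(self):
        q, sig = fdr_bh(np.ones(10))
        assert not sig.any()

    def test_single_p_identity(self):
        q, sig = fdr_bh(np.array([0.04]))
        assert q[0] == pytest.approx(0.04)
        assert sig[0]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            fdr_bh(np.array([0.5, 1.2]))


class TestPermutationNull:
    def test_determinism(self, null_cohort):
        cohort = null_cohort[0]
        n1 = permutation_null(cohort, 10, seed=3)
        n2 = permutation_null(cohort, 10, seed=3)
        np.testing.assert_array_equal(n1, n2)

    def test_mirror_cohort_null_symmetric(self):
        """Female and male data are copies: the null D is symmetric
        about zero per edge."""
        rng = np.random.default_rng(4)
        half = rng.normal(100, 10, (20, 4))
        vol = np.vstack([half, half])
        age = np.concatenate([np.linspace(50, 90, 20)] * 2)
        cohort = make_cohort(vol, ["female"] * 20 + ["male"] * 20, age=age)
        null = permutation_null(cohort, 300, seed=0)
        assert np.abs(null.mean(axis=0)).max() < 0.05

    def test_fast_mode_close_to_full_on_null_data(self, null_cohort):
        cohort = null_cohort[0]
        full = permutation_null(cohort, 200, seed=1, mode="full")
        fast = permutation_null(cohort, 200, seed=1, mode="fast")
        # same seeds, same label draws; residualization differs only in the
        # group age fits, so the null distributions agree closely
        assert abs(full.std() - fast.std()) < 0.02

    def test_exhaustive_oracle_matches_monte_carlo(self):
        """3F/3M cohort: p from all C(6,3)=20 assignments vs 10,000 random
        permutations, per edge within binomial sampling error."""
        rng = np.random.default_rng(8)
        vol = rng.normal(100, 10, (6, 4))
        age = np.array([55.0, 60, 70, 56, 63, 75])
        cohort = make_cohort(vol, ["female"] * 3 + ["male"] * 3, age=age)

        from sexcov.qc import residualize_age as ra
        from sexcov.sexdiff import sex_correlation_matrices as scm

        res = ra(cohort)
        rf, rm = scm(res)
        obs = edge_vector(sexdiff_matrix(rf, rm))

        ex = exhaustive_null(cohort)
        assert ex.shape[0] == 20
        p_ex = (np.abs(ex) >= np.abs(obs)[None, :]).mean(axis=0)
        mc = permutation_null(cohort, 10_000, seed=0)
        p_mc = empirical_pvalues(obs, mc)
        tol = 4 * np.sqrt(p_ex * (1 - p_ex) / 10_000) + 2e-4
        assert (np.abs(p_mc - p_ex) <= tol).all()

    def test_nperm_zero_rejected(self, null_cohort):
        with pytest.raises(ValidationError):
            permutation_null(null_cohort[0], 0)


class TestRunSexdiff:
    def test_label_swap_antisymmetry_bit_exact(self, null_cohort):
        cohort = null_cohort[0]
        swapped = cohort.copy()
        swapped.subjects["sex"] = np.where(
            cohort.sex == "female", "male", "female")
        a = run_sexdiff(cohort, n_perm=50, seed=2)
        b = run_sexdiff(swapped, n_perm=50, seed=2)
        np.testing.assert_array_equal(a.edges["D"].to_numpy(),
                                      -b.edges["D"].to_numpy())
        np.testing.assert_array_equal(a.edges["p_perm"].to_numpy(),
                                      b.edges["p_perm"].to_numpy())
        np.testing.assert_array_equal(a.edges["q"].to_numpy(),
                                      b.edges["q"].to_numpy())

    def test_planted_edge_found(self, planted_cohort):
        cohort, _, truth = planted_cohort
        result = run_sexdiff(cohort, n_perm=500, seed=1)
        a, b, delta = truth.true_sexdiff_edges[0]
        row = result.edges[(result.edges["region_i"] == a)
                           & (result.edges["region_j"] == b)].iloc[0]
        # delta is female-minus-male; default convention is male-minus-female;
        # tolerance covers ~2 sampling SDs of a correlation difference at
        # n=150/sex
        assert row["D"] == pytest.approx(-delta, abs=0.25)
        assert row["p_perm"] == pytest.approx(1 / 501)

    def test_power_nondecreasing_in_delta(self):
        """Recovery power of a planted edge grows with the planted
        difference."""
        pvals = []
        for delta in (0.2, 0.4, 0.6):
            ps = []
            for rep in range(5):
                cfg = SimConfig(n_female=100, n_male=100, p=6,
                                base_correlation=0.2,
                                planted_edges=[(0, 1, delta)],
                                seed=700 + rep)
                cohort, _, _ = simulate_cohort(cfg)
                r = run_sexdiff(cohort, n_perm=200, seed=rep)
                ps.append(r.edges["p_perm"].iloc[0])
            pvals.append(np.mean(ps))
        assert pvals[0] >= pvals[1] >= pvals[2]


class TestMeanComparison:
    def _mats(self, rf_val, rm_val, p=4):
        idx = [f"r{i}" for i in range(p)]
        rf = pd.DataFrame(np.full((p, p), rf_val), index=idx, columns=idx)
        rm = pd.DataFrame(np.full((p, p), rm_val), index=idx, columns=idx)
        np.fill_diagonal(rf.values, 1.0)
        np.fill_diagonal(rm.values, 1.0)
        return rf, rm

    def test_identical_matrices_degenerate_zero(self):
        rf, rm = self._mats(0.3, 0.3)
        mc = compare_mean_correlations(rf, rm)
        assert mc.delta == 0.0
        assert mc.degenerate

    def test_constant_differences_degenerate(self):
        rf, rm = self._mats(0.2, 0.3)
        mc = compare_mean_correlations(rf, rm)
        assert mc.delta == pytest.approx(0.1)
        assert mc.ci_low == mc.ci_high == pytest.approx(0.1)
        assert mc.degenerate

    def test_planted_uniform_shift_recovered(self):
        cfg = SimConfig(n_female=500, n_male=500, p=8, base_correlation=0.35,
                        planted_edges=[(i, j, 0.3) for i in range(8)
                                       for j in range(i + 1, 8)], seed=13)
        cohort, _, _ = simulate_cohort(cfg)
        res = residualize_age(cohort)
        rf, rm = sex_correlation_matrices(res)
        mc = compare_mean_correlations(rf, rm,
                                       sign_convention="female_minus_male")
        assert mc.delta == pytest.approx(0.3, abs=0.05)
        assert mc.ci_low <= mc.delta <= mc.ci_high

    def test_too_few_edges(self):
        rf, rm = self._mats(0.2, 0.3, p=2)
        with pytest.raises(ValidationError):
            compare_mean_correlations(rf, rm, edge_mask=np.array([False]))


class TestStrengthVsDifference:
    def _inputs(self, seed=0, p=10):
        cfg = SimConfig(n_female=80, n_male=80, p=p, base_correlation=0.3,
                        seed=seed)
        cohort, _, _ = simulate_cohort(cfg)
        res = residualize_age(cohort)
        rf, rm = sex_correlation_matrices(res)
        d = edge_vector(sexdiff_matrix(rf, rm))
        null = permutation_null(cohort, 99, seed=seed)
        pv = empirical_pvalues(d, null)
        return rf, rm, d, pv

    def test_vacuous_threshold_uses_all_edges(self):
        rf, rm, d, pv = self._inputs()
        t = strength_vs_difference(rf, rm, d, pv, [1.0])
        assert t["n_edges"].iloc[0] == len(d)

    def test_nested_thresholds_nonincreasing_counts(self):
        rf, rm, d, pv = self._inputs(seed=2)
        t = strength_vs_difference(rf, rm, d, pv, [1.0, 0.5, 0.05])
        counts = t["n_edges"].to_numpy()
        assert (np.diff(counts) <= 0).all()

    def test_tiny_threshold_undefined_not_error(self):
        rf, rm, d, pv = self._inputs(seed=3)
        t = strength_vs_difference(rf, rm, d, np.ones_like(pv), [0.001])
        assert t["n_edges"].iloc[0] == 0
        assert np.isnan(t["strength_absdiff_r"].iloc[0])

    def test_bounded_correlation_geometry_gives_negative_relation(self):
        """Edges with weaker within-sex correlation show larger observed
        sex differences: planting a fixed difference across a grid of
        baseline strengths yields a negative strength-vs-|D| relation."""
        from sexcov.synth import simulate_bounded_pairs

        t = simulate_bounded_pairs([0.0, 0.2, 0.4, 0.6, 0.8], 0.2,
                                   150, 300, seed=9)
        r = np.corrcoef(t["mean_within_sex_r"], t["mean_abs_diff"])[0, 1]
        assert r < 0
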