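import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surrqa import (
    compare_distributions,
    compare_proportions,
    correlate_meanNN,
    generate_set,
    mc_pvalue,
    proportion_ci,
    rejection_rates,
    surrogate_test,
)
from surrqa.testing import TestResult
from ._rqa_oracle import brute_mc_pvalue


class TestMcPvalue:
    def test_original_outside_range_hits_floor(self, rng):
        surr = rng.normal(0, 1, size=99)
        assert mc_pvalue(surr.max() + 10, surr) == pytest.approx(0.01)
        assert mc_pvalue(surr.min() - 10, surr) == pytest.approx(0.01)

    def test_original_at_median_central(self, rng):
        surr = np.arange(99.0)
        assert mc_pvalue(49.0, surr) == pytest.approx(0.5, abs=0.02)

    def test_tie_counting_matches_enumeration(self):
        surr = [1.0] * 4 + list(np.linspace(2, 50, 95))
        # original tied with 4 surrogates in the lower tail, none beyond
        assert mc_pvalue(1.0, np.array(surr)) == pytest.approx((1 + 4) / 100)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_permutation_invariant(self, seed):
        r = np.random.default_rng(seed)
        surr = np.round(r.normal(size=39), 1)  # coarse grid provokes ties
        orig = float(np.round(r.normal(), 1))
        p = mc_pvalue(orig, surr)
        assert p == pytest.approx(brute_mc_pvalue(orig, list(surr)))
        assert p == pytest.approx(mc_pvalue(orig, r.permutation(surr)))
        assert p >= 1 / 40

    def test_reject_iff_below_alpha(self, ar2s_series):
        sset = generate_set(ar2s_series, method="IAAFT", n_surr=19, seed=0)
        for r in surrogate_test(ar2s_series, sset, m=5, tau=3, indices=["det", "lam"]):
            assert r.reject == (r.p_value < 0.05)
            assert r.p_value >= 1 / 20


class TestSurrogateTestMechanics:
    def test_custom_profile_fn_and_floor(self, ar2s_series):
        # statistic = lag-1 autocorrelation; IAAFT preserves it, so no rejection
        def prof(values):
            z = values - values.mean()
            return {"ac1": float(z[1:] @ z[:-1] / (z @ z))}

        sset = generate_set(ar2s_series, method="IAAFT", n_surr=39, seed=1)
        (res,) = surrogate_test(ar2s_series, sset, m=1, tau=1,
                                indices=["ac1"], profile_fn=prof)
        assert not res.reject

    def test_custom_statistic_with_power(self, ar2s_series):
        # statistic = time of the largest absolute value: surrogates scramble it
        def prof(values):
            return {"argmax": float(np.argmax(np.abs(values)))}

        sset = generate_set(ar2s_series, method="IAAFT", n_surr=39, seed=1)
        (res,) = surrogate_test(ar2s_series, sset, m=1, tau=1,
                                indices=["argmax"], profile_fn=prof)
        assert 0 < res.p_value <= 1

    def test_sentinel_statistic_excluded(self, ar2s_series):
        def prof(values):
            return {"bad": float("nan")}

        sset = generate_set(ar2s_series, method="IAAFT", n_surr=19, seed=2)
        (res,) = surrogate_test(ar2s_series, sset, m=1, tau=1,
                                indices=["bad"], profile_fn=prof)
        assert not res.tested and not res.reject


class TestRejectionRates:
    @staticmethod
    def _results(rejects):
        return [[TestResult("det", 0.5, np.empty(0), 0.01 if r else 0.5, r)]
                for r in rejects]

    def test_zero_rejections(self):
        out = rejection_rates({"g": self._results([False] * 29)})
        (s,) = out
        assert s.pct == 0.0 and s.ci_low == 0.0 and s.n_series == 29

    def test_full_rejections(self):
        (s,) = rejection_rates({"g": self._results([True] * 29)})
        assert s.pct == 100.0 and s.ci_high == 100.0

    def test_printed_table_cell_26_of_40(self):
        (s,) = rejection_rates({"g": self._results([True] * 26 + [False] * 14)})
        assert s.pct == pytest.approx(65.0)
        assert s.ci_low == pytest.approx(49.6, abs=0.05)
        assert s.ci_high == pytest.approx(78.3, abs=0.05)

    def test_empty_group_warns(self):
        with pytest.warns(UserWarning):
            assert rejection_rates({"g": []}) == []


class TestProportionCi:
    def test_wilson_alternative(self):
        lo, hi = proportion_ci(26, 40, method="wilson")
        assert 0.4 < lo < 0.65 < hi < 0.85

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            proportion_ci(5, 4)


class TestCompareProportions:
    def test_identical_proportions_p_one(self):
        assert compare_proportions(10, 20, 10, 20) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        from scipy import stats

        # table (1,9 / 11,3): enumerate the hypergeometric tail directly
        p_mine = compare_proportions(1, 10, 11, 14)
        rv = stats.hypergeom(24, 12, 10)  # N, K (first col total), n (row a total)
        probs = np.array([rv.pmf(k) for k in range(13)])
        p_exact = probs[probs <= rv.pmf(1) * (1 + 1e-9)].sum()
        assert p_mine == pytest.approx(p_exact, rel=1e-6)

    def test_bonferroni_multiplies_and_caps(self):
        p1 = compare_proportions(2, 10, 8, 10)
        p5 = compare_proportions(2, 10, 8, 10, n_comparisons=5)
        assert p5 == pytest.approx(min(1.0, p1 * 5))
        assert compare_proportions(10, 20, 10, 20, n_comparisons=5) == 1.0


class TestCorrelateMeanNN:
    def test_monotone_and_antimonotone(self):
        mean_nn = [0.6, 0.7, 0.8, 0.9, 1.0]
        profiles = [{"det": v, "lam": -v} for v in (1, 2, 3, 4, 5)]
        out = correlate_meanNN(mean_nn, profiles, indices=["det", "lam"])
        assert out["det"][0] == pytest.approx(1.0)
        assert out["lam"][0] == pytest.approx(-1.0)

    def test_single_swap_matches_rank_formula(self):
        mean_nn = [1, 2, 3, 4, 5]
        vals = [1, 2, 4, 3, 5]  # one adjacent swap: rho = 1 - 6*2/(5*24) = 0.9
        out = correlate_meanNN(mean_nn, [{"det": v} for v in vals], indices=["det"])
        assert out["det"][0] == pytest.approx(0.9)

    def test_constant_column_sentinel(self):
        out = correlate_meanNN([1, 2, 3, 4, 5], [{"det": 1.0}] * 5, indices=["det"])
        assert np.isnan(out["det"][0])

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            correlate_meanNN([1, 2], [{"det": 1}, {"det": 2}])


class TestCompareDistributions:
    def test_identical_groups_p_near_one(self):
        a = list(range(10))
        out = compare_distributions(a, a)
        assert out["p"] > 0.9

    def test_separated_groups_match_exact_enumeration(self):
        from scipy import stats

        a, b = list(range(1, 11)), list(range(11, 21))
        out = compare_distributions(a, b)
        p_exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert out["p"] == pytest.approx(p_exact)
        assert out["median_a"] < out["median_b"]
        assert out["ci_a"][0] <= out["median_a"] <= out["ci_a"][1]

    def test_small_group_errors(self):
        with pytest.raises(ValueError):
            compare_distributions([1, 2], [1, 2, 3])
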