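"""Linear, mixed-effects and ANCOVA association models; BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clrbalance.association import (adjust_by_family, ancova_first_last,
                                    bh_adjust, fit_cross_sectional,
                                    fit_cross_sectional_continuous,
                                    fit_longitudinal, one_vs_rest)
from clrbalance.synthetic_data import simulate_longitudinal_feature


def bh_textbook(p):
    """Step-up BH oracle straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_ in range(m, 0, -1):
        i = order[rank_ - 1]
        running = min(running, p[i] * m / rank_)
        adj[i] = running
    return adj


class TestCrossSectional:
    def test_identical_groups_zero_coefficient(self):
        f = pd.DataFrame({"x": [1.0, 2.0, 1.0, 2.0]})
        res = fit_cross_sectional(f, [0, 0, 1, 1])
        assert res["coefficient"][0] == pytest.approx(0.0)

    def test_matches_two_sample_t_test(self, rng):
        f = pd.DataFrame(rng.normal(size=(30, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = np.repeat([0, 1], 15)
        res = fit_cross_sectional(f, y)
        for j, col in enumerate(f.columns):
            t, p = stats.ttest_ind(f[col][y == 1], f[col][y == 0])
            assert res["p_value"][j] == pytest.approx(p, abs=1e-10)
            assert res["coefficient"][j] == pytest.approx(
                f[col][y == 1].mean() - f[col][y == 0].mean(), abs=1e-12)

    def test_planted_shift_recovered(self, rng):
        # delta=1.0, n=20+20, sigma=0.5: mean estimate within +/-0.15
        est = []
        y = np.repeat([0, 1], 20)
        for _ in range(200):
            f = pd.DataFrame({"x": rng.normal(0, 0.5, 40) + y * 1.0})
            est.append(fit_cross_sectional(f, y)["coefficient"][0])
        assert np.mean(est) == pytest.approx(1.0, abs=0.15)

    def test_constant_feature_flagged(self):
        f = pd.DataFrame({"x": [3.0] * 8})
        res = fit_cross_sectional(f, [0] * 4 + [1] * 4)
        assert res["flag"][0] == "degenerate"
        assert res["p_value"][0] == 1.0 and res["coefficient"][0] == 0.0

    def test_continuous_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        f = pd.DataFrame(rng.normal(size=(25, 3)), columns=list("abc"))
        y = rng.normal(size=25)
        res = fit_cross_sectional_continuous(f, y)
        for j, col in enumerate(f.columns):
            fit = sm.OLS(f[col].to_numpy(), sm.add_constant(y)).fit()
            assert res["coefficient"][j] == pytest.approx(fit.params[1], abs=1e-10)
            assert res["p_value"][j] == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestLongitudinal:
    def test_constant_outcome_flagged_without_estimate(self):
        f = pd.DataFrame({"x": np.arange(6.0)})
        res = fit_longitudinal(f, np.ones(6), ["a", "a", "b", "b", "c", "c"])
        assert res["flag"][0] == "constant_outcome"
        assert np.isnan(res["p_value"][0])

    def test_single_observation_per_subject_equals_ols(self):
        import statsmodels.api as sm
        feat, x, subj = simulate_longitudinal_feature(40, 1, 0.3, 1.0, 0.5,
                                                      seed=5)
        res = fit_longitudinal(pd.DataFrame({"f": feat}), x, subj)
        ols = sm.OLS(feat, sm.add_constant(x)).fit()
        assert res["coefficient"][0] == pytest.approx(ols.params[1], abs=1e-6)

    def test_slope_estimator_consistency(self):
        # estimation error shrinks from n=20 to n=200 subjects (50 sims
        # each); RMSE rather than mean error, which for this unbiased
        # estimator is Monte-Carlo noise at 50 simulations
        rmse = {}
        for n in (20, 200):
            est = []
            for rep in range(50):
                feat, x, subj = simulate_longitudinal_feature(
                    n, 3, 0.3, 1.0, 0.5, seed=1000 * n + rep)
                r = fit_longitudinal(pd.DataFrame({"f": feat}), x, subj)
                est.append(r["coefficient"][0])
            rmse[n] = float(np.sqrt(np.mean((np.array(est) - 0.3) ** 2)))
        assert rmse[200] < rmse[20]

    def test_degenerate_feature_flagged(self):
        f = pd.DataFrame({"x": [2.0] * 6})
        res = fit_longitudinal(f, np.arange(6.0), ["a", "a", "b", "b", "c", "c"])
        assert res["flag"][0] == "degenerate" and res["p_value"][0] == 1.0


class TestBH:
    @pytest.mark.parametrize("p,expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.005, 0.5], [0.01, 0.5]),
        ([0.2], [0.2]),
    ])
    def test_known_adjustments(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_matches_textbook_oracle(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_array_equal(bh_adjust(p), bh_textbook(p))

    def test_matches_statsmodels_within_rounding(self, rng):
        from statsmodels.stats.multitest import multipletests
        p = rng.uniform(size=200)
        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_families_adjusted_separately(self):
        df = pd.DataFrame({
            "feature": list("abcd"), "feature_kind": ["taxon"] * 2 + ["metabolite"] * 2,
            "rank": [None] * 4, "outcome": ["o"] * 4,
            "metadata_group": ["g"] * 4, "model_kind": ["linear"] * 4,
            "coefficient": [0.0] * 4, "p_value": [0.01, 0.04, 0.02, 0.03],
            "fdr": [np.nan] * 4, "n": [10] * 4, "flag": [""] * 4})
        out = adjust_by_family(df)
        np.testing.assert_allclose(
            out.loc[out["feature_kind"] == "taxon", "fdr"], [0.02, 0.04])
        np.testing.assert_allclose(
            out.loc[out["feature_kind"] == "metabolite", "fdr"], [0.03, 0.03])

    def test_fdr_at_least_p_within_family(self, rng):
        p = rng.uniform(size=25)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestAncova:
    @staticmethod
    def _pairs(n_per_group, delta_shift, sigma, rng):
        n = 2 * n_per_group
        g = np.repeat([0, 1], n_per_group)
        first = rng.normal(size=n)
        last = first + rng.normal(0, sigma, n) + delta_shift * g
        feats = pd.DataFrame({"x": np.concatenate([first, last])},
                             index=[f"f{i}" for i in range(n)]
                                   + [f"l{i}" for i in range(n)])
        return feats, g, [f"f{i}" for i in range(n)], [f"l{i}" for i in range(n)]

    def test_identical_deltas_zero_group_effect(self, rng):
        feats, g, fids, lids = self._pairs(6, 0.0, 0.0, rng)
        res = ancova_first_last(feats, g, fids, lids)
        assert res["coefficient"][0] == pytest.approx(0.0, abs=1e-10)

    def test_power_on_planted_delta_shift(self, rng):
        # delta-shift 1.0, n=13+13, sigma=0.5: detected at p<0.05 in >=90%
        hits = 0
        for _ in range(200):
            feats, g, fids, lids = self._pairs(13, 1.0, 0.5, rng)
            res = ancova_first_last(feats, g, fids, lids)
            hits += res["p_value"][0] < 0.05
        assert hits >= 180

    def test_baseline_covariate_mild_when_balanced(self, rng):
        import statsmodels.api as sm
        diffs = []
        for _ in range(100):
            feats, g, fids, lids = self._pairs(13, 1.0, 0.5, rng)
            res = ancova_first_last(feats, g, fids, lids)
            delta = (feats.loc[lids, "x"].to_numpy()
                     - feats.loc[fids, "x"].to_numpy())
            no_cov = sm.OLS(delta, sm.add_constant(g.astype(float))).fit()
            diffs.append(abs(res["coefficient"][0] - no_cov.params[1]))
        assert np.mean(diffs) < 0.1

    def test_small_group_skipped_with_warning(self, rng):
        feats, g, fids, lids = self._pairs(4, 0.0, 0.1, rng)
        g = np.array([0, 0, 0, 0, 0, 0, 0, 1])
        with pytest.warns(UserWarning, match="fewer than 2"):
            res = ancova_first_last(feats, g, fids, lids)
        assert res.empty


class TestOneVsRest:
    def test_small_category_excluded(self):
        cats = ["A"] * 16 + ["B"] * 13 + ["C"] * 12 + ["D"] * 3
        out = one_vs_rest(cats, min_size=5)
        assert set(out) == {"A", "B", "C"}

    def test_single_category_empty(self):
        assert one_vs_rest(["A"] * 10) == {}

    def test_indicators_sum_to_category_counts(self):
        cats = ["A"] * 7 + ["B"] * 6
        out = one_vs_rest(cats, min_size=5)
        assert out["A"].sum() == 7 and out["B"].sum() == 6
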