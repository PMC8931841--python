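"""Theil-Sen fitting, detrending and the per-season change tests."""

import numpy as np
import pytest
from scipy import stats

import trendshift as ts
from trendshift.exceptions import DegenerateInputError, InsufficientDataError
from trendshift.trend_tests import dense_season_test, detrend_baseline, sparse_season_test

from conftest import make_series


def brute_force_theil_sen(t, y):
    slopes = [(y[j] - y[i]) / (t[j] - t[i])
              for i in range(len(t)) for j in range(i + 1, len(t)) if t[j] != t[i]]
    slope = np.median(slopes)
    return slope, np.median(np.asarray(y) - slope * np.asarray(t))


class TestTheilSen:
    def test_exact_line(self):
        t = np.arange(10.0)
        fit = ts.theil_sen_fit(t, 2 * t + 1)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-12)

    def test_median_of_pairwise_slopes(self):
        # pairwise slopes {1, 1, 1, 7/3, 9/2, 8} -> median (1 + 7/3)/2 = 13/6... no:
        # median of 6 values = mean of 3rd and 4th sorted = (1 + 7/3)/2 = 5/3?
        # sorted: 1, 1, 1, 7/3, 9/2, 8 -> median = (1 + 7/3)/2 = 13/6 exactly.
        fit = ts.theil_sen_fit([0, 1, 2, 3], [0, 1, 2, 10])
        assert fit.slope == pytest.approx(13 / 6)

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ts.theil_sen_fit([1.0], [2.0])

    def test_constant_time_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ts.theil_sen_fit([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])

    @pytest.mark.parametrize("trial", range(30))
    def test_matches_all_pairs_oracle(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(3, 51))
        t = rng.uniform(0, 100, n)
        y = rng.normal(0, 10, n)
        fit = ts.theil_sen_fit(t, y)
        slope, intercept = brute_force_theil_sen(t, y)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    @pytest.mark.parametrize("trial", range(10))
    def test_slope_agrees_with_scipy(self, trial):
        rng = np.random.default_rng(100 + trial)
        t = np.arange(40.0)
        y = 0.5 * t + rng.normal(0, 3, 40)
        assert ts.theil_sen_fit(t, y).slope == pytest.approx(
            stats.theilslopes(y, t).slope)

    @pytest.mark.parametrize("trial", range(20))
    def test_more_outlier_resistant_than_ols(self, trial):
        rng = np.random.default_rng(200 + trial)
        t = np.arange(50.0)
        y = 1.5 * t + rng.normal(0, 1, 50)
        clean_ts = ts.theil_sen_fit(t, y).slope
        clean_ols = np.polyfit(t, y, 1)[0]
        y_out = y.copy()
        idx = rng.choice(50, 5, replace=False)
        y_out[idx] += rng.uniform(50, 200, 5)
        d_ts = abs(ts.theil_sen_fit(t, y_out).slope - clean_ts)
        d_ols = abs(np.polyfit(t, y_out, 1)[0] - clean_ols)
        assert d_ts < d_ols


class TestDetrendBaseline:
    def test_extrapolation_identity_on_line(self, epochs):
        n = 520
        t = np.arange(n)
        s = make_series(10 + 0.05 * t, start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        res = detrend_baseline(annot)
        np.testing.assert_allclose(res, 0.0, atol=1e-9)

    def test_post_shift_appears_in_residuals(self, epochs):
        n = 520
        t = np.arange(n)
        vals = 50 + 0.02 * t
        s0 = make_series(vals, start="2011-03-06")
        annot0 = ts.annotate(s0, epochs, branch="dense")
        vals = vals.copy()
        vals[annot0.epoch == "post"] -= 5
        annot = ts.annotate(s0.replace(vals), epochs, branch="dense")
        res = detrend_baseline(annot)
        assert np.allclose(res[annot.epoch == "post"], -5, atol=1e-9)
        assert np.allclose(res[annot.epoch == "baseline"], 0, atol=1e-9)

    def test_slope_robust_to_single_outlier(self, epochs):
        t = np.arange(520.0)
        vals = 10 + 0.05 * t
        vals[100] += 500
        s = make_series(vals, start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        base = annot.epoch == "baseline"
        fit = ts.theil_sen_fit(t[base], np.asarray(s.values)[base])
        assert fit.slope == pytest.approx(0.05, abs=1e-6)

    def test_all_missing_baseline_degenerate(self, epochs):
        n = 520
        missing = np.arange(n) < 469
        s = make_series(np.ones(n) * 5, start="2011-03-06", missing=missing)
        annot = ts.annotate(s, epochs, branch="dense")
        with pytest.raises(DegenerateInputError):
            detrend_baseline(annot)


class TestDenseSeasonTest:
    def test_constant_residuals_null_identity(self, epochs):
        s = make_series(np.full(520, 30.0), start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        res = detrend_baseline(annot)
        r = dense_season_test(annot, res, "winter")
        assert r.effect == pytest.approx(0.0, abs=1e-9)
        assert r.p_two == pytest.approx(1.0)

    def test_simulated_reduction_detected(self):
        series, _ = ts.generate_series(
            ts.SyntheticSpec(seed=1, noise_sd=2.0, season_effects={"winter": 0.5}))
        annot = ts.annotate(ts.hampel_filter(series), branch="dense")
        results = ts.season_tests(annot)
        assert results["winter"].p_one_decrease < 0.05
        assert results["winter"].direction == "decrease"

    def test_simulated_increase_one_sided_insensitive(self):
        series, _ = ts.generate_series(
            ts.SyntheticSpec(seed=1, noise_sd=2.0, season_effects={"winter": 1.5}))
        annot = ts.annotate(ts.hampel_filter(series), branch="dense")
        r = ts.season_tests(annot)["winter"]
        assert r.p_two < 0.05
        assert r.p_one_decrease > 0.5
        assert r.direction == "increase"

    def test_one_two_sided_coherence(self):
        for seed in range(8):
            series, _ = ts.generate_series(ts.SyntheticSpec(seed=300 + seed))
            annot = ts.annotate(ts.hampel_filter(series), branch="dense")
            for r in ts.season_tests(annot).values():
                if r.effect < 0:
                    assert r.p_one_decrease < 0.5
                    assert r.p_one_decrease == pytest.approx(r.p_two / 2, rel=1e-6)
                elif r.effect > 0:
                    assert r.p_one_decrease == pytest.approx(1 - r.p_two / 2, rel=1e-6)

    def test_insufficient_baseline_clusters_raises(self, epochs):
        # two baseline years only -> spring has 2 clusters, fine; but restrict more
        s = make_series(np.full(520, 10.0), start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        res = detrend_baseline(annot)
        with pytest.raises(InsufficientDataError):
            dense_season_test(annot, res, "winter", min_baseline_clusters=20)


class TestSparseSeasonTest:
    def test_all_zero_post_spring_strong_decrease(self, epochs):
        series, _ = ts.generate_series(
            ts.SyntheticSpec(seed=3, baseline_level=10, noise_sd=1, seasonal_amplitude=0))
        annot0 = ts.annotate(series, epochs)
        vals = series.values.copy()
        vals[(annot0.epoch == "post") & (annot0.season_label == "spring")] = 0.0
        annot = ts.annotate(series.replace(vals), epochs, branch="sparse")
        r = sparse_season_test(annot)
        assert r["spring"].p_one_decrease < 0.01
        assert r["spring"].effect < 0

    def test_no_post_weeks_not_estimable(self, epochs):
        series, _ = ts.generate_series(ts.SyntheticSpec(seed=4))
        annot0 = ts.annotate(series, epochs)
        keep = annot0.epoch == "baseline"
        trimmed = ts.SearchSeries("x", "US", series.week_starts[keep],
                                  series.values[keep], series.missing_mask[keep])
        annot = ts.annotate(trimmed, epochs, branch="sparse")
        r = sparse_season_test(annot)
        assert all(not res.estimable for res in r.values())

    def test_null_with_zeros_roughly_uniform(self):
        """False-positive rate at alpha=.05 stays near nominal with 30% zeros."""
        hits = 0
        n_rep = 120
        for i in range(n_rep):
            series, _ = ts.generate_series(
                ts.SyntheticSpec(seed=700 + i, seasonal_amplitude=0, zero_prob=0.3))
            annot = ts.annotate(ts.hampel_filter(series),
                                branch=ts.classify_branch(series))
            assert annot.branch == "sparse"
            r = sparse_season_test(annot)
            hits += sum(r[s].p_two < 0.05 for s in ts.SEASON_ORDER)
        rate = hits / (4 * n_rep)
        assert 0.01 < rate < 0.10


class TestClassifyDirection:
    @pytest.mark.parametrize("p_two,p_one,expected", [
        (0.0004, 0.0002, "decrease"),
        (0.001, 0.99, "increase"),
        (0.5, 0.3, "none"),
        (0.04, 0.05, "increase"),   # one-sided not below alpha
        (0.06, 0.02, "decrease"),
    ])
    def test_rule(self, p_two, p_one, expected):
        r = ts.SeasonalChangeResult("t", "winter", p_two, p_one, -1.0, "dense")
        assert ts.classify_direction(r, alpha=0.05) == expected
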