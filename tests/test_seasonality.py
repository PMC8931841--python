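"""Annual profiles, AtM ratio, circular peak week and wavelet significance."""

import numpy as np
import pytest

import trendshift as ts
from trendshift.exceptions import DegenerateInputError, InputError, InsufficientDataError
from trendshift.seasonality import (amplitude_to_mean, annual_profile,
                                    circular_peak_week, wavelet_seasonality_p)

from conftest import make_series


def cosine_series(amplitude, level=50.0, noise_sd=0.0, seed=0, peak_week=2.0,
                  n_years=10):
    spec = ts.SyntheticSpec(n_years_baseline=n_years - 1, n_years_post=1,
                            baseline_level=level, seasonal_amplitude=amplitude,
                            noise_sd=noise_sd, peak_week=peak_week, seed=seed)
    series, _ = ts.generate_series(spec)
    return ts.annotate(series, branch="dense")


class TestAnnualProfile:
    def test_mean_of_identical_years(self):
        annot = cosine_series(10.0)
        profile, per_year = annual_profile(annot)
        assert len(profile) == 52
        assert len(per_year) >= 8
        first = list(per_year.values())[0]
        np.testing.assert_allclose(profile, first, atol=1e-9)

    def test_mean_of_two_levels(self, epochs):
        # two flat years at 10 and 20 -> profile constant 15
        vals = np.concatenate([np.full(52, 10.0), np.full(52, 20.0),
                               np.full(520 - 104, 15.0)])
        s = make_series(vals, start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        profile, per_year = annual_profile(annot)
        years = sorted(per_year)
        np.testing.assert_allclose(per_year[years[0]], 10.0)
        np.testing.assert_allclose(per_year[years[1]], 20.0)

    def test_insufficient_years_raises(self, epochs):
        s = make_series(np.full(60, 5.0), start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        with pytest.raises(InsufficientDataError):
            annual_profile(annot)


class TestAmplitudeToMean:
    def test_cosine_closed_form(self):
        w = np.arange(52)
        profile = 10 + 2 * np.cos(2 * np.pi * w / 52)
        atm, _ = amplitude_to_mean(profile)
        assert atm == pytest.approx(0.2, abs=0.01)

    def test_constant_profile_zero(self):
        atm, _ = amplitude_to_mean(np.full(52, 7.0))
        assert atm == 0.0

    def test_four_point_toy(self):
        atm, _ = amplitude_to_mean(np.array([8.0, 12.0, 10.0, 10.0]))
        assert atm == pytest.approx(0.2)

    def test_zero_mean_undefined(self):
        with pytest.raises(DegenerateInputError):
            amplitude_to_mean(np.zeros(52))

    @pytest.mark.parametrize("ratio", [0.1, 0.25, 0.5])
    def test_closed_form_within_one_percent(self, ratio):
        m = 40.0
        annot = cosine_series(amplitude=ratio * m, level=m)
        profile, per_year = annual_profile(annot)
        atm, atm_sd = amplitude_to_mean(profile, per_year)
        assert atm == pytest.approx(ratio, rel=0.01)


class TestCircularPeakWeek:
    def per_year(self, profiles):
        return {i: p for i, p in enumerate(profiles)}

    def test_point_mass_recovered(self):
        prof = np.zeros(52)
        prof[9] = 1.0  # week 10
        week, sd, defined = circular_peak_week(self.per_year([prof, prof]))
        assert defined
        assert week == pytest.approx(10.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_wraparound_mean_of_51_and_3(self):
        prof = np.zeros(52)
        prof[50] = 1.0  # week 51
        prof[2] = 1.0   # week 3
        week, _, defined = circular_peak_week(self.per_year([prof]))
        assert defined
        # circular distance to week 1 (a float hair below 53 is the same point)
        assert min(abs(week - 1.0), 52 - abs(week - 1.0)) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_profile_undefined(self):
        week, sd, defined = circular_peak_week(self.per_year([np.ones(52)]))
        assert not defined

    @pytest.mark.parametrize("shift", [5, 17, 30])
    def test_rotation_equivariance(self, shift):
        rng = np.random.default_rng(3)
        profs = [np.abs(rng.normal(10, 3, 52)) for _ in range(4)]
        base_week, _, _ = circular_peak_week(self.per_year(profs))
        rolled = [np.roll(p, shift) for p in profs]
        new_week, _, _ = circular_peak_week(self.per_year(rolled))
        assert (new_week - base_week) % 52 == pytest.approx(shift, abs=1e-6)

    def test_generator_peak_recovered(self):
        annot = cosine_series(amplitude=20.0, peak_week=10.0)
        _, per_year = annual_profile(annot)
        week, sd, defined = circular_peak_week(per_year)
        assert defined
        assert abs(week - 10.0) < 0.5 or abs(week - 10.0) > 51.5


class TestWaveletSeasonality:
    def test_strong_sinusoid_significant(self):
        annot = cosine_series(amplitude=20.0, noise_sd=2.0, seed=3, n_years=8)
        p = wavelet_seasonality_p(annot, n_surrogates=500, seed=3)
        assert p < 0.05

    def test_white_noise_mostly_nonsignificant(self):
        hits = 0
        for i in range(20):
            annot = cosine_series(amplitude=0.0, noise_sd=5.0, seed=400 + i, n_years=8)
            p = wavelet_seasonality_p(annot, n_surrogates=200, seed=400 + i)
            hits += p > 0.05
        assert hits >= 18

    def test_partial_sinusoid_nonsignificant(self):
        """The max-over-time rule demands the cycle in every interior year."""
        annot = cosine_series(amplitude=20.0, noise_sd=2.0, seed=5, n_years=8)
        vals = annot.base.values.copy()
        vals[4 * 52:] = 50.0 + np.random.default_rng(5).normal(0, 2, len(vals) - 4 * 52)
        annot2 = ts.annotate(annot.base.replace(vals), branch="dense")
        p = wavelet_seasonality_p(annot2, n_surrogates=200, seed=5)
        assert p > 0.05

    def test_monotone_in_amplitude(self):
        ps = []
        for amp in (0.0, 5.0, 10.0, 20.0):
            spec = ts.SyntheticSpec(seasonal_amplitude=amp, noise_sd=5.0, seed=77)
            series, _ = ts.generate_series(spec)
            annot = ts.annotate(series, branch="dense")
            ps.append(wavelet_seasonality_p(annot, n_surrogates=200, seed=9))
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_short_series_raises(self, epochs):
        s = make_series(np.full(100, 5.0), start="2011-03-06")
        annot = ts.annotate(s, epochs, branch="dense")
        with pytest.raises(InsufficientDataError):
            wavelet_seasonality_p(annot, n_surrogates=10, seed=0)

    def test_profile_reports_atm_only_when_significant(self):
        seasonal = cosine_series(amplitude=20.0, noise_sd=2.0, seed=6, n_years=8)
        prof = ts.seasonality_profile(seasonal, n_surrogates=200, seed=6)
        assert prof.p_seasonal < 0.05 and prof.atm is not None
        flat = cosine_series(amplitude=0.0, noise_sd=5.0, seed=6, n_years=8)
        prof2 = ts.seasonality_profile(flat, n_surrogates=200, seed=6)
        if prof2.p_seasonal >= 0.05:
            assert prof2.atm is None and prof2.peak_week is None


class TestSeasonalityVsReduction:
    def test_identity_pairing_slope_one(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 1, 20)
        slope, p = ts.seasonality_vs_reduction(x, x)
        assert slope == pytest.approx(1.0)
        assert p < 0.001

    def test_independent_uniforms_mostly_nonsignificant(self):
        hits = 0
        for i in range(60):
            rng = np.random.default_rng(500 + i)
            x, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
            _, p = ts.seasonality_vs_reduction(x, y)
            hits += p > 0.05
        assert hits >= 51  # >= 85% of runs

    def test_constant_x_rejected(self):
        with pytest.raises(InputError):
            ts.seasonality_vs_reduction([0.5] * 10, np.linspace(0, 1, 10))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            ts.seasonality_vs_reduction([0.1, 0.2], [0.1, 0.2, 0.3])
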