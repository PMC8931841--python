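"""Seasonal characterization of a weekly series.

Three summaries per term, computed on the pre-intervention epoch:

* **significance** — Morlet continuous-wavelet power at the annual period,
  compared per time point against seeded white-noise surrogates; the
  reported P value is the *maximum* per-time-point P over the interior of
  the series (first and last year excluded).  Taking the max demands a
  consistent annual cycle in every year, which makes the test conservative
  by construction.
* **strength** — the amplitude-to-mean (AtM) ratio of the mean annual
  profile: (peak - mean)/mean, 0 for a flat profile.
* **timing** — the volume-weighted circular mean week of the annual cycle,
  with an across-year circular SD.

By the results-table convention, AtM and peak week are only reported when
the seasonality P value is below .05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import stats

from .exceptions import DegenerateInputError, InputError, InsufficientDataError
from .preprocess import AnnotatedSeries
from .trend_tests import theil_sen_fit

__all__ = ["SeasonalityProfile", "annual_profile", "amplitude_to_mean",
           "circular_peak_week", "wavelet_seasonality_p", "seasonality_vs_reduction",
           "seasonality_profile"]

TROPICAL_YEAR_WEEKS = 52.18


@dataclass
class SeasonalityProfile:
    """Per-term seasonality summary (AtM/peak only when significant)."""

    p_seasonal: float
    atm: float | None = None
    atm_sd: float | None = None
    peak_week: float | None = None
    peak_week_sd: float | None = None
    peak_defined: bool = True


def _study_year(ts: pd.DatetimeIndex, anchor_month: int) -> np.ndarray:
    """Year blocks anchored at the baseline start month (Mar..Feb by default)."""
    return np.where(ts.month >= anchor_month, ts.year, ts.year - 1)


def annual_profile(annot: AnnotatedSeries, anchor_month: int = 3,
                   min_years: int = 2, min_weeks_per_year: int = 48):
    """Mean 52-point weekly profile of the baseline epoch, plus per-year profiles.

    Weeks are indexed by ISO week-of-year with week 53 folded into week 52
    (averaged).  Years are 12-month blocks anchored at ``anchor_month``;
    blocks with fewer than ``min_weeks_per_year`` grid weeks are dropped as
    incomplete.  Returns ``(profile, per_year)`` where ``profile`` is a
    length-52 array (index = week 1..52) and ``per_year`` maps year label to
    its length-52 profile (NaN where absent).
    """
    base = annot.epoch == "baseline"
    ts = pd.DatetimeIndex(annot.base.week_starts[base])
    vals = np.where(annot.base.missing_mask[base], np.nan, annot.base.values[base])
    years = _study_year(ts, anchor_month)
    weeks = np.minimum(np.asarray(ts.isocalendar().week, dtype=int), 52)
    per_year: dict[int, np.ndarray] = {}
    for y in np.unique(years):
        sel = years == y
        if sel.sum() < min_weeks_per_year:
            continue
        prof = np.full(52, np.nan)
        counts = np.zeros(52)
        for w, v in zip(weeks[sel], vals[sel]):
            if np.isnan(v):
                continue
            if np.isnan(prof[w - 1]):
                prof[w - 1] = 0.0
            prof[w - 1] += v
            counts[w - 1] += 1
        with np.errstate(invalid="ignore"):
            prof = prof / np.where(counts > 0, counts, np.nan)
        per_year[int(y)] = prof
    if len(per_year) < min_years:
        raise InsufficientDataError(
            f"{len(per_year)} complete baseline years (< {min_years})")
    stack = np.vstack(list(per_year.values()))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        profile = np.nanmean(stack, axis=0)
    return profile, per_year


def amplitude_to_mean(profile: np.ndarray, per_year_profiles: dict | None = None):
    """AtM ratio of a weekly profile: (max - mean)/mean, with across-year SD.

    The SD is the standard deviation of the per-year AtM values (the only
    replicate structure available); None when per-year profiles are absent.
    """
    profile = np.asarray(profile, float)
    m = np.nanmean(profile)
    if not np.isfinite(m) or m <= 0:
        raise DegenerateInputError("AtM undefined for a non-positive-mean profile")
    atm = float((np.nanmax(profile) - m) / m)
    atm_sd = None
    if per_year_profiles:
        vals = []
        for prof in per_year_profiles.values():
            my = np.nanmean(prof)
            if np.isfinite(my) and my > 0:
                vals.append((np.nanmax(prof) - my) / my)
        if len(vals) > 1:
            atm_sd = float(np.std(vals, ddof=1))
    return atm, atm_sd


def _circular_mean_angle(angles: np.ndarray, weights: np.ndarray | None = None):
    """Mean direction and resultant length of weighted angles."""
    if weights is None:
        weights = np.ones_like(angles)
    c = np.sum(weights * np.cos(angles))
    s = np.sum(weights * np.sin(angles))
    r = np.hypot(c, s) / np.sum(weights)
    return np.arctan2(s, c), r


def _angle_to_week(theta: float) -> float:
    return float((theta % (2 * np.pi)) / (2 * np.pi) * 52 + 1)


def circular_peak_week(per_year_profiles: dict, eps: float = 1e-12):
    """Volume-weighted circular mean week of the annual cycle.

    Week ``w`` maps to angle ``2*pi*(w-1)/52``; each year's mean angle is
    weighted by that year's profile values, then the across-year circular
    mean gives the peak week and the across-year circular SD (in weeks) its
    dispersion.  Returns ``(peak_week, peak_week_sd, defined)``; ``defined``
    is False for a (near-)uniform profile with no direction.
    """
    year_angles = []
    for prof in per_year_profiles.values():
        prof = np.asarray(prof, float)
        w = np.arange(52)
        ok = np.isfinite(prof)
        if not ok.any() or np.nansum(prof) <= 0:
            continue
        theta, r = _circular_mean_angle(2 * np.pi * w[ok] / 52, prof[ok])
        if r > eps:
            year_angles.append(theta)
    if not year_angles:
        return np.nan, np.nan, False
    theta_bar, r_bar = _circular_mean_angle(np.asarray(year_angles))
    if r_bar <= eps:
        return np.nan, np.nan, False
    sd_rad = np.sqrt(max(0.0, -2.0 * np.log(min(r_bar, 1.0)))) if r_bar < 1 else 0.0
    return _angle_to_week(theta_bar), float(sd_rad * 52 / (2 * np.pi)), True


def _interpolate_missing(values: np.ndarray, missing: np.ndarray) -> np.ndarray:
    x = values.astype(float).copy()
    x[missing] = np.nan
    n = len(x)
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise InsufficientDataError("too few present weeks to interpolate")
    return np.interp(np.arange(n), np.flatnonzero(ok), x[ok])


def wavelet_seasonality_p(annot: AnnotatedSeries, n_surrogates: int = 1000,
                          seed: int = 0, period_weeks: float = TROPICAL_YEAR_WEEKS,
                          edge_weeks: int = 52) -> float:
    """Morlet-wavelet test of a consistent annual cycle.

    The standardized series (missing weeks linearly interpolated) is
    transformed at the scale whose Fourier period is closest to one tropical
    year; ``n_surrogates`` white-noise series of the same length provide the
    null power distribution at each time point.  The per-point P value is
    ``(1 + #{surrogate power >= observed}) / (1 + n_surrogates)`` and the
    reported P value is its maximum over interior points (first and last
    ``edge_weeks`` excluded), so *every* interior point must show annual
    power for the series to test significant.
    """
    values = annot.base.values
    n = len(values)
    if n < 3 * edge_weeks:
        raise InsufficientDataError(
            f"need >= {3 * edge_weeks} weeks for the wavelet test, got {n}")
    x = _interpolate_missing(values, annot.base.missing_mask)
    sd = x.std()
    if sd == 0:
        return 1.0  # constant series carries no annual cycle
    x = (x - x.mean()) / sd
    # complex Morlet: |coef|^2 is a smooth power envelope (a real-valued
    # wavelet would oscillate through zero once per cycle)
    wavelet = "cmor1.5-1.0"
    scale = pywt.central_frequency(wavelet) * period_weeks  # dt = 1 week
    coef, _ = pywt.cwt(x, [scale], wavelet, method="fft")
    power = np.abs(coef[0]) ** 2
    rng = np.random.default_rng(seed)
    surr = rng.standard_normal((n_surrogates, n))
    surr = (surr - surr.mean(axis=1, keepdims=True)) / surr.std(axis=1, keepdims=True)
    scoef, _ = pywt.cwt(surr, [scale], wavelet, method="fft", axis=-1)
    spower = np.abs(scoef[0]) ** 2  # (n_surrogates, n)
    exceed = np.sum(spower >= power[None, :], axis=0)
    p_t = (1.0 + exceed) / (1.0 + n_surrogates)
    interior = p_t[edge_weeks: n - edge_weeks]
    return float(interior.max())


def seasonality_profile(annot: AnnotatedSeries, n_surrogates: int = 1000,
                        seed: int = 0, alpha: float = 0.05) -> SeasonalityProfile:
    """Full seasonality summary; AtM/peak reported only when significant."""
    p = wavelet_seasonality_p(annot, n_surrogates=n_surrogates, seed=seed)
    if p >= alpha:
        return SeasonalityProfile(p_seasonal=p)
    profile, per_year = annual_profile(annot)
    atm, atm_sd = amplitude_to_mean(profile, per_year)
    week, week_sd, defined = circular_peak_week(per_year)
    return SeasonalityProfile(p, atm, atm_sd,
                              week if defined else None,
                              week_sd if defined else None, defined)


def seasonality_vs_reduction(seasonality_ps, reduction_ps):
    """Association between per-term seasonality P and reduction P.

    Theil-Sen slope of reduction P on seasonality P, with significance from
    the Kendall-tau test on the pairs (the standard inference companion to
    a Theil-Sen fit).  Returns ``(slope, p_value)``.
    """
    x = np.asarray(seasonality_ps, float)
    y = np.asarray(reduction_ps, float)
    if x.shape != y.shape:
        raise InputError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise InputError("need at least 3 pairs")
    if len(np.unique(x)) < 2:
        raise InputError("seasonality P values are constant; slope undefined")
    fit = theil_sen_fit(x, y)
    tau = stats.kendalltau(x, y)
    return float(fit.slope), float(tau.pvalue)
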