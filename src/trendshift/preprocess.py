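"""Outlier filtering, dense/sparse branch classification and week annotation.

The Hampel filter slides a window over the series and replaces any point
deviating from the window median by more than ``t`` multiples of the scaled
MAD (1.4826 * median absolute deviation) with that median.  Missing weeks
are excluded from window statistics and never imputed.

Series with more than 20% missing-or-zero weeks go down the *sparse*
modelling branch; all others are *dense*.  Zeros count toward the 20% rule
(a zero export means below-threshold interest) but are kept as value-0
observations for modelling.

Annotation assigns each week a season (by the month of its start date), a
season-year cluster (December grouped with the following January/February)
and an epoch (baseline vs post-intervention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InputError, RangeError
from .io import EpochConfig, SearchSeries

__all__ = ["HampelParams", "AnnotatedSeries", "hampel_filter", "classify_branch",
           "missing_or_zero_fraction", "annotate"]

MAD_SCALE = 1.4826  # consistency factor: MAD * 1.4826 estimates a normal SD


@dataclass(frozen=True)
class HampelParams:
    """Hampel window half-width (weeks each side) and threshold in scaled-MAD units."""

    half_window: int = 3
    threshold_t: float = 3.0

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise InputError("half_window must be >= 1")
        if self.threshold_t <= 0:
            raise InputError("threshold_t must be > 0")


def hampel_filter(series: SearchSeries, params: HampelParams = HampelParams()) -> SearchSeries:
    """Replace outliers by the local window median.

    A point is replaced when ``|x - med| > t * 1.4826 * MAD`` over the
    ``2*half_window + 1`` window centred on it (missing entries excluded; the
    centre itself participates in the window statistics).  When the window
    MAD is zero, any nonzero deviation from the median is replaced.  Windows
    with fewer than 3 usable values leave the centre unchanged.

    Zero-valued weeks are censored below-threshold reports, not level
    measurements: they are excluded from window statistics and never
    replaced themselves (otherwise zero-heavy windows acquire median 0 and
    MAD 0 and the filter overwrites genuine values with 0).
    """
    n = len(series)
    k = params.half_window
    if n <= 2 * k:
        raise ConfigError(f"series length {n} too short for half_window {k}")
    x = np.where(series.missing_mask | (series.values == 0), np.nan, series.values)
    out = series.values.copy()

    def apply(idx: int, window: np.ndarray) -> None:
        window = window[~np.isnan(window)]
        if len(window) < 3 or np.isnan(x[idx]):
            return
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        if abs(x[idx] - med) > params.threshold_t * MAD_SCALE * mad:
            out[idx] = med

    # full windows vectorized; truncated edge windows handled individually
    if n >= 2 * k + 1:
        wins = np.lib.stride_tricks.sliding_window_view(x, 2 * k + 1)
        centers = np.arange(k, n - k)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
            med = np.nanmedian(wins, axis=1)
            mad = np.nanmedian(np.abs(wins - med[:, None]), axis=1)
        count = np.sum(~np.isnan(wins), axis=1)
        xc = x[centers]
        flag = (
            (count >= 3)
            & ~np.isnan(xc)
            & (np.abs(xc - med) > params.threshold_t * MAD_SCALE * mad)
        )
        out[centers[flag]] = med[flag]
    for i in list(range(k)) + list(range(n - k, n)):
        apply(i, x[max(0, i - k): i + k + 1])
    return series.replace(out)


def missing_or_zero_fraction(series: SearchSeries) -> float:
    """Fraction of weeks that are missing or exactly zero."""
    return float(np.mean(series.missing_mask | series.zero_mask))


def classify_branch(series: SearchSeries) -> str:
    """``sparse`` iff strictly more than 20% of weeks are missing or zero."""
    if len(series) == 0:
        raise InputError("empty series")
    return "sparse" if missing_or_zero_fraction(series) > 0.20 else "dense"


@dataclass
class AnnotatedSeries:
    """A (typically Hampel-filtered) series with per-week analysis labels."""

    base: SearchSeries
    season_label: np.ndarray  # str per week
    year_cluster: np.ndarray  # str per week, e.g. "winter-2020/21"
    epoch: np.ndarray  # "baseline" | "post" per week
    missing_fraction: float  # missing-or-zero fraction used for branching
    branch: str  # "dense" | "sparse"

    @property
    def week_index(self) -> np.ndarray:
        """Weeks since the first grid week (the regression time axis)."""
        return np.arange(len(self.base), dtype=float)

    @property
    def week_of_year(self) -> np.ndarray:
        """ISO week of each week start, week 53 folded into 52."""
        iso = pd.DatetimeIndex(self.base.week_starts).isocalendar().week
        return np.minimum(np.asarray(iso, dtype=int), 52)

    def present(self) -> np.ndarray:
        """Boolean mask of non-missing weeks (zeros are present)."""
        return ~self.base.missing_mask


def _cluster_label(season: str, year: int, month: int) -> str:
    if season == "winter":
        start = year if month == 12 else year - 1
        return f"winter-{start}/{(start + 1) % 100:02d}"
    return f"{season}-{year}"


def annotate(series: SearchSeries, epochs: EpochConfig = EpochConfig(),
             branch: str | None = None,
             missing_fraction: float | None = None) -> AnnotatedSeries:
    """Label every week with season, season-year cluster and epoch.

    ``branch``/``missing_fraction`` may be supplied from the *raw* series
    when ``series`` has already been filtered (the 20% rule is always
    counted on raw data); by default they are computed from ``series``.
    """
    ts = pd.DatetimeIndex(series.week_starts)
    start = np.datetime64(epochs.baseline_start, "D")
    end = np.datetime64(epochs.analysis_end, "D")
    if series.week_starts[0] < start or series.week_starts[-1] > end:
        raise RangeError(
            f"series '{series.term_id}' spans {series.week_starts[0]}..{series.week_starts[-1]}, "
            f"outside the configured window {start}..{end}"
        )
    seasons = np.array([epochs.season_of(m) for m in ts.month])
    clusters = np.array([_cluster_label(s, y, m)
                         for s, y, m in zip(seasons, ts.year, ts.month)])
    interv = np.datetime64(epochs.intervention_date, "D")
    epoch = np.where(series.week_starts >= interv, "post", "baseline")
    if missing_fraction is None:
        missing_fraction = missing_or_zero_fraction(series)
    if branch is None:
        branch = "sparse" if missing_fraction > 0.20 else "dense"
    return AnnotatedSeries(series, seasons, clusters, epoch,
                           float(missing_fraction), branch)
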