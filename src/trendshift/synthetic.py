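"""Synthetic weekly search-interest panels with known ground truth.

The generator emulates a decade of weekly relative-search-volume data for
one term: a baseline level with a linear secular trend, an annual cosine
cycle peaking at a configurable week, Gaussian noise, occasional
multiplicative outlier weeks, zero-censored and missing weeks, and
multiplicative per-season effects applied after the intervention date.
Values are clipped at zero (RSV cannot be negative); clipped weeks are
flagged in the truth record because clipping breaks the closed-form AtM of
a pure cosine.

Defaults reproduce the study layout: weekly Sundays from 2011-03-06, 9
baseline years + 1 post year (intervention 2020-03-01, which falls exactly
on the weekly grid), level 50, amplitude 20, noise SD 5.

``generate_study`` builds a class-structured panel (16 COVID-like terms
with post increases, 29 communicable terms with strong seasonality and
post reductions, 23 noncommunicable terms with weak seasonality and no
effect) with per-term parameter jitter, mirroring the 16/29/23 design.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import InputError
from .io import EpochConfig, SearchSeries, TermMeta

__all__ = ["SyntheticSpec", "generate_series", "generate_study", "DEFAULT_CLASS_SIZES"]

#: First grid week (a Sunday) and the intervention Sunday used by defaults.
DEFAULT_START = _dt.date(2011, 3, 6)

DEFAULT_CLASS_SIZES = {"covid": 16, "communicable": 29, "noncommunicable": 23}


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters for one synthetic term."""

    n_years_baseline: int = 9
    n_years_post: int = 1
    baseline_level: float = 50.0
    trend_slope: float = 0.0  # RSV units per week
    seasonal_amplitude: float = 20.0
    peak_week: float = 2.0  # week of year in [1, 53)
    noise_sd: float = 5.0
    outlier_prob: float = 0.0
    outlier_scale: float = 3.0
    missing_prob: float = 0.0
    zero_prob: float = 0.0
    season_effects: dict = field(default_factory=dict)  # season -> multiplier post
    seed: int = 0
    start: _dt.date = DEFAULT_START
    intervention: _dt.date = _dt.date(2020, 3, 1)
    term_id: str = "synthetic"
    geolocation: str = "US"

    def __post_init__(self) -> None:
        for name in ("outlier_prob", "missing_prob", "zero_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InputError(f"{name} must be in [0,1], got {v}")
        if self.baseline_level <= 0:
            raise InputError("baseline_level must be > 0")
        if self.seasonal_amplitude < 0 or self.noise_sd < 0:
            raise InputError("amplitude and noise_sd must be >= 0")
        if not 1 <= self.peak_week < 53:
            raise InputError("peak_week must lie in [1, 53)")
        if self.outlier_scale < 1:
            raise InputError("outlier_scale must be >= 1")


def _season_of_month(m: int) -> str:
    return {3: "spring", 4: "spring", 5: "spring", 6: "summer", 7: "summer",
            8: "summer", 9: "autumn", 10: "autumn", 11: "autumn",
            12: "winter", 1: "winter", 2: "winter"}[m]


def generate_series(spec: SyntheticSpec):
    """Generate one weekly series; returns ``(SearchSeries, truth)``.

    The deterministic signal at week t (start date d_t, ISO week w_t) is::

        mu_t = (level + slope*t + A*cos(2*pi*(w_t - peak_week)/52)) * f_t

    with f_t the season effect after the intervention (1 before), then
    ``v_t = max(0, mu_t + eps_t)`` with Gaussian noise, outlier
    multiplication, zero-censoring and missingness applied in that order.
    ``truth`` records the parameters, the affected week indices and which
    weeks were clipped at zero.
    """
    n = 52 * (spec.n_years_baseline + spec.n_years_post)
    rng = np.random.default_rng(spec.seed)
    weeks = np.arange(np.datetime64(spec.start, "D"),
                      np.datetime64(spec.start, "D") + np.timedelta64(7 * n, "D"),
                      np.timedelta64(7, "D"))
    ts = pd.DatetimeIndex(weeks)
    woy = np.minimum(np.asarray(ts.isocalendar().week, dtype=int), 52)
    t = np.arange(n, dtype=float)
    signal = (spec.baseline_level + spec.trend_slope * t
              + spec.seasonal_amplitude * np.cos(2 * np.pi * (woy - spec.peak_week) / 52))
    post = weeks >= np.datetime64(spec.intervention, "D")
    factors = np.ones(n)
    if spec.season_effects:
        seasons = np.array([_season_of_month(m) for m in ts.month])
        for season, f in spec.season_effects.items():
            factors[post & (seasons == season)] = f
    noise = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    values = signal * factors + noise
    outliers = rng.random(n) < spec.outlier_prob
    values = np.where(outliers, values * spec.outlier_scale, values)
    clipped = values < 0
    values = np.maximum(values, 0.0)
    zeros = rng.random(n) < spec.zero_prob
    values = np.where(zeros, 0.0, values)
    missing = rng.random(n) < spec.missing_prob
    values = np.where(missing, np.nan, values)
    series = SearchSeries(spec.term_id, spec.geolocation, weeks, values, missing)
    truth = {
        "spec": spec,
        "outlier_weeks": np.flatnonzero(outliers),
        "zero_weeks": np.flatnonzero(zeros),
        "missing_weeks": np.flatnonzero(missing),
        "clipped_weeks": np.flatnonzero(clipped),
        "post_start_index": int(np.argmax(post)) if post.any() else n,
    }
    return series, truth


#: Class templates: the study conditions each class of terms emulates.
_CLASS_TEMPLATES = {
    "covid": SyntheticSpec(seasonal_amplitude=8.0, peak_week=4.0,
                           season_effects={s: 2.0 for s in ("spring", "summer",
                                                            "autumn", "winter")}),
    "communicable": SyntheticSpec(seasonal_amplitude=20.0, peak_week=2.0,
                                  season_effects={s: 0.5 for s in ("spring", "summer",
                                                                   "autumn", "winter")}),
    "noncommunicable": SyntheticSpec(seasonal_amplitude=3.0, peak_week=26.0,
                                     season_effects={}),
}


def generate_study(n_terms: dict[str, int] | None = None, seed: int = 0,
                   templates: dict[str, SyntheticSpec] | None = None,
                   jitter: float = 0.15):
    """Generate a class-structured panel; returns ``(series, metas, truth_table)``.

    Each term draws its level, amplitude and season effects by jittering its
    class template (+-``jitter`` relative, seeded), so terms are exchangeable
    within class but not identical.  ``truth_table`` records every term's
    realized parameters.
    """
    n_terms = dict(DEFAULT_CLASS_SIZES if n_terms is None else n_terms)
    templates = dict(_CLASS_TEMPLATES if templates is None else templates)
    if any(v < 1 for v in n_terms.values()):
        raise InputError("need at least 1 term per class")
    rng = np.random.default_rng(seed)
    series_list, metas, rows = [], [], []
    for cls, count in n_terms.items():
        tmpl = templates[cls]
        for i in range(count):
            term = f"{cls}-{i:02d}"
            level = tmpl.baseline_level * (1 + jitter * rng.uniform(-1, 1))
            amp = tmpl.seasonal_amplitude * (1 + jitter * rng.uniform(-1, 1))
            peak = float((tmpl.peak_week - 1 + rng.uniform(-2, 2)) % 52 + 1)
            effects = {s: max(0.05, f * (1 + jitter * rng.uniform(-1, 1)))
                       for s, f in tmpl.season_effects.items()}
            spec = replace(tmpl, baseline_level=level, seasonal_amplitude=amp,
                           peak_week=peak, season_effects=effects,
                           seed=int(rng.integers(0, 2**31 - 1)), term_id=term)
            s, truth = generate_series(spec)
            series_list.append(s)
            metas.append(TermMeta(term=term, class_label=cls, geolocation="US"))
            rows.append({"term": term, "class": cls, "level": level,
                         "amplitude": amp, "peak_week": peak,
                         **{f"effect_{s_}": effects.get(s_, 1.0)
                            for s_ in ("spring", "summer", "autumn", "winter")},
                         "seed": spec.seed})
    return series_list, metas, pd.DataFrame(rows)


def default_epochs() -> EpochConfig:
    """Epoch configuration matching the generator's default calendar."""
    return EpochConfig()
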