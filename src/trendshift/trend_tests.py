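"""Per-term tests for post-intervention change in each season.

Two branches, chosen by data completeness:

*dense* (at most 20% missing-or-zero weeks)
    The pre-intervention epoch is detrended with Theil-Sen regression on
    calendar time (weeks); residuals are computed for *all* weeks against
    the extrapolated line.  For each season, residuals are demeaned by
    ISO week-of-year (comparing each post week to the corresponding weeks
    of previous years), summarized per season-year cluster with a Huber
    M-estimate of location (c = 1.345, MAD scale), and the post cluster is
    compared with the extrapolation of a Theil-Sen trend over the baseline
    cluster locations, using a prediction-style standard error and a
    Student-t reference with G-2 degrees of freedom.  Collapsing to
    cluster locations makes the inference robust to within-year
    correlation and outlier weeks; estimating the post cluster's
    uncertainty from the between-cluster dispersion avoids the degenerate
    sandwich variance that arises when a single post cluster is confounded
    with the post indicator; and the per-season trend absorbs the residual
    drift that a single global detrend leaves when extrapolated a year
    ahead.

*sparse* (more than 20% missing-or-zero weeks)
    The same cluster-location comparison is applied to the raw
    (Hampel-filtered) values without detrending: one model per series with
    an overall baseline level plus one indicator per post season, each
    indicator tested against the between-cluster dispersion of all baseline
    season-year clusters.  Zero weeks are observations with value 0; only
    missing weeks are dropped.

A significant two-sided P value is read as an *increase* unless the
one-sided (decrease) test is also significant, in which case it is a
*decrease*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateInputError, InputError, InsufficientDataError
from .io import SEASON_ORDER
from .preprocess import AnnotatedSeries

__all__ = ["TheilSenFit", "SeasonalChangeResult", "theil_sen_fit", "detrend_baseline",
           "huber_location", "dense_season_test", "sparse_season_test",
           "season_tests", "classify_direction"]

HUBER_C = 1.345  # 95% efficiency at the normal


@dataclass
class TheilSenFit:
    """Theil-Sen line: slope = median of pairwise slopes, intercept = median(y - b*t)."""

    slope: float
    intercept: float
    residuals: np.ndarray

    def predict(self, times: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(times, float)


@dataclass
class SeasonalChangeResult:
    """Post-vs-baseline comparison for one term and season."""

    term_id: str
    season: str
    p_two: float
    p_one_decrease: float
    effect: float  # post-minus-baseline location shift, RSV units
    branch: str  # "dense" | "sparse"
    direction: str = "none"  # set by classify_direction
    estimable: bool = True
    n_post: int = 0
    n_baseline_clusters: int = 0

    @classmethod
    def not_estimable(cls, term_id: str, season: str, branch: str) -> "SeasonalChangeResult":
        return cls(term_id, season, np.nan, np.nan, np.nan, branch, estimable=False)


def theil_sen_fit(times, values, exact_threshold: int = 2000,
                  n_subsample_pairs: int = 1_000_000, seed: int = 0) -> TheilSenFit:
    """Fit a Theil-Sen line.

    The slope is the median of all pairwise slopes ``(y_j - y_i)/(t_j - t_i)``
    over pairs with distinct times; the intercept is the median of
    ``y_i - slope * t_i``.  NaN values are dropped pairwise.  All pairs are
    enumerated for up to ``exact_threshold`` points; beyond that a seeded
    random subsample of ``n_subsample_pairs`` pairs is used.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.shape != y.shape:
        raise InputError("times and values must have the same length")
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    n = len(t)
    if len(np.unique(t)) < 2:
        raise DegenerateInputError("Theil-Sen needs >= 2 distinct time points")
    if n <= exact_threshold:
        dt = t[:, None] - t[None, :]
        dy = y[:, None] - y[None, :]
        iu = np.triu_indices(n, k=1)
        dt, dy = dt[iu], dy[iu]
        keep = dt != 0
        slopes = dy[keep] / dt[keep]
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, n_subsample_pairs)
        j = rng.integers(0, n, n_subsample_pairs)
        keep = t[i] != t[j]
        slopes = (y[j][keep] - y[i][keep]) / (t[j][keep] - t[i][keep])
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * t))
    # residuals for every *supplied* point (NaN where the input was NaN)
    t_all = np.asarray(times, float)
    y_all = np.asarray(values, float)
    residuals = y_all - (intercept + slope * t_all)
    return TheilSenFit(slope, intercept, residuals)


def detrend_baseline(annot: AnnotatedSeries) -> np.ndarray:
    """Residuals of the whole series against the baseline-epoch Theil-Sen line.

    The line is fitted on present baseline weeks only and extrapolated over
    the post epoch, so post residuals measure departure from the
    pre-intervention trend.  Missing weeks get NaN residuals.
    """
    if annot.branch != "dense":
        raise InputError("detrend_baseline applies to the dense branch")
    t = annot.week_index
    y = np.where(annot.base.missing_mask, np.nan, annot.base.values)
    base = (annot.epoch == "baseline") & annot.present()
    if base.sum() < 2:
        raise DegenerateInputError("fewer than 2 present baseline weeks")
    fit = theil_sen_fit(t[base], y[base])
    return y - fit.predict(t)


def huber_location(x, c: float = HUBER_C, tol: float = 1e-9, max_iter: int = 200) -> float:
    """Huber M-estimate of location with fixed MAD scale.

    IRLS from the median; scale = 1.4826 * MAD.  Falls back to the median
    when the MAD is zero (at least half the points identical).
    """
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise DegenerateInputError("huber_location of empty sample")
    mu = float(np.median(x))
    s = 1.4826 * float(np.median(np.abs(x - mu)))
    if s == 0 or x.size < 3:
        return mu
    for _ in range(max_iter):
        r = (x - mu) / s
        w = np.where(np.abs(r) <= c, 1.0, c / np.maximum(np.abs(r), 1e-300))
        mu_new = float(np.sum(w * x) / np.sum(w))
        if abs(mu_new - mu) <= tol * max(s, 1.0):
            mu = mu_new
            break
        mu = mu_new
    return mu


def _cluster_locations(values: np.ndarray, clusters: np.ndarray) -> dict[str, float]:
    out = {}
    for c in np.unique(clusters):
        v = values[clusters == c]
        v = v[np.isfinite(v)]
        if v.size:
            out[str(c)] = huber_location(v)
    return out


def _cluster_year(label: str) -> int:
    """Season-year cluster start year, e.g. 'winter-2019/20' -> 2019."""
    return int(label.split("-")[1].split("/")[0])


def dense_season_test(annot: AnnotatedSeries, residuals: np.ndarray, season: str,
                      min_baseline_clusters: int = 2, min_post_weeks: int = 4) -> SeasonalChangeResult:
    """Compare the post-intervention season's residuals to baseline years.

    Restricts to weeks of ``season`` across all years and collapses each
    season-year cluster to a Huber location of its residuals.  Because the
    global Theil-Sen detrend can leave a small season-specific residual
    drift (its slope is estimated on a strongly seasonal series and then
    extrapolated a full year), the baseline cluster locations are given
    their own Theil-Sen trend over years; the post cluster is compared with
    that line's extrapolation using a prediction-style standard error

        SE = s * sqrt(1 + 1/G + (x0 - xbar)^2 / sum((x - xbar)^2))

    where ``s`` is the SD of the baseline locations about their line and
    ``x0`` the post year.  With only two baseline clusters the trend is
    dropped and the post cluster is compared with their mean.
    """
    if season not in SEASON_ORDER:
        raise InputError(f"unknown season {season!r}")
    sel = (annot.season_label == season) & np.isfinite(residuals)
    post_sel = sel & (annot.epoch == "post")
    base_sel = sel & (annot.epoch == "baseline")
    if post_sel.sum() < min_post_weeks:
        if post_sel.sum() == 0:
            return SeasonalChangeResult.not_estimable(annot.base.term_id, season, "dense")
        raise InsufficientDataError(
            f"season {season}: only {post_sel.sum()} post weeks (< {min_post_weeks})")
    # week-of-year demeaning ("corresponding times of previous years"):
    # subtract the baseline mean residual at each ISO week so the
    # within-season seasonal shape — which differs deterministically between
    # 13- and 14-week season-years — cancels out of every cluster location
    residuals = residuals.copy()
    woy = annot.week_of_year
    for w in np.unique(woy[sel]):
        ref = base_sel & (woy == w)
        here = sel & (woy == w)
        if ref.any():
            residuals[here] -= np.nanmean(residuals[ref])
    base_locs = _cluster_locations(residuals[base_sel], annot.year_cluster[base_sel])
    if len(base_locs) < min_baseline_clusters:
        raise InsufficientDataError(
            f"season {season}: {len(base_locs)} baseline year-clusters (< {min_baseline_clusters})")
    years = np.array([_cluster_year(c) for c in base_locs])
    order = np.argsort(years)
    x = years[order].astype(float)
    m_base = np.array(list(base_locs.values()))[order]
    m_post = huber_location(residuals[post_sel])
    post_years = {_cluster_year(c) for c in np.unique(annot.year_cluster[post_sel])}
    x0 = float(min(post_years))
    g = len(m_base)
    if g >= 3:
        fit = theil_sen_fit(x, m_base)
        expected = float(fit.predict(np.array([x0]))[0])
        resid = m_base - fit.predict(x)
        s = float(np.sqrt(np.sum(resid ** 2) / (g - 2)))
        xbar = x.mean()
        leverage = 1.0 / g + (x0 - xbar) ** 2 / np.sum((x - xbar) ** 2)
    else:
        expected = float(m_base.mean())
        s = float(m_base.std(ddof=1))
        leverage = 1.0 / g
    effect = float(m_post - expected)
    se = s * np.sqrt(1.0 + leverage)
    df = g - 2 if g >= 3 else g - 1  # spread estimated about a fitted line / mean
    if se == 0:
        p_two, p_one = (1.0, 0.5) if effect == 0 else (0.0, 0.0 if effect < 0 else 1.0)
    else:
        z = effect / se
        p_two = float(2 * stats.t.sf(abs(z), df))
        p_one = float(stats.t.cdf(z, df))
    return SeasonalChangeResult(annot.base.term_id, season, p_two, p_one, effect,
                                "dense", n_post=int(post_sel.sum()),
                                n_baseline_clusters=g)


def sparse_season_test(annot: AnnotatedSeries,
                       min_baseline_clusters: int = 4) -> dict[str, SeasonalChangeResult]:
    """Indicator-style comparison on raw values for sparse series.

    One model per series, an intercept plus one indicator per post season:
    the baseline level is the mean of the baseline season-year cluster
    means (all seasons pooled) and each post season's indicator effect is
    its post-cluster mean minus that level.  The variance decomposes as a
    year random intercept plus within-cluster noise, estimated by moments
    from the baseline clusters::

        v_b    = var(cluster means)             (between, ddof=1)
        s2_w   = pooled within-cluster variance
        tau2   = max(0, v_b - s2_w * mean(1/n_c))
        SE_s^2 = tau2 + s2_w / n_post_s + v_b / G

    with standard-normal one-/two-sided P values per indicator.  Cluster
    means (not M-estimates) are used deliberately: zeros are genuine
    below-threshold observations whose one-sided contamination a Huber
    location shrinks nonlinearly, producing heavy-tailed cluster summaries;
    spike outliers are already handled by the upstream Hampel filter.
    Seasons with no post observations are flagged not-estimable; the rest
    are still returned.
    """
    y = np.where(annot.base.missing_mask, np.nan, annot.base.values)
    base_sel = (annot.epoch == "baseline") & np.isfinite(y)
    if base_sel.sum() == 0:
        raise InsufficientDataError("no present baseline weeks")
    means, sizes, withins = [], [], []
    for c in np.unique(annot.year_cluster[base_sel]):
        v = y[base_sel & (annot.year_cluster == c)]
        v = v[np.isfinite(v)]
        if v.size == 0:
            continue
        means.append(v.mean())
        sizes.append(v.size)
        if v.size >= 2:
            withins.append((v.size - 1, v.var(ddof=1)))
    if len(means) < min_baseline_clusters:
        raise InsufficientDataError(
            f"{len(means)} baseline season-year clusters (< {min_baseline_clusters})")
    m_base = np.asarray(means)
    sizes = np.asarray(sizes, float)
    g = len(m_base)
    level = float(m_base.mean())
    v_b = float(m_base.var(ddof=1))
    if withins:
        dof = sum(d for d, _ in withins)
        s2_w = sum(d * v for d, v in withins) / dof
    else:
        s2_w = 0.0
    tau2 = max(0.0, v_b - s2_w * float(np.mean(1.0 / sizes)))
    out: dict[str, SeasonalChangeResult] = {}
    for season in SEASON_ORDER:
        post_sel = (annot.season_label == season) & (annot.epoch == "post") & np.isfinite(y)
        n_post = int(post_sel.sum())
        if n_post == 0:
            out[season] = SeasonalChangeResult.not_estimable(
                annot.base.term_id, season, "sparse")
            continue
        effect = float(y[post_sel].mean() - level)
        se = float(np.sqrt(tau2 + s2_w / n_post + v_b / g))
        if se == 0:
            p_two, p_one = (1.0, 0.5) if effect == 0 else (0.0, 0.0 if effect < 0 else 1.0)
        else:
            z = effect / se
            p_two = float(2 * stats.norm.sf(abs(z)))
            p_one = float(stats.norm.cdf(z))
        out[season] = SeasonalChangeResult(annot.base.term_id, season, p_two, p_one,
                                           effect, "sparse", n_post=n_post,
                                           n_baseline_clusters=g)
    return out


def season_tests(annot: AnnotatedSeries, alpha: float = 0.05) -> dict[str, SeasonalChangeResult]:
    """Run the branch-appropriate per-season tests and classify directions."""
    if annot.branch == "dense":
        residuals = detrend_baseline(annot)
        results = {s: dense_season_test(annot, residuals, s) for s in SEASON_ORDER}
    else:
        results = sparse_season_test(annot)
    for r in results.values():
        if r.estimable:
            r.direction = classify_direction(r, alpha)
    return results


def classify_direction(result: SeasonalChangeResult, alpha: float = 0.05) -> str:
    """decrease if the one-sided test is significant; else increase if the
    two-sided test is; else none."""
    if not result.estimable:
        return "none"
    if result.p_one_decrease < alpha:
        return "decrease"
    if result.p_two < alpha:
        return "increase"
    return "none"
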