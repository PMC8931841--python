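# Methods

`trendshift` implements a blinded, multi-stage statistical pipeline for
weekly relative-search-volume (RSV) time series: per-term tests for
sustained per-season changes after an intervention date, per-term
characterization of annual seasonality, and group-level meta-tests
comparing classes of terms.  This note describes the models, their
assumptions, the tunable parameters, and the design choices made where the
design was genuinely open.

## Data model

A series is a term's weekly RSV values on a strict 7-day grid: dimensionless
shares on the provider's 0–100 scale, never negative.  Three week states are
distinguished:

* **present** — a positive (or zero) value was exported;
* **zero** — the export reported exactly 0, which we treat as *censored
  below the provider's privacy threshold*: genuinely low interest, but not a
  calibrated level measurement;
* **missing** — no row for that week; stored as NaN with a mask bit.

Weeks are annotated with a **season** (by the month of the week's start
date: Mar–May spring, Jun–Aug summer, Sep–Nov autumn, Dec–Feb winter), a
**season-year cluster** (December grouped with the following January and
February, so one winter is one cluster), and an **epoch** (baseline before
the intervention date, post from it onward).  The default calendar is a
9-year baseline (March 2011 – February 2020), intervention 2020-03-01, and
analysis end 2021-02-28.

## Outlier filtering (Hampel)

Each series is first passed through a Hampel filter: a point is replaced by
its window median when it deviates from that median by more than
`t × 1.4826 × MAD` over a `2k+1`-week window.  Defaults `k = 3` (7-week
window) and `t = 3` are the conventional choices for this filter family.
Missing weeks are excluded from window statistics and never imputed.

Two deliberate refinements:

* **Zeros are censored, not levels.**  Zero weeks are excluded from window
  statistics and are never themselves replaced.  If zeros participate,
  zero-heavy windows acquire median 0 and MAD 0 and the filter overwrites
  genuine values with 0; on zero-inflated synthetic series this inflated the
  final winter cluster's sampling SD from 7.2 to 11.8 RSV units and biased
  it by about −1.
* **Zero-MAD windows** replace any nonzero deviation (the limit of the rule;
  avoids a divide-by-zero special case).

The filter is *not* exactly idempotent on noisy data: each replacement
shifts neighbouring window statistics, so a second pass can flag further
points.  This is a property of the standard definition, not an
implementation artifact; replacement of an isolated spike in an otherwise
clean series is a fixed point.

## Branching rule

Series with **more than 20%** missing-or-zero weeks take the *sparse*
branch; all others the *dense* branch.  The fraction is counted on the raw
series (before filtering), and the boundary case of exactly 20% is dense.
Zeros count toward the rule but are retained as value-0 observations for
modelling.

## Dense branch: detrend and per-season comparison

1. **Detrend.**  Theil-Sen regression (slope = median of all pairwise
   slopes; intercept = median of `y − slope·t`; time in weeks) is fitted to
   the present baseline weeks and extrapolated over the whole series;
   residuals measure departure from the pre-intervention trend.  All pairs
   are enumerated exactly up to 2000 points (the default study size of ~470
   baseline weeks is always exact); beyond that a seeded random subsample of
   10⁶ pairs is used.
2. **Week-of-year matching.**  Within the tested season, residuals are
   demeaned by ISO week-of-year (week 53 folded into 52) using baseline
   means, so each post week is compared to the corresponding weeks of
   previous years.  This matters because a season covers 13 ISO weeks in
   some years and 14 in others; without matching, the deterministic
   within-season profile biases the post-season summary by up to ~2 RSV
   units for a strongly seasonal series.
3. **Cluster summaries.**  Each season-year cluster is collapsed to a Huber
   M-estimate of location (tuning constant 1.345, MAD scale) — robust to
   outlier weeks and to within-year correlation, since all inference happens
   between clusters.
4. **Comparison.**  The baseline cluster locations get their own Theil-Sen
   trend over years (a single global detrend of a strongly seasonal series
   leaves a small slope misfit that a one-year extrapolation amplifies; the
   per-season trend absorbs it).  With `G` baseline clusters, residual
   spread `s` about that line and post year `x₀`:

   ```
   effect = m_post − trend(x₀)
   SE     = s · sqrt(1 + 1/G + (x₀ − x̄)² / Σ(xᵢ − x̄)²)
   ```

   One- and two-sided P values come from a Student-t reference with `G − 2`
   degrees of freedom (the spread is estimated about a fitted line; with
   only two baseline clusters the trend is dropped and `G − 1` is used).
   The one-sided P targets decreases: `p_one = T(effect/SE)`.

With a single post year the post indicator is confounded with the post
cluster, so a cluster-robust sandwich variance degenerates (the
within-cluster score sum vanishes at the estimate).  Estimating the post
cluster's uncertainty from the *between-cluster dispersion* of the baseline
years — a prediction interval, in effect — is what makes the test honest in
this design.  Under the null synthetic generator (amplitude 20, noise SD 5,
9 + 1 years) the one-sided rejection rate at α = .05 is 0.03–0.06 per season
over 1000 replicates; a normal reference instead of the t gives 0.06–0.09.

## Sparse branch: indicator comparison on raw values

Sparse series are modelled on the (filtered) raw values without detrending:
an overall baseline level plus one indicator per post season.  Cluster
summaries here are plain means: zeros are genuine one-sided contamination,
and a Huber location shrinks them nonlinearly, making cluster summaries
heavy-tailed (measured null rejection 0.08–0.11 versus 0.03–0.06 with
means); spike outliers have already been handled by the Hampel filter.
The variance uses a method-of-moments year random-intercept decomposition
over the `G` baseline season-year clusters:

```
v_b   = var(cluster means)                   (between-cluster, ddof 1)
s²_w  = pooled within-cluster variance
τ²    = max(0, v_b − s²_w · mean(1/n_c))     (random-intercept variance)
SE²_s = τ² + s²_w / n_post,s + v_b / G
```

which correctly handles unequal cluster sizes (the final winter has 11
weeks, not 13, because the analysis window ends in late February).  P values
use the standard normal (G ≈ 36 clusters).  A season with no post
observations is flagged not-estimable; other seasons are still returned.

## Direction rule

A term-season is called a **decrease** when the one-sided P is below α, an
**increase** when only the two-sided P is, and **none** otherwise
(α = 0.05 throughout).  For these symmetric statistics
`p_one ≈ p_two/2` when the effect is negative and `1 − p_two/2` when
positive.

## Seasonality characterization

* **Significance** — the standardized series (missing weeks linearly
  interpolated for the transform only) is run through a continuous Morlet
  wavelet transform (complex Morlet `cmor1.5-1.0`; a real-valued wavelet
  would oscillate through zero once per cycle rather than give a power
  envelope) at the scale whose Fourier period is closest to one tropical
  year (52.18 weeks).  `n` white-noise surrogates of the same length give
  the null power distribution per time point; the per-point P value is
  `(1 + #exceedances)/(1 + n)` and the reported P value is the **maximum**
  per-point P over the interior of the series (first and last 52 weeks
  excluded).  Taking the max demands annual power in *every* interior year
  — deliberately conservative; a cycle present only in early years tests
  non-significant.  Default `n = 1000` surrogates, seeded; AR(1) surrogates
  are not implemented (white noise is the standard default for this test
  family).
* **Strength** — the amplitude-to-mean (AtM) ratio of the mean 52-week
  baseline annual profile: `(peak − mean)/mean`, 0 for a flat profile, with
  an across-year SD (the only replicate structure available).  For a cosine
  of amplitude A about level m the ratio equals A/m within 1% at 52-point
  resolution.
* **Timing** — the volume-weighted circular mean week: week w maps to angle
  `2π(w−1)/52`, each baseline year's mean angle is weighted by its profile
  values, and the across-year circular mean/SD give the peak week and its
  dispersion.  Wrap-around is handled natively (the mean of weeks 51 and 3
  is week 1); a near-uniform profile has no defined direction and is
  flagged.

AtM and peak week are reported only when the seasonality P value is below
.05, mirroring the reporting convention of the results tables.

## Group-level inference

Per season and family (two-sided *change*, one-sided *reduction*), the
per-term P values of the communicable and noncommunicable classes (COVID
class excluded) are compared with:

* the **Wilcoxon rank-sum** test on the raw P values (exact enumeration
  when both groups have ≤ 10 tie-free values, otherwise the normal
  approximation with tie and continuity corrections), and
* the **Fisher exact** test on the 2×2 table of significance counts,
  dichotomized at strict `P < α` (a value exactly at .05 is not
  significant).

Benjamini-Hochberg FDR correction is applied within each family × season
across terms (and separately to the seasonality P values) before reporting;
the group tests consume the *uncorrected* per-term P values by default
(configurable), the least anti-conservative defensible ordering.

A per-season Theil-Sen regression of each term's reduction P on its
seasonality P, with significance from the Kendall-tau test on the pairs
(the standard inference companion of a Theil-Sen fit; exact for small n,
tie-corrected normal approximation otherwise), quantifies whether more
seasonal terms were more reduced.

## Masking

Terms, class labels and geolocations are replaced by seeded
random-permutation numeric codes before analysis; the codebook is a
bijection and every statistic is label-invariant, so masked and unmasked
runs agree exactly (tested end-to-end).

## Synthetic data generator

The generator emulates the study conditions: weekly Sundays from
2011-03-06, 52×(9+1) weeks, intervention 2020-03-01 (exactly on the grid).
The signal is `level + slope·t + A·cos(2π(w_t − peak)/52)` with `w_t` the
ISO week-of-year — the annual cycle tracks the calendar, as real seasonal
behaviour does, which is why the analysis must match weeks-of-year rather
than assume a fixed 52-week phase.  Multiplicative per-season effects apply
after the intervention; Gaussian noise (RSV values are normalized shares,
not counts), occasional multiplicative outliers, zero-censoring and
missingness follow, in that order, all from one seed.  Values clip at 0 and
clipped weeks are recorded in the truth output because clipping breaks the
closed-form AtM of a pure cosine.

Defaults are the study conditions used throughout the tests: level 50,
amplitude 20, noise SD 5, peak week 2 (flu-like early-January peak).  The
class-structured panel (`generate_study`) draws 16 COVID-like terms (post
increases ×2), 29 communicable terms (strong seasonality, post effects
×0.5) and 23 noncommunicable controls (weak seasonality, no effect), with
±15% per-term jitter.

What the generator does **not** emulate: the provider's sampling noise and
rescaling quirks, cross-term correlation (news events moving many terms at
once), non-Gaussian heavy-tailed interest spikes, and secular trends that
change slope mid-baseline.  Passing tests therefore demonstrate
calibration and power under a clean interrupted-seasonal model, not
robustness to every artifact of real search data.

## Numerical choices and degenerate inputs

* Theil-Sen needs ≥ 2 distinct time points; a constant-time input is a
  degenerate-input error.  Exact all-pairs enumeration ≤ 2000 points.
* Huber location: IRLS from the median with fixed 1.4826·MAD scale;
  zero-MAD samples return the median.
* Zero standard error in a season test: P = 1 at zero effect, else 0 (the
  limit of the rule).
* A week off the 7-day grid anchored at a term's first observed week is
  rejected, not snapped — silent snapping hides upstream export errors.
* Coarsened P rendering: `<.001` below .001, `>.99` above .99, otherwise
  two significant figures without the leading zero; full precision is
  always stored alongside.  Replays of published coarsened tables coerce
  `<.001` → .001 and `>.99` → .99.

## Problem sizes used by the acceptance script

Null calibration uses 500 replicates, winter-halving recovery 200, wavelet
sensitivity/specificity 20 runs at 200 surrogates, and one full 68-term
panel end-to-end — sizes chosen to pin each rate well inside its expected
band on a single CPU.  Larger runs reproduce the same rates.

## Known limitations

* With one post year the design cannot separate a post-intervention shift
  from that single year's random intercept; the reported effect absorbs
  both (inherent to the study design, not the estimator).
* The sparse branch compares each post season to the *overall* baseline
  level, so a strongly seasonal sparse series dilutes its own evidence (the
  seasonal spread sits in the between-cluster variance); sparse series are
  expected to be weakly seasonal low-volume terms.
* Wavelet P values are surrogate-resolution limited (min `1/(n+1)`), and
  the max-over-time rule trades power for the consistency guarantee.
* The published per-term table is coarsened, so group-test replays are
  bounds, not exact value reproductions.
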