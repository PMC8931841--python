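"""Detect a post-intervention reduction in one weekly search-interest series.

Generates ten years of weekly data for a flu-like seasonal term whose
winter search interest is halved after the intervention date (2020-03-01),
then runs the dense-branch analysis: Hampel filter, Theil-Sen detrend of
the 9-year baseline, and a robust year-clustered comparison per season.
"""

import trendshift as ts

spec = ts.SyntheticSpec(seed=12, season_effects={"winter": 0.5})
series, truth = ts.generate_series(spec)

annot, results, profile = ts.analyze_term(series, ts.RunConfig(n_surrogates=200))

print(f"term: {series.term_id}  branch: {annot.branch}  "
      f"missing-or-zero: {annot.missing_fraction:.0%}")
print(f"seasonality P = {ts.format_p(profile.p_seasonal)}  "
      f"AtM = {profile.atm:.2f}  peak week = {profile.peak_week:.1f}")
print()
print(f"{'season':8} {'two-sided P':>12} {'one-sided P':>12} {'effect':>8}  call")
for s in ts.SEASON_ORDER:
    r = results[s]
    print(f"{s:8} {ts.format_p(r.p_two):>12} {ts.format_p(r.p_one_decrease):>12} "
          f"{r.effect:8.1f}  {r.direction}")

print()
print("The halved winter shows a large negative effect (relative-search-volume"
      " units) with one-sided P < .001 — a significant sustained reduction;"
      " the untouched seasons stay non-significant.")
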