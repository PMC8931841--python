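"""Replay the published per-term P values through the group-level tests.

The package ships the printed per-term P values of the 52 non-COVID US
panel terms (29 communicable, 23 noncommunicable control).  Feeding the
one-sided "reduction" columns — with coarsened entries coerced,
"<.001" -> .001 and ">.99" -> .99 — through the Wilcoxon rank-sum and
Fisher exact tests reproduces the published class-comparison bounds.
"""

import trendshift as ts

panel = ts.load_reference_panel()
table = ts.replay_group_tests(panel)

print("one-sided (reduction) family, communicable vs noncommunicable:")
one = table[table["family"] == "one_sided_reduction"]
for _, row in one.iterrows():
    print(f"  {row['season']:8} Wilcoxon P = {row['wilcoxon_p']:.2e}  "
          f"Fisher P = {row['fisher_p']:.2e}  "
          f"(significant terms {row['communicable_sig']}/29 vs "
          f"{row['noncommunicable_sig']}/23)")

print()
print("Summer, autumn and winter all come out far below .001, matching the"
      " published '<.001' bounds; spring separates only weakly, matching the"
      " published exception.  The replay uses coarsened inputs, so values are"
      " bounds rather than exact reproductions.")
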