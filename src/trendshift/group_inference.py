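"""Second-level inference: FDR correction and class-comparison meta-tests.

Per season and test family (two-sided change / one-sided reduction), the
per-term P values of the communicable and noncommunicable classes are
compared two ways: the Wilcoxon rank-sum (Mann-Whitney) test on the raw P
values, and the Fisher exact test on the 2x2 table of significance counts
(P < alpha, strict).  COVID-class terms are excluded from these
comparisons.  Benjamini-Hochberg FDR correction is applied within each
(family x season) across terms before reporting; the meta-tests consume
the uncorrected per-term P values by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import InputError
from .io import SEASON_ORDER, TermMeta
from .trend_tests import SeasonalChangeResult

__all__ = ["GroupTestResult", "bh_fdr", "wilcoxon_group_test", "fisher_group_test",
           "run_group_comparisons", "wilcoxon_exact_enumeration"]

FAMILIES = ("two_sided_change", "one_sided_reduction")


@dataclass
class GroupTestResult:
    """Class-comparison outcome for one season and test family."""

    season: str
    family: str
    wilcoxon_p: float
    fisher_p: float
    table2x2: np.ndarray  # rows: (communicable, noncommunicable); cols: (sig, not)
    n_a: int
    n_b: int


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P values (order preserved)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InputError("P values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_group_test(ps_group_a, ps_group_b) -> float:
    """Two-sided Wilcoxon rank-sum P value comparing two groups of P values.

    Exact enumeration when both groups have <= 10 values and there are no
    ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(ps_group_a, float)
    b = np.asarray(ps_group_b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (no_ties and a.size <= 10 and b.size <= 10) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


def wilcoxon_exact_enumeration(a, b) -> float:
    """Brute-force exact two-sided rank-sum P value (tie-free inputs, small n).

    Enumerates every assignment of ranks to group A and counts assignments
    whose U statistic is at least as extreme as observed.  Test oracle; not
    used by the pipeline.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    if len(np.unique(pooled)) != len(pooled):
        raise InputError("enumeration oracle requires tie-free data")
    n_a, n = len(a), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    mean_u = n_a * (n - n_a) / 2
    count = total = 0
    for idx in combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - n_a * (n_a + 1) / 2
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


def fisher_group_test(ps_group_a, ps_group_b, alpha: float = 0.05):
    """Fisher exact test on significance counts; returns ``(p, table2x2)``.

    Each P value is dichotomized at strict ``< alpha`` (a value exactly at
    alpha is not significant).  The two-sided P value sums the
    probabilities of all tables with the observed margins whose probability
    does not exceed the observed table's.
    """
    a = np.asarray(ps_group_a, float)
    b = np.asarray(ps_group_b, float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    table = np.array([[int(np.sum(a < alpha)), int(np.sum(a >= alpha))],
                      [int(np.sum(b < alpha)), int(np.sum(b >= alpha))]])
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return p, table


def _collect(results, metas: list[TermMeta], family: str, season: str):
    """Per-class P-value vectors for one family and season."""
    attr = "p_two" if family == "two_sided_change" else "p_one_decrease"
    by_class: dict[str, list[float]] = {"communicable": [], "noncommunicable": []}
    class_of = {m.term: m.class_label for m in metas}
    for r in results:
        if r.season != season or not r.estimable:
            continue
        if r.term_id not in class_of:
            raise InputError(f"term {r.term_id!r} has no class label")
        cls = class_of[r.term_id]
        if cls in by_class:
            by_class[cls].append(getattr(r, attr))
    return by_class["communicable"], by_class["noncommunicable"]


def run_group_comparisons(results: list[SeasonalChangeResult], metas: list[TermMeta],
                          families=FAMILIES, alpha: float = 0.05,
                          seasons=SEASON_ORDER) -> list[GroupTestResult]:
    """Communicable-vs-noncommunicable meta-tests for every season x family.

    COVID-class terms are dropped; non-estimable per-term results are
    skipped.  Raises on terms with no class label.
    """
    out = []
    for family in families:
        if family not in FAMILIES:
            raise InputError(f"unknown family {family!r}")
        for season in seasons:
            a, b = _collect(results, metas, family, season)
            if not a or not b:
                raise InputError(f"empty class group for {family}/{season}")
            wp = wilcoxon_group_test(a, b)
            fp, table = fisher_group_test(a, b, alpha)
            out.append(GroupTestResult(season, family, wp, fp, table, len(a), len(b)))
    return out
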