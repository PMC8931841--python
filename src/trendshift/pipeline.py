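"""End-to-end blinded analysis: filter, branch, test, characterize, compare.

``run_pipeline`` takes weekly series plus term metadata and produces

* a per-term table (seasonality P/AtM/peak week, per-season two-sided and
  one-sided P values, effects, directions, branch) with BH-FDR-adjusted
  companions per (family x season),
* a group table of communicable-vs-noncommunicable Wilcoxon/Fisher tests
  per season and family,
* a per-season Theil-Sen/Kendall association between each term's
  seasonality P and reduction P,
* a run log (branch counts, seeds, settings).

With masking enabled the whole analysis runs on numeric codes and the
tables are unmasked only at the end; since every statistic ignores the
labels, masked and unmasked runs agree exactly.

``replay_group_tests`` feeds an already-published per-term P-value table
(coarsened entries coerced: "<.001" → .001, ">.99" → .99) through the same
group-level tests — the reproduction path for the published class
comparison.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .exceptions import InputError, TrendshiftError
from .group_inference import (FAMILIES, GroupTestResult, bh_fdr,
                              run_group_comparisons)
from .io import (SEASON_ORDER, Codebook, EpochConfig, SearchSeries, TermMeta,
                 format_p, mask_codebook, parse_p, write_results)
from .preprocess import (AnnotatedSeries, HampelParams, annotate, classify_branch,
                         hampel_filter, missing_or_zero_fraction)
from .seasonality import seasonality_profile, seasonality_vs_reduction
from .trend_tests import SeasonalChangeResult, season_tests

__all__ = ["RunConfig", "run_pipeline", "analyze_term", "replay_group_tests",
           "group_table", "plot_annual_overlay", "overlay_data"]


@dataclass
class RunConfig:
    """Serializable settings for a reproducible run."""

    epochs: EpochConfig = field(default_factory=EpochConfig)
    hampel: HampelParams = field(default_factory=HampelParams)
    alpha: float = 0.05
    n_surrogates: int = 1000
    wavelet_seed: int = 0
    mask_seed: int = 0
    masking: bool = False
    fdr_within_family_season: bool = True
    group_tests_on_corrected: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["epochs"] = {k: (v.isoformat() if isinstance(v, _dt.date) else
                           {s: sorted(m) for s, m in v.items()})
                       for k, v in dataclasses.asdict(self.epochs).items()}
        return d


def analyze_term(series: SearchSeries, config: RunConfig):
    """Single-term analysis: filter → branch → season tests → seasonality.

    Returns ``(annotated, season_results, seasonality)``; the annotated
    series holds the Hampel-filtered values with the branch decided on the
    raw series.
    """
    frac = missing_or_zero_fraction(series)
    branch = classify_branch(series)
    filtered = hampel_filter(series, config.hampel)
    annot = annotate(filtered, config.epochs, branch=branch, missing_fraction=frac)
    results = season_tests(annot, alpha=config.alpha)
    season_prof = seasonality_profile(annot, n_surrogates=config.n_surrogates,
                                      seed=config.wavelet_seed, alpha=config.alpha)
    return annot, results, season_prof


def _term_row(term: str, meta: TermMeta, annot: AnnotatedSeries,
              results: dict[str, SeasonalChangeResult], prof) -> dict:
    row = {"term": term, "class": meta.class_label, "geolocation": meta.geolocation,
           "branch": annot.branch, "missing_fraction": annot.missing_fraction,
           "seasonality_p": prof.p_seasonal, "atm": prof.atm, "atm_sd": prof.atm_sd,
           "peak_week": prof.peak_week, "peak_week_sd": prof.peak_week_sd}
    for s in SEASON_ORDER:
        r = results[s]
        row[f"p_two_{s}"] = r.p_two
        row[f"p_one_{s}"] = r.p_one_decrease
        row[f"effect_{s}"] = r.effect
        row[f"direction_{s}"] = r.direction if r.estimable else "not-estimable"
    return row


def _apply_fdr(term_table: pd.DataFrame) -> pd.DataFrame:
    """BH-adjusted companions, corrected within each (family x season) and
    for the seasonality family, across terms."""
    df = term_table.copy()
    for col in [f"p_two_{s}" for s in SEASON_ORDER] + \
               [f"p_one_{s}" for s in SEASON_ORDER] + ["seasonality_p"]:
        p = pd.to_numeric(df[col])
        ok = p.notna()
        adj = p.copy()
        if ok.any():
            adj[ok] = bh_fdr(p[ok].to_numpy())
        df[col + "_fdr"] = adj
    return df


def group_table(group_results: list[GroupTestResult]) -> pd.DataFrame:
    rows = []
    for g in group_results:
        rows.append({"season": g.season, "family": g.family,
                     "wilcoxon_p": g.wilcoxon_p, "fisher_p": g.fisher_p,
                     "communicable_sig": int(g.table2x2[0, 0]),
                     "communicable_not": int(g.table2x2[0, 1]),
                     "noncommunicable_sig": int(g.table2x2[1, 0]),
                     "noncommunicable_not": int(g.table2x2[1, 1])})
    return pd.DataFrame(rows)


def run_pipeline(series_list: list[SearchSeries], metas: list[TermMeta],
                 config: RunConfig | None = None, outdir=None) -> dict:
    """Run the full analysis; returns a result bundle.

    Bundle keys: ``terms`` (per-term DataFrame), ``groups`` (class
    comparisons), ``seasonality_regression`` (per-season Theil-Sen of
    reduction P on seasonality P), ``log`` (run log string), ``codebook``
    (when masking).  With ``outdir`` set the tables are also written as
    CSV with coarsened P-value companions.
    """
    config = config or RunConfig()
    meta_by_term = {m.term: m for m in metas}
    missing = [s.term_id for s in series_list if s.term_id not in meta_by_term]
    if missing:
        raise InputError(f"terms without metadata: {missing[:5]}")

    codebook = None
    if config.masking:
        codebook = mask_codebook(metas, config.mask_seed)
        series_list = [codebook.mask_series(s) for s in series_list]
        meta_by_term = {codebook.mask_term(t): TermMeta(
            term=codebook.mask_term(t), class_label=m.class_label,
            geolocation=str(codebook.geo_to_code[m.geolocation]),
            masked_code=codebook.term_to_code[t])
            for t, m in meta_by_term.items()}

    rows, per_term_results, annots = [], [], {}
    errors = []
    for s in sorted(series_list, key=lambda s: s.term_id):
        meta = meta_by_term[s.term_id]
        try:
            annot, results, prof = analyze_term(s, config)
        except TrendshiftError as exc:
            errors.append(f"{s.term_id}: {exc}")
            continue
        annots[s.term_id] = annot
        rows.append(_term_row(s.term_id, meta, annot, results, prof))
        per_term_results.extend(results.values())
    if not rows:
        raise InputError("no term could be analyzed: " + "; ".join(errors))

    term_table = _apply_fdr(pd.DataFrame(rows))

    noncovid = [meta_by_term[t] for t in term_table["term"]
                if meta_by_term[t].class_label != "covid"]
    groups = None
    if ({m.class_label for m in noncovid} >= {"communicable", "noncommunicable"}):
        use = per_term_results
        if config.group_tests_on_corrected:
            use = _corrected_results(term_table, per_term_results)
        keep = {m.term for m in noncovid}
        use = [r for r in use if r.term_id in keep]
        groups = run_group_comparisons(use, noncovid, alpha=config.alpha)

    season_reg = _seasonality_regressions(term_table)

    if config.masking and codebook is not None:
        term_table = term_table.assign(term=[codebook.unmask_term(t)
                                             for t in term_table["term"]],
                                       geolocation=[codebook.code_to_geo[int(g)]
                                                    for g in term_table["geolocation"]])

    log = _run_log(config, term_table, errors)
    bundle = {"terms": term_table,
              "groups": group_table(groups) if groups is not None else None,
              "seasonality_regression": season_reg,
              "annotated": annots, "log": log, "codebook": codebook}
    if outdir is not None:
        tables = {"terms": term_table, "seasonality_regression": season_reg}
        if bundle["groups"] is not None:
            tables["groups"] = bundle["groups"]
        write_results(tables, outdir)
        import os

        with open(os.path.join(outdir, "run_log.txt"), "w") as fh:
            fh.write(log)
    return bundle


def _corrected_results(term_table: pd.DataFrame, results):
    adj = {(row["term"], s): (row[f"p_two_{s}_fdr"], row[f"p_one_{s}_fdr"])
           for _, row in term_table.iterrows() for s in SEASON_ORDER}
    out = []
    for r in results:
        if (r.term_id, r.season) in adj and r.estimable:
            p2, p1 = adj[(r.term_id, r.season)]
            out.append(dataclasses.replace(r, p_two=p2, p_one_decrease=p1))
        else:
            out.append(r)
    return out


def _seasonality_regressions(term_table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    sub = term_table[term_table["class"] != "covid"]
    for s in SEASON_ORDER:
        x = pd.to_numeric(sub["seasonality_p"]).to_numpy()
        y = pd.to_numeric(sub[f"p_one_{s}"]).to_numpy()
        try:
            slope, p = seasonality_vs_reduction(x, y)
        except InputError:
            slope, p = np.nan, np.nan
        rows.append({"season": s, "theilsen_slope": slope, "kendall_p": p})
    return pd.DataFrame(rows)


def _run_log(config: RunConfig, term_table: pd.DataFrame, errors: list[str]) -> str:
    counts = term_table["branch"].value_counts().to_dict()
    lines = [f"trendshift {_version}",
             f"terms analyzed: {len(term_table)}",
             f"branch counts: {counts}",
             f"config: {config.to_dict()}"]
    if errors:
        lines.append("skipped terms: " + "; ".join(errors))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Published-table replay


def replay_group_tests(panel: pd.DataFrame, alpha: float = 0.05,
                       families=FAMILIES) -> pd.DataFrame:
    """Group tests on an already-published per-term P-value table.

    ``panel`` needs columns ``term``, ``class`` and per-season P columns
    ``p_two_<season>`` / ``p_one_<season>`` whose entries may be coarsened
    strings; these are coerced ("<.001" → .001, ">.99" → .99) before the
    Wilcoxon and Fisher tests run exactly as in the live pipeline.
    """
    metas = [TermMeta(term=str(r["term"]), class_label=str(r["class"]))
             for _, r in panel.iterrows()]
    results = []
    for _, r in panel.iterrows():
        for s in SEASON_ORDER:
            results.append(SeasonalChangeResult(
                term_id=str(r["term"]), season=s,
                p_two=parse_p(r[f"p_two_{s}"]), p_one_decrease=parse_p(r[f"p_one_{s}"]),
                effect=np.nan, branch="replay"))
    return group_table(run_group_comparisons(results, metas, families=families,
                                             alpha=alpha))


# ---------------------------------------------------------------------------
# Plotting


def overlay_data(annot: AnnotatedSeries) -> pd.DataFrame:
    """Data behind the annual overlay: log(value+1) by week-of-year and year group.

    Year groups follow the presentation convention: 2011-2013, 2014-2016,
    2017-2019, 2020, 2021 (calendar year of the week start).
    """
    ts = pd.DatetimeIndex(annot.base.week_starts)
    vals = np.where(annot.base.missing_mask, np.nan, annot.base.values)
    woy = np.minimum(np.asarray(ts.isocalendar().week, dtype=int), 52)

    def group(y: int) -> str:
        if y <= 2013:
            return "2011-2013"
        if y <= 2016:
            return "2014-2016"
        if y <= 2019:
            return "2017-2019"
        return str(y)

    df = pd.DataFrame({"week_of_year": woy,
                       "year_group": [group(y) for y in ts.year],
                       "log_value": np.log1p(vals)})
    return (df.groupby(["year_group", "week_of_year"], as_index=False)["log_value"]
            .mean())


def plot_annual_overlay(annot: AnnotatedSeries, results=None, path=None,
                        title: str | None = None):
    """Annual overlay plot: one log(value+1) line per year group.

    Season boundaries are dashed verticals; per-season P values (when
    ``results`` given) are annotated along the top.  Plotting failures are
    logged and swallowed — figures are presentation, not analysis.
    """
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = overlay_data(annot)
        fig, ax = plt.subplots(figsize=(8, 4))
        for grp, sub in df.groupby("year_group"):
            sub = sub.sort_values("week_of_year")
            style = "--" if grp == "2021" else "-"
            color = {"2020": "tab:red", "2021": "tab:red"}.get(grp)
            ax.plot(sub["week_of_year"], sub["log_value"], style, label=grp,
                    color=color, lw=1.4 if color else 1.0)
        for wk in (9, 22, 35, 48):  # approx. 1 Mar / 1 Jun / 1 Sep / 1 Dec
            ax.axvline(wk, ls="--", color="grey", lw=0.6)
        if results:
            for i, s in enumerate(SEASON_ORDER):
                r = results.get(s)
                if r is not None and r.estimable:
                    ax.annotate(f"{s[:2]}: {format_p(r.p_two)}/{format_p(r.p_one_decrease)}",
                                ((9, 22, 35, 48)[i] + 1, ax.get_ylim()[1]),
                                fontsize=7, va="top")
        ax.set_xlabel("week of year")
        ax.set_ylabel("log(search interest + 1)")
        ax.set_title(title or annot.base.term_id)
        ax.legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig
    except Exception as exc:  # pragma: no cover - presentation only
        import logging

        logging.getLogger(__name__).warning("plotting failed: %s", exc)
        return None
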