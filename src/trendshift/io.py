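"""Weekly search-interest series I/O, epoch configuration and the masking codec.

Search-interest exports provide, per term and geolocation, one relative
search volume (RSV) value per week on a 0-100 scale: the term's share of all
searches in that week and place, rescaled by the provider.  Weeks where the
provider returned nothing are *missing*; weeks reported as exactly zero mean
"below the provider's privacy threshold" and are kept as value 0 with a flag
rather than silently converted to missing.

The masking codec replaces term names, class labels and geolocations with
opaque numeric codes so the statistical analysis can be run blind to which
series is which; a bijective codebook restores the labels afterwards.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConflictError, InputError, ParseError

__all__ = [
    "SearchSeries",
    "TermMeta",
    "EpochConfig",
    "Codebook",
    "SEASON_ORDER",
    "CLASS_LABELS",
    "read_series_table",
    "read_meta_table",
    "mask_codebook",
    "write_results",
    "format_p",
    "parse_p",
    "load_reference_panel",
]

#: Fixed season order used throughout (study years run March..February).
SEASON_ORDER = ("spring", "summer", "autumn", "winter")

#: Closed set of a-priori term classes.
CLASS_LABELS = ("covid", "communicable", "noncommunicable")

_WEEK = np.timedelta64(7, "D")


@dataclass
class SearchSeries:
    """One term's weekly RSV series on a complete 7-day grid.

    ``missing_mask`` is true where the export had no row for that week;
    zero-valued weeks are *not* missing (``values`` holds 0 there).
    """

    term_id: str
    geolocation: str
    week_starts: np.ndarray  # datetime64[D], strictly increasing, 7-day spacing
    values: np.ndarray  # float, >= 0 where not missing (nan where missing)
    missing_mask: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.week_starts = np.asarray(self.week_starts, dtype="datetime64[D]")
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n = len(self.week_starts)
        if not (len(self.values) == n == len(self.missing_mask)):
            raise InputError(f"series '{self.term_id}': field lengths differ")
        if n > 1:
            diffs = np.diff(self.week_starts)
            if not np.all(diffs == _WEEK):
                raise InputError(
                    f"series '{self.term_id}': week_starts must be strictly "
                    "increasing with 7-day spacing"
                )
        ok = ~self.missing_mask
        if np.any(self.values[ok] < 0) or np.any(~np.isfinite(self.values[ok])):
            raise InputError(f"series '{self.term_id}': non-missing values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.week_starts)

    @property
    def zero_mask(self) -> np.ndarray:
        """Weeks reported as exactly zero (present but below threshold)."""
        return (~self.missing_mask) & (self.values == 0)

    def replace(self, values: np.ndarray) -> "SearchSeries":
        """Copy of this series with new values (same grid and mask)."""
        return SearchSeries(self.term_id, self.geolocation, self.week_starts.copy(),
                            np.asarray(values, float).copy(), self.missing_mask.copy())


@dataclass(frozen=True)
class TermMeta:
    """Term metadata: the phrase, its opaque code and a-priori class."""

    term: str
    class_label: str
    geolocation: str = "US"
    masked_code: int | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise InputError(
                f"term '{self.term}': class_label must be one of {CLASS_LABELS}, "
                f"got '{self.class_label}'"
            )


def _month_season(month: int, season_definitions: dict[str, frozenset[int]]) -> str:
    for label, months in season_definitions.items():
        if month in months:
            return label
    raise InputError(f"month {month} not covered by season definitions")


@dataclass(frozen=True)
class EpochConfig:
    """Analysis window and season layout.

    Defaults reproduce the study design: a 9-year pre-intervention baseline
    (March 2011 - February 2020), intervention at 2020-03-01, analysis ending
    2021-02-28, with meteorological seasons (winter = Dec + following Jan/Feb).
    """

    baseline_start: _dt.date = _dt.date(2011, 3, 1)
    intervention_date: _dt.date = _dt.date(2020, 3, 1)
    analysis_end: _dt.date = _dt.date(2021, 2, 28)
    season_definitions: dict = field(default_factory=lambda: {
        "spring": frozenset({3, 4, 5}),
        "summer": frozenset({6, 7, 8}),
        "autumn": frozenset({9, 10, 11}),
        "winter": frozenset({12, 1, 2}),
    })

    def __post_init__(self) -> None:
        if not (self.baseline_start < self.intervention_date < self.analysis_end):
            raise InputError("require baseline_start < intervention_date < analysis_end")
        months = [m for s in self.season_definitions.values() for m in s]
        if sorted(months) != list(range(1, 13)) or any(
            len(s) != 3 for s in self.season_definitions.values()
        ):
            raise InputError("season_definitions must partition the 12 months into 4 blocks of 3")

    def season_of(self, month: int) -> str:
        return _month_season(month, self.season_definitions)


# ---------------------------------------------------------------------------
# Reading


def _to_date(x, row: int) -> np.datetime64:
    try:
        d = pd.Timestamp(x)
        if pd.isna(d):
            raise ValueError
        return np.datetime64(d.date(), "D")
    except (ValueError, TypeError):
        raise ParseError(f"row {row}: malformed date {x!r}") from None


def _to_value(x, row: int) -> float:
    if pd.isna(x):
        return np.nan
    try:
        v = float(x)
    except (ValueError, TypeError):
        raise ParseError(f"row {row}: non-numeric value {x!r}") from None
    if v < 0:
        raise ParseError(f"row {row}: negative RSV value {v}")
    return v


def _build_series(term: str, geo: str, dates: list, values: list, rows: list) -> SearchSeries:
    order = np.argsort(np.asarray(dates))
    dates = [dates[i] for i in order]
    values = [values[i] for i in order]
    rows = [rows[i] for i in order]
    seen = {}
    for d, r in zip(dates, rows):
        if d in seen:
            raise ConflictError(f"row {r}: duplicate (term={term!r}, week={d})")
        seen[d] = r
    first, last = dates[0], dates[-1]
    for d, r in zip(dates, rows):
        if (d - first) % _WEEK != np.timedelta64(0, "D"):
            raise ParseError(
                f"row {r}: date {d} is not on the weekly grid anchored at {first}"
            )
    grid = np.arange(first, last + _WEEK, _WEEK)
    vals = np.full(len(grid), np.nan)
    miss = np.ones(len(grid), dtype=bool)
    idx = {d: i for i, d in enumerate(grid)}
    for d, v in zip(dates, values):
        i = idx[d]
        if np.isnan(v):
            continue  # blank value cell -> missing week
        vals[i] = v
        miss[i] = False
    return SearchSeries(term, geo, grid, vals, miss)


def read_series_table(path, dialect: str = "long", geolocation: str = "US") -> list[SearchSeries]:
    """Read weekly RSV series from CSV.

    ``dialect='long'`` expects columns ``term, date, value`` (optionally
    ``geolocation``); ``dialect='wide'`` expects a ``date`` column plus one
    column per term.  Gaps in each term's weekly grid become missing weeks;
    dates off the 7-day grid anchored at the term's first week are rejected.
    """
    df = pd.read_csv(path, dtype=str)
    out: list[SearchSeries] = []
    if dialect == "long":
        required = {"term", "date", "value"}
        if not required.issubset(df.columns):
            raise ParseError(f"long dialect needs columns {sorted(required)}")
        has_geo = "geolocation" in df.columns
        for term, sub in df.groupby("term", sort=True):
            dates, values, rows = [], [], []
            geo = geolocation
            for row, rec in sub.iterrows():
                dates.append(_to_date(rec["date"], row))
                values.append(_to_value(rec["value"], row))
                rows.append(row)
                if has_geo and not pd.isna(rec["geolocation"]):
                    geo = rec["geolocation"]
            out.append(_build_series(str(term), geo, dates, values, rows))
    elif dialect == "wide":
        if "date" not in df.columns:
            raise ParseError("wide dialect needs a 'date' column")
        terms = [c for c in df.columns if c != "date"]
        dates = [_to_date(d, i) for i, d in enumerate(df["date"])]
        for term in terms:
            values = [_to_value(v, i) for i, v in enumerate(df[term])]
            out.append(_build_series(term, geolocation, list(dates), values,
                                     list(range(len(dates)))))
    else:
        raise InputError(f"unknown dialect {dialect!r}")
    return out


def read_meta_table(path) -> list[TermMeta]:
    """Read term metadata CSV with columns ``term, class`` (+ ``geolocation``)."""
    df = pd.read_csv(path, dtype=str)
    if not {"term", "class"}.issubset(df.columns):
        raise ParseError("metadata CSV needs columns term, class")
    metas = []
    for row, rec in df.iterrows():
        geo = rec.get("geolocation", "US")
        if pd.isna(geo):
            geo = "US"
        metas.append(TermMeta(term=str(rec["term"]), class_label=str(rec["class"]),
                              geolocation=str(geo)))
    if len({m.term for m in metas}) != len(metas):
        raise ConflictError("duplicate terms in metadata")
    return metas


# ---------------------------------------------------------------------------
# Masking codec


@dataclass
class Codebook:
    """Bijective term/class/geolocation <-> numeric-code maps for blinding."""

    term_to_code: dict[str, int]
    class_to_code: dict[str, int]
    geo_to_code: dict[str, int]

    @property
    def code_to_term(self) -> dict[int, str]:
        return {v: k for k, v in self.term_to_code.items()}

    @property
    def code_to_class(self) -> dict[int, str]:
        return {v: k for k, v in self.class_to_code.items()}

    @property
    def code_to_geo(self) -> dict[int, str]:
        return {v: k for k, v in self.geo_to_code.items()}

    def mask_term(self, term: str) -> str:
        return str(self.term_to_code[term])

    def unmask_term(self, code: str) -> str:
        return self.code_to_term[int(code)]

    def mask_series(self, s: SearchSeries) -> SearchSeries:
        return SearchSeries(self.mask_term(s.term_id), str(self.geo_to_code[s.geolocation]),
                            s.week_starts, s.values, s.missing_mask)

    def unmask_series(self, s: SearchSeries) -> SearchSeries:
        return SearchSeries(self.unmask_term(s.term_id), self.code_to_geo[int(s.geolocation)],
                            s.week_starts, s.values, s.missing_mask)

    def mask_meta(self, m: TermMeta) -> TermMeta:
        return TermMeta(term=self.mask_term(m.term),
                        class_label=m.class_label,  # class handled separately in tables
                        geolocation=str(self.geo_to_code[m.geolocation]),
                        masked_code=self.term_to_code[m.term])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"terms": self.term_to_code, "classes": self.class_to_code,
                       "geolocations": self.geo_to_code}, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["terms"], d["classes"], d["geolocations"])


def mask_codebook(metas: list[TermMeta], seed: int) -> Codebook:
    """Build a deterministic codebook for a fixed seed.

    Codes are a seeded random permutation so the numeric order carries no
    information about the alphabetical order of the terms.
    """
    terms = [m.term for m in metas]
    if len(set(terms)) != len(terms):
        raise ConflictError("duplicate terms supplied to mask_codebook")
    rng = np.random.default_rng(seed)
    term_codes = rng.permutation(len(terms)) + 101
    classes = sorted({m.class_label for m in metas})
    class_codes = rng.permutation(len(classes)) + 1
    geos = sorted({m.geolocation for m in metas})
    geo_codes = rng.permutation(len(geos)) + 11
    return Codebook(
        term_to_code={t: int(c) for t, c in zip(sorted(terms), term_codes)},
        class_to_code={g: int(c) for g, c in zip(classes, class_codes)},
        geo_to_code={g: int(c) for g, c in zip(geos, geo_codes)},
    )


# ---------------------------------------------------------------------------
# P-value rendering and result output


def format_p(p: float) -> str:
    """Render a P value with the results-table coarsening convention.

    Values below .001 print as ``<.001``, above .99 as ``>.99``; everything
    else is shown to 2 significant figures without the leading zero.
    """
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    if not 0 <= p <= 1:
        raise InputError(f"P value out of [0,1]: {p}")
    if p < 0.001:
        return "<.001"
    if p > 0.99:
        return ">.99"
    s = f"{p:.2g}"
    return s[1:] if s.startswith("0.") else s


def parse_p(s) -> float:
    """Parse a possibly coarsened P value string back to a float.

    Coarsened bounds are coerced to their edge: ``<.001`` → 0.001 and
    ``>.99`` → 0.99 (used when replaying published tables through the
    group-level tests).
    """
    if isinstance(s, (int, float)):
        return float(s)
    t = str(s).strip().replace(" ", "")
    if not t:
        return float("nan")
    sign = ""
    if t[0] in "<>":
        sign, t = t[0], t[1:]
    if not t.startswith(".") and not t.startswith("0."):
        # tolerate a dropped decimal point after < or >, e.g. "<001"
        t = "." + t.lstrip(".")
    try:
        v = float("0" + t if t.startswith(".") else t)
    except ValueError:
        raise ParseError(f"cannot parse P value {s!r}") from None
    if not 0 <= v <= 1:
        raise ParseError(f"P value out of [0,1]: {s!r}")
    return v


def write_results(results: dict[str, pd.DataFrame], outdir) -> dict[str, str]:
    """Write result tables as CSV, coarsening every ``*_p``-style column.

    ``results`` maps a table name (e.g. ``terms``, ``groups``) to a
    DataFrame.  For each column whose name ends in ``_p`` or contains
    ``p_``, a companion ``<col>_printed`` column holds the coarsened
    rendering while the original keeps full precision.  Returns the paths
    written.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in results.items():
        df = df.copy()
        for col in list(df.columns):
            if col.endswith("_p") or col.startswith("p_") or "_p_" in col:
                df[col + "_printed"] = [
                    format_p(v) if v == v else "" for v in pd.to_numeric(df[col])
                ]
        path = os.path.join(outdir, f"{name}.csv")
        df.to_csv(path, index=False)
        paths[name] = path
    return paths


def load_reference_panel() -> pd.DataFrame:
    """Published per-term P values for the 52 non-COVID US panel terms.

    Columns: term, class, seasonality_p, two-sided change P per season
    (``p_two_<season>``) and one-sided reduction P per season
    (``p_one_<season>``), all as printed (coarsened strings).  Companion
    ``*_num`` columns hold the coerced numeric values.  These are the inputs
    to the group-level replay of the class comparison.
    """
    with resources.files("trendshift").joinpath(
        "data/us_noncovid_panel_pvalues.csv"
    ).open() as fh:
        df = pd.read_csv(fh, dtype=str)
    for col in df.columns:
        if col.startswith(("seasonality_p", "p_two_", "p_one_")):
            df[col + "_num"] = [parse_p(v) for v in df[col]]
    return df
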