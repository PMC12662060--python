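"""Survey data model and long-format colony-record I/O.

A bleaching survey records, for every 1 m² quadrat deployed at a station,
the number of coral colonies of each genus falling into each of six ordered
health categories:

====  ========  =======================================
code  weight    meaning (share of the colony affected)
====  ========  =======================================
C1    0         Healthy (<1% bleached or dead)
C2    1         Low (1–10%)
C3    2         Medium (10–50%)
C4    3         High (50–90%)
C5    4         Extreme (>90%)
C6    5         Dead (recently or long dead)
====  ========  =======================================

The canonical on-disk form is long-format CSV with header
``site,station,period,quadrat,genus,category,count``.  Field datasets
exported from survey workbooks ("supplementary-wide" dialect) are mapped
onto this form by :func:`read_survey` with an explicit column map.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "HealthCategory",
    "CATEGORIES",
    "CATEGORY_CODES",
    "CATEGORY_WEIGHTS",
    "HYDROCORAL_TAXA",
    "SiteDesign",
    "SurveyDesign",
    "SurveyDataset",
    "normalize_category",
    "normalize_genus",
    "read_survey",
    "write_survey",
    "aggregate_counts",
]


@dataclass(frozen=True)
class HealthCategory:
    """One of the six ordered colony health categories."""

    code: str
    weight: int
    label: str
    bleach_range: str


CATEGORIES: tuple[HealthCategory, ...] = (
    HealthCategory("C1", 0, "Healthy", "<1% bleached or dead"),
    HealthCategory("C2", 1, "Low", "1-10% bleached"),
    HealthCategory("C3", 2, "Medium", "10-50% bleached"),
    HealthCategory("C4", 3, "High", "50-90% bleached"),
    HealthCategory("C5", 4, "Extreme", ">90% bleached"),
    HealthCategory("C6", 5, "Dead", "recently or long dead"),
)

CATEGORY_CODES: tuple[str, ...] = tuple(c.code for c in CATEGORIES)
CATEGORY_WEIGHTS: dict[str, int] = {c.code: c.weight for c in CATEGORIES}

#: Calcareous hydrocorals surveyed alongside scleractinians; can be excluded
#: from "hard coral" summaries via the ``include_hydrocorals`` flags.
HYDROCORAL_TAXA: frozenset[str] = frozenset({"Millepora"})

# Accepted spellings for each category code (lower-cased keys).
_CATEGORY_ALIASES: dict[str, str] = {}
for _cat in CATEGORIES:
    _CATEGORY_ALIASES[_cat.code.lower()] = _cat.code
    _CATEGORY_ALIASES[_cat.label.lower()] = _cat.code
    _CATEGORY_ALIASES[str(_cat.weight + 1)] = _cat.code  # 1..6 numeric coding


def normalize_category(label: object) -> str:
    """Map a raw category label to its canonical code ``C1``..``C6``.

    Accepts the codes themselves (any case), the labels (``Healthy`` ...
    ``Dead``) and plain ``1``..``6``.  Idempotent on canonical codes.

    Raises
    ------
    ValidationError
        If the label matches no known category.
    """
    key = str(label).strip().lower()
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise ValidationError(f"unknown health category label: {label!r}") from None


_WS = re.compile(r"\s+")


def normalize_genus(name: object) -> str:
    """Canonicalise a taxon name: trimmed, single-spaced, genus capitalised.

    All-lower or all-upper input is recased with the genus word (last
    token) capitalised and growth-form qualifiers lower-case, so
    ``"MASSIVE PORITES"`` and ``"massive porites"`` both map to
    ``"massive Porites"``.  Mixed-case input is trusted as already
    canonical and only whitespace-normalised.  Idempotent.
    """
    cleaned = _WS.sub(" ", str(name).strip())
    if not cleaned:
        raise ValidationError("empty genus name")
    if not (cleaned.islower() or cleaned.isupper()):
        return cleaned
    words = cleaned.split(" ")
    head = [w.lower() for w in words[:-1]]
    return " ".join(head + [words[-1].capitalize()])


@dataclass(frozen=True)
class SiteDesign:
    """Sampling design for one reef site."""

    name: str
    stations: tuple[str, ...]
    quadrats_per_station: int = 20
    quadrat_area_m2: float = 1.0

    def __post_init__(self) -> None:
        if self.quadrat_area_m2 <= 0:
            raise ValidationError(f"quadrat area must be positive, got {self.quadrat_area_m2}")
        if self.quadrats_per_station <= 0:
            raise ValidationError("quadrats_per_station must be positive")


@dataclass(frozen=True)
class SurveyDesign:
    """The full survey layout: sites, stations, quadrats, and the two periods."""

    sites: tuple[SiteDesign, ...]
    periods: tuple[str, str] = ("during", "after")

    def site(self, name: str) -> SiteDesign:
        for s in self.sites:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def site_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sites)

    @property
    def station_site(self) -> dict[str, str]:
        """Map station name -> site name."""
        return {st: s.name for s in self.sites for st in s.stations}

    @property
    def n_stations(self) -> int:
        return sum(len(s.stations) for s in self.sites)


#: Canonical record columns, in storage order.
RECORD_COLUMNS = ["site", "station", "period", "quadrat", "genus", "category", "count"]
KEY_COLUMNS = RECORD_COLUMNS[:-1]


class SurveyDataset:
    """Validated colony records plus the design they were collected under.

    ``records`` is a pandas DataFrame with the canonical columns; duplicate
    keys are summed on construction so that
    (site, station, period, quadrat, genus, category) is unique.
    """

    def __init__(self, records: pd.DataFrame, design: SurveyDesign | None = None):
        df = records.copy()
        missing = [c for c in RECORD_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for col in KEY_COLUMNS:
            df[col] = df[col].astype(str)
        df["category"] = df["category"].map(normalize_category)
        df["genus"] = df["genus"].map(normalize_genus)
        counts = pd.to_numeric(df["count"], errors="raise")
        if (counts < 0).any():
            bad = df.index[counts < 0][0]
            raise ValidationError(f"negative colony count at record index {bad}")
        df["count"] = counts.astype(int)
        # Collapse duplicate keys by summing counts.
        df = (
            df.groupby(KEY_COLUMNS, as_index=False, sort=True)["count"]
            .sum()
            .loc[:, RECORD_COLUMNS]
        )
        if design is None:
            design = _infer_design(df)
        _check_against_design(df, design)
        self.records = df.reset_index(drop=True)
        self.design = design

    # ------------------------------------------------------------------
    @property
    def total_count(self) -> int:
        return int(self.records["count"].sum())

    @property
    def periods(self) -> tuple[str, str]:
        return self.design.periods

    def subset(self, **selector: object) -> pd.DataFrame:
        """Records matching equality constraints, e.g. ``subset(period="during")``."""
        df = self.records
        for key, value in selector.items():
            if key not in KEY_COLUMNS:
                raise KeyError(f"unknown selector key: {key}")
            df = df[df[key] == str(value)]
        return df

    def taxa(self) -> list[str]:
        """Taxa ordered by total abundance (descending), ties alphabetical."""
        totals = self.records.groupby("genus")["count"].sum()
        return list(totals.sort_values(ascending=False, kind="stable").index)

    def without_hydrocorals(self) -> "SurveyDataset":
        keep = ~self.records["genus"].isin(HYDROCORAL_TAXA)
        return SurveyDataset(self.records[keep], self.design)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return self.records.equals(other.records)

    def __repr__(self) -> str:
        return (
            f"SurveyDataset({len(self.records)} records, {self.total_count} colonies, "
            f"{len(self.design.sites)} sites)"
        )


def _infer_design(df: pd.DataFrame) -> SurveyDesign:
    """Reconstruct a minimal design from the records themselves.

    Quadrats-per-station defaults to the survey standard of 20 (1 m² each)
    unless the data name more quadrats at some station.
    """
    sites = []
    for site_name, grp in df.groupby("site", sort=True):
        stations = tuple(sorted(grp["station"].unique()))
        n_quadrats = 20
        for _, sgrp in grp.groupby("station"):
            n_quadrats = max(n_quadrats, sgrp["quadrat"].nunique())
        sites.append(SiteDesign(str(site_name), stations, quadrats_per_station=n_quadrats))
    periods = sorted(df["period"].unique())
    if set(periods) <= {"during", "after"}:
        period_pair = ("during", "after")
    elif len(periods) == 2:
        period_pair = (periods[0], periods[1])
    elif len(periods) == 1:
        period_pair = (periods[0], "after" if periods[0] != "after" else "during")
    else:
        raise ValidationError(f"expected at most two periods, found {periods}")
    return SurveyDesign(tuple(sites), period_pair)


def _check_against_design(df: pd.DataFrame, design: SurveyDesign) -> None:
    known_sites = set(design.site_names)
    bad_sites = set(df["site"].unique()) - known_sites
    if bad_sites:
        raise ValidationError(f"site(s) not in design: {sorted(bad_sites)}")
    station_site = design.station_site
    for site_name, station in df[["site", "station"]].drop_duplicates().itertuples(index=False):
        if station_site.get(station) != site_name:
            raise ValidationError(f"station {station!r} not in design for site {site_name!r}")
    bad_periods = set(df["period"].unique()) - set(design.periods)
    if bad_periods:
        raise ValidationError(f"period(s) not in design: {sorted(bad_periods)}")


# ----------------------------------------------------------------------
# Reading and writing


#: Default column map for the supplementary-wide dialect (survey workbook
#: export).  Keys are canonical names, values the workbook column headers.
DEFAULT_WIDE_COLUMN_MAP: dict[str, object] = {
    "site": "Site",
    "station": "Station",
    "period": "Season",
    "quadrat": "Quadrant",
    "genus": "Genus",
    "category": "Bleaching status",
    "count": "Count",
    # Month-of-survey labels used in place of during/after.
    "period_map": {"march": "during", "august": "after", "during": "during", "after": "after"},
}


def read_survey(
    path: str | os.PathLike | io.IOBase,
    dialect: str = "canonical-long",
    column_map: Mapping[str, object] | None = None,
    design: SurveyDesign | None = None,
) -> SurveyDataset:
    """Read colony records from delimited text.

    Parameters
    ----------
    path
        CSV file (or open text handle).  Lines starting with ``#`` are
        treated as comments.
    dialect
        ``"canonical-long"`` expects the canonical header; the ``count``
        column may be omitted, in which case each row is one colony.
        ``"supplementary-wide"`` accepts a survey-workbook layout: key
        columns named per ``column_map``, and either a single category
        column (one row per colony, or with a count column) or six
        ``C1``..``C6`` count columns.
    column_map
        Overrides for the supplementary dialect's column names; see
        :data:`DEFAULT_WIDE_COLUMN_MAP`.  May include ``period_map``, a
        mapping of raw period/season labels to ``during``/``after``.
    design
        Optional explicit design; inferred from the data when omitted.
    """
    raw = pd.read_csv(path, comment="#", dtype=str)
    if dialect == "canonical-long":
        df = _from_canonical(raw)
    elif dialect == "supplementary-wide":
        df = _from_wide(raw, column_map)
    else:
        raise FormatError(f"unknown dialect: {dialect!r}")
    return SurveyDataset(df, design)


def _from_canonical(raw: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in KEY_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = raw.copy()
    if "count" not in df.columns:
        df["count"] = 1
    _validate_rows(df)
    return df[RECORD_COLUMNS]


def _from_wide(raw: pd.DataFrame, column_map: Mapping[str, object] | None) -> pd.DataFrame:
    cmap = dict(DEFAULT_WIDE_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    rename = {}
    for canonical in ("site", "station", "period", "quadrat", "genus"):
        source = str(cmap[canonical])
        if source not in raw.columns:
            raise FormatError(f"missing required column: {source} (for {canonical})")
        rename[source] = canonical
    df = raw.rename(columns=rename)

    wide_codes = [c for c in CATEGORY_CODES if c in df.columns]
    if len(wide_codes) == len(CATEGORY_CODES):
        # One count column per category: melt to long.
        df = df.melt(
            id_vars=["site", "station", "period", "quadrat", "genus"],
            value_vars=list(CATEGORY_CODES),
            var_name="category",
            value_name="count",
        )
        df["count"] = pd.to_numeric(df["count"], errors="coerce").fillna(0).astype(int)
        df = df[df["count"] > 0]
    else:
        cat_col = str(cmap["category"])
        if cat_col not in df.columns:
            raise FormatError(
                f"missing required column: {cat_col} (for category), "
                f"and no C1..C6 count columns found"
            )
        df = df.rename(columns={cat_col: "category"})
        count_col = str(cmap.get("count", "Count"))
        if count_col in df.columns:
            df = df.rename(columns={count_col: "count"})
        else:
            df["count"] = 1  # one row per colony

    period_map = {str(k).lower(): v for k, v in dict(cmap.get("period_map") or {}).items()}
    if period_map:
        df["period"] = df["period"].map(lambda p: period_map.get(str(p).strip().lower(), p))
    _validate_rows(df)
    return df[RECORD_COLUMNS]


def _validate_rows(df: pd.DataFrame) -> None:
    """Row-addressed validation so errors cite the offending data row
    (1-based, not counting the header)."""
    for idx, label in df["category"].items():
        try:
            normalize_category(label)
        except ValidationError:
            raise ValidationError(
                f"unknown health category {label!r} on data row {int(idx) + 1}"
            ) from None
    counts = pd.to_numeric(df["count"], errors="coerce")
    if counts.isna().any():
        idx = int(df.index[counts.isna()][0])
        raise ValidationError(f"non-numeric count on data row {idx + 1}")
    if (counts < 0).any():
        idx = int(df.index[counts < 0][0])
        raise ValidationError(f"negative count on data row {idx + 1}")


def write_survey(dataset: SurveyDataset, path: str | os.PathLike | io.IOBase) -> str | os.PathLike:
    """Write a dataset in canonical long format.  Round-trips exactly."""
    dataset.records.to_csv(path, index=False, columns=RECORD_COLUMNS)
    return path


# ----------------------------------------------------------------------
# Aggregation


def aggregate_counts(
    dataset: SurveyDataset, stratum: Sequence[str] | Iterable[str]
) -> pd.DataFrame:
    """Sum colony counts within ``stratum`` keys × category.

    ``stratum`` must be a non-empty subset of
    {site, station, period, quadrat, genus} and include ``period`` —
    pooling across survey periods mixes two snapshots of the same reef.
    Grand total is preserved.
    """
    keys = list(stratum)
    if not keys or "period" not in keys:
        raise ValidationError("stratum keys must be non-empty and include 'period'")
    unknown = set(keys) - {"site", "station", "period", "quadrat", "genus"}
    if unknown:
        raise ValidationError(f"unknown stratum key(s): {sorted(unknown)}")
    out = (
        dataset.records.groupby(keys + ["category"], as_index=False, sort=True)["count"]
        .sum()
    )
    return out
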