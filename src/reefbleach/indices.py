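"""Bleaching severity and susceptibility statistics.

Two indices summarise a colony-level bleaching survey:

* **BRI** (Bleaching Response Index) — a weighted average of the
  percentages P1..P6 of colonies in the six health categories,

      BRI = (0·P1 + 1·P2 + 2·P3 + 3·P4 + 4·P5 + 5·P6) / 5,

  normalised to a 0–100 scale (0 = every colony healthy, 100 = every
  colony dead).  A site's BRI pools all colonies of all genera at that
  site and period before applying the formula.

* **BSI** (Bleaching Susceptibility Index) — a community-level index:
  each genus's BRI is weighted by its relative abundance D_i (percent of
  all colonies at the site-period), summed over genera with at least
  ``min_n`` observations, and divided by the number N of included genera,

      BSI = Σ_i BRI_i · D_i / N.

  Rare taxa (< 5 colonies by default) are excluded from the sum because
  a handful of colonies can swing a genus BRI from 0 to 100.

Prevalence is the percentage of colonies showing live bleaching
(categories C2–C5); dead colonies count in the denominator but not the
numerator, so prevalence, healthy share and dead share partition 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import UndefinedIndexError, ValidationError
from .survey_io import (
    CATEGORY_CODES,
    CATEGORY_WEIGHTS,
    SurveyDataset,
    SurveyDesign,
)

__all__ = [
    "CategoryBreakdown",
    "category_breakdown",
    "bri",
    "site_bri",
    "prevalence",
    "density",
    "bsi",
    "mortality_change",
    "summary_tables",
    "BLEACHED_CODES",
]

#: Live-bleaching categories: the prevalence numerator.
BLEACHED_CODES: tuple[str, ...] = ("C2", "C3", "C4", "C5")

_WEIGHTS = np.array([CATEGORY_WEIGHTS[c] for c in CATEGORY_CODES], dtype=float)


@dataclass(frozen=True)
class CategoryBreakdown:
    """Counts and percentages over the six health categories for a stratum.

    ``empty`` flags a stratum with no colonies: counts are all zero and
    ``percentages`` is None (percentages of nothing are undefined, and
    downstream tables must be able to tell "not surveyed" from "healthy").
    """

    stratum: Mapping[str, str]
    n_total: int
    counts: tuple[int, int, int, int, int, int]

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    @property
    def percentages(self) -> tuple[float, ...] | None:
        if self.empty:
            return None
        return tuple(100.0 * c / self.n_total for c in self.counts)


def category_breakdown(dataset: SurveyDataset, **selector: object) -> CategoryBreakdown:
    """Tally colonies per health category within a stratum.

    The stratum is an equality selector over the record keys, e.g.
    ``category_breakdown(ds, period="during", site="Itampolo")``.
    An empty stratum is a valid, flagged result — not an error.
    """
    df = dataset.subset(**selector)
    by_cat = df.groupby("category")["count"].sum()
    counts = tuple(int(by_cat.get(code, 0)) for code in CATEGORY_CODES)
    return CategoryBreakdown(
        stratum={k: str(v) for k, v in selector.items()},
        n_total=int(sum(counts)),
        counts=counts,  # type: ignore[arg-type]
    )


def bri(breakdown: CategoryBreakdown) -> float:
    """Bleaching Response Index of a category breakdown, on the 0–100 scale."""
    if breakdown.empty:
        raise UndefinedIndexError(f"BRI undefined for empty stratum {dict(breakdown.stratum)}")
    pct = np.asarray(breakdown.percentages, dtype=float)
    return float(np.dot(_WEIGHTS, pct) / 5.0)


def site_bri(dataset: SurveyDataset, site: str, period: str) -> float:
    """Site-level BRI: all colonies of all genera at the site-period, pooled."""
    return bri(category_breakdown(dataset, site=site, period=period))


def prevalence(breakdown: CategoryBreakdown) -> float:
    """Percent of colonies with live bleaching (C2–C5) among all colonies."""
    if breakdown.empty:
        raise UndefinedIndexError(
            f"prevalence undefined for empty stratum {dict(breakdown.stratum)}"
        )
    bleached = sum(
        c for code, c in zip(CATEGORY_CODES, breakdown.counts) if code in BLEACHED_CODES
    )
    return 100.0 * bleached / breakdown.n_total


def density(
    dataset: SurveyDataset,
    design: SurveyDesign | None = None,
    **selector: object,
) -> tuple[float, float]:
    """Colony density (colonies per m²) over quadrats: mean and standard error.

    Every designed quadrat in the stratum contributes, including quadrats
    in which no colony was recorded (zeros): a quadrat with no corals is
    an observation of density 0, not missing data.  SE is the sample
    standard deviation over quadrats divided by √(number of quadrats).
    """
    if design is None:
        design = dataset.design
    df = dataset.subset(**selector)
    if s := selector.get("site"):
        try:
            sites = [design.site(str(s))]
        except KeyError:
            raise UndefinedIndexError(f"site {s!r} not in design") from None
    else:
        sites = list(design.sites)

    per_quadrat: list[float] = []
    for site in sites:
        stations = site.stations
        if "station" in selector:
            stations = tuple(st for st in stations if st == str(selector["station"]))
        for station in stations:
            observed = (
                df[df["station"] == station].groupby("quadrat")["count"].sum()
            )
            values = [
                float(observed.get(q, 0.0)) / site.quadrat_area_m2
                for q in _quadrat_labels(observed.index, site.quadrats_per_station)
            ]
            per_quadrat.extend(values)
    n = len(per_quadrat)
    if n == 0:
        raise UndefinedIndexError(f"no quadrats in stratum {selector}")
    arr = np.asarray(per_quadrat)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return mean, se


def _quadrat_labels(observed_labels: pd.Index, designed_n: int) -> list[str]:
    """The designed quadrat set for a station: observed labels, padded with
    placeholders up to the designed count (unsurveyed quadrats are zeros)."""
    labels = list(observed_labels)
    pad = designed_n - len(labels)
    labels += [f"__unobserved_{i}" for i in range(max(pad, 0))]
    return labels


def bsi(
    dataset: SurveyDataset, site: str, period: str, min_n: int = 5
) -> tuple[float, int]:
    """Bleaching Susceptibility Index of a site-period.

    Returns ``(bsi, n_genera)`` where ``n_genera`` is the number of taxa
    entering the sum (those with at least ``min_n`` colonies).  Relative
    abundance D_i is in percent of *all* colonies recorded at the
    site-period, so excluded rare taxa still dilute the index.
    """
    df = dataset.subset(site=site, period=period)
    total = int(df["count"].sum())
    if total == 0:
        raise UndefinedIndexError(f"no colonies at site={site!r}, period={period!r}")
    acc = 0.0
    n_genera = 0
    for genus, grp in df.groupby("genus"):
        n_i = int(grp["count"].sum())
        if n_i < min_n:
            continue
        bd = category_breakdown(dataset, site=site, period=period, genus=genus)
        d_i = 100.0 * n_i / total
        acc += bri(bd) * d_i
        n_genera += 1
    if n_genera == 0:
        raise UndefinedIndexError(
            f"no genus with >= {min_n} colonies at site={site!r}, period={period!r}"
        )
    return acc / n_genera, n_genera


def mortality_change(dataset: SurveyDataset, **selector: object) -> float:
    """Change in the dead-colony share between the two periods, in points.

    Positive means more dead colonies (as a share of those surveyed) after
    the event than during it.  Antisymmetric under swapping the periods.
    """
    if "period" in selector:
        raise ValidationError("mortality_change compares periods; do not fix one")
    p_during, p_after = dataset.periods
    shares = {}
    for period in (p_during, p_after):
        bd = category_breakdown(dataset, period=period, **selector)
        if bd.empty:
            raise UndefinedIndexError(f"no colonies in period {period!r} for {selector}")
        shares[period] = bd.percentages[CATEGORY_CODES.index("C6")]
    return shares[p_after] - shares[p_during]


def summary_tables(
    dataset: SurveyDataset,
    min_n: int = 5,
    include_hydrocorals: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the genus-level and site-level summary tables.

    Genus table: one row per taxon × period with colony count N and BRI,
    ordered by total abundance (both periods) descending.  Taxa absent in
    a period carry N=0 and a missing (NaN) BRI rather than a fake zero.

    Site table: one row per site × period with abundance, prevalence (%),
    BRI, density ± SE (colonies/m²), BSI and the number of genera that
    entered the BSI sum.
    """
    ds = dataset if include_hydrocorals else dataset.without_hydrocorals()
    p1, p2 = ds.periods

    genus_rows = []
    for genus in ds.taxa():
        for period in (p1, p2):
            bd = category_breakdown(ds, genus=genus, period=period)
            genus_rows.append(
                {
                    "genus": genus,
                    "period": period,
                    "n": bd.n_total,
                    "bri": float("nan") if bd.empty else round(bri(bd), 1),
                }
            )
    genus_table = pd.DataFrame(genus_rows, columns=["genus", "period", "n", "bri"])

    site_rows = []
    for site in ds.design.site_names:
        for period in (p1, p2):
            bd = category_breakdown(ds, site=site, period=period)
            if bd.empty:
                row = {
                    "site": site,
                    "period": period,
                    "abundance": 0,
                    "prevalence_pct": float("nan"),
                    "bri": float("nan"),
                    "density": float("nan"),
                    "density_se": float("nan"),
                    "bsi": float("nan"),
                    "n_genera_bsi": 0,
                }
            else:
                mean_d, se_d = density(ds, site=site, period=period)
                try:
                    bsi_val, n_gen = bsi(ds, site, period, min_n=min_n)
                except UndefinedIndexError:
                    bsi_val, n_gen = float("nan"), 0
                row = {
                    "site": site,
                    "period": period,
                    "abundance": bd.n_total,
                    "prevalence_pct": round(prevalence(bd), 1),
                    "bri": round(bri(bd), 1),
                    "density": round(mean_d, 1),
                    "density_se": round(se_d, 1),
                    "bsi": round(bsi_val, 1) if not math.isnan(bsi_val) else bsi_val,
                    "n_genera_bsi": n_gen,
                }
            site_rows.append(row)
    site_table = pd.DataFrame(
        site_rows,
        columns=[
            "site",
            "period",
            "abundance",
            "prevalence_pct",
            "bri",
            "density",
            "density_se",
            "bsi",
            "n_genera_bsi",
        ],
    )
    return genus_table, site_table
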