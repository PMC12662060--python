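"""Period-to-period comparison of bleached/dead relative abundance.

The survey's two snapshots (during / after the thermal-stress season) are
compared per taxon group with a matched-sample Student's t-test on
station-level relative abundances.  Stations are the pairing unit: they
persist across periods, while quadrats are re-deployed haphazardly each
time and cannot be matched.

Taxa are partitioned into the most abundant genera (those that together
pass 80% of total colony abundance, or an explicit list) plus a pooled
"Others" group, so rare taxa still enter the comparison without producing
a forest of unstable single-genus tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, ValidationError
from .indices import BLEACHED_CODES
from .survey_io import SurveyDataset

__all__ = [
    "OTHERS_LABEL",
    "TTestResult",
    "main_genus_grouping",
    "station_relative_abundance",
    "paired_t_test",
    "compare_periods",
    "significance_stars",
]

OTHERS_LABEL = "Others"

#: Status name -> category codes forming the numerator.
STATUS_CODES: dict[str, tuple[str, ...]] = {
    "bleached": BLEACHED_CODES,
    "dead": ("C6",),
    "healthy": ("C1",),
}


def main_genus_grouping(
    dataset: SurveyDataset,
    coverage: float = 0.80,
    named: Sequence[str] | None = None,
) -> dict[str, str]:
    """Map every taxon to its comparison group (itself, or ``Others``).

    Without an explicit ``named`` list, taxa are ranked by total abundance
    and named one by one until their cumulative relative abundance
    strictly exceeds ``coverage``; the rest pool into ``Others``.
    Ties in abundance break alphabetically for determinism.
    """
    if dataset.total_count == 0:
        raise ValidationError("cannot group taxa of an empty dataset")
    taxa = dataset.taxa()
    if named is not None:
        named_set = set(named)
        return {t: (t if t in named_set else OTHERS_LABEL) for t in taxa}

    totals = dataset.records.groupby("genus")["count"].sum()
    total = float(totals.sum())
    mapping: dict[str, str] = {}
    cum = 0.0
    naming = True
    for taxon in taxa:  # already sorted by abundance desc, name asc
        if naming:
            mapping[taxon] = taxon
            cum += float(totals[taxon]) / total
            if cum > coverage:
                naming = False
        else:
            mapping[taxon] = OTHERS_LABEL
    return mapping


def station_relative_abundance(
    dataset: SurveyDataset,
    grouping: Mapping[str, str],
    status: str,
    unit: str = "station",
) -> pd.DataFrame:
    """Relative abundance of a health status per group × pairing unit × period.

    value = (group colonies in the status's categories) / (all group
    colonies in the unit-period).  Units where the group was not recorded
    at all get a missing (NaN) value, flagged — a ratio 0/0 is not a zero.

    Returns a tidy frame (genus_group, status, period, unit, n_group, value).
    """
    if status not in STATUS_CODES:
        raise ParameterError(f"unknown status {status!r}; expected {sorted(STATUS_CODES)}")
    if unit not in ("station", "site"):
        raise ParameterError(f"pairing unit must be 'station' or 'site', got {unit!r}")
    codes = STATUS_CODES[status]
    df = dataset.records.copy()
    df["genus_group"] = df["genus"].map(dict(grouping))
    if df["genus_group"].isna().any():
        missing = sorted(df.loc[df["genus_group"].isna(), "genus"].unique())
        raise ValidationError(f"taxa missing from grouping: {missing}")

    all_units = sorted(
        dataset.design.station_site
        if unit == "station"
        else dataset.design.site_names
    )
    rows = []
    for group in sorted(set(grouping.values())):
        gdf = df[df["genus_group"] == group]
        if gdf.empty:
            raise ValidationError(f"group {group!r} has no colonies anywhere")
        for period in dataset.periods:
            pdf = gdf[gdf["period"] == period]
            totals = pdf.groupby(unit)["count"].sum()
            in_status = pdf[pdf["category"].isin(codes)].groupby(unit)["count"].sum()
            for u in all_units:
                n_group = int(totals.get(u, 0))
                value = float(in_status.get(u, 0)) / n_group if n_group else float("nan")
                rows.append(
                    {
                        "genus_group": group,
                        "status": status,
                        "period": period,
                        "unit": u,
                        "n_group": n_group,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TTestResult:
    """Matched-sample Student's t-test outcome."""

    t: float
    df: int
    p: float
    n_pairs: int
    infinite: bool = False  # zero-variance differences with nonzero mean


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Student's t-test for matched samples on per-unit values.

    d = y − x, t = mean(d) / (sd(d)/√n), df = n − 1, two-sided p.  Positive
    t means the second sample is larger.  Degenerate cases: identical
    samples give t = 0, p = 1; a constant nonzero difference has no
    within-pair variance and is flagged ``infinite`` with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 2:
        raise ParameterError(f"need at least 2 complete pairs, got {n}")
    d = y - x
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    dof = n - 1
    if sd == 0.0:
        if md == 0.0:
            return TTestResult(t=0.0, df=dof, p=1.0, n_pairs=n)
        return TTestResult(
            t=math.copysign(math.inf, md), df=dof, p=0.0, n_pairs=n, infinite=True
        )
    t = md / (sd / math.sqrt(n))
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return TTestResult(t=t, df=dof, p=p, n_pairs=n)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_periods(
    dataset: SurveyDataset,
    coverage: float = 0.80,
    named: Sequence[str] | None = None,
    unit: str = "station",
    statuses: Sequence[str] = ("bleached", "dead"),
) -> pd.DataFrame:
    """Matched t-tests per genus group and status between the two periods.

    Differences are taken after − during, so a negative t for bleached
    abundance means less bleaching after the event.  Units missing in
    either period are dropped listwise; ``n_dropped`` records how many.
    """
    grouping = main_genus_grouping(dataset, coverage=coverage, named=named)
    p_during, p_after = dataset.periods
    rows = []
    for status in statuses:
        ra = station_relative_abundance(dataset, grouping, status, unit=unit)
        for group in sorted(ra["genus_group"].unique()):
            sub = ra[ra["genus_group"] == group].pivot(
                index="unit", columns="period", values="value"
            )
            complete = sub.dropna()
            res = paired_t_test(complete[p_during], complete[p_after])
            rows.append(
                {
                    "genus_group": group,
                    "status": status,
                    "t": round(res.t, 2) if math.isfinite(res.t) else res.t,
                    "df": res.df,
                    "p": res.p,
                    "stars": significance_stars(res.p),
                    "n_pairs": res.n_pairs,
                    "n_dropped": int(len(sub) - len(complete)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genus_group", "status", "t", "df", "p", "stars", "n_pairs", "n_dropped"],
    )
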