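"""Synthetic survey and SST generators.

The generators reproduce the statistical structure the analysis assumes,
so that every pipeline stage can be exercised without field data:

* colony counts per 1 m² quadrat follow a negative binomial (the count
  family ecological quadrat data is usually modelled with);
* each colony is assigned a genus by community relative abundance, and a
  during-period health category from that genus's category distribution;
* between the two survey periods, bleached colonies (C2–C5) recover to
  C1 with a genus-specific probability, die (C6) with another, and
  otherwise retain their category; C1 and C6 persist.  The after-period
  survey re-draws quadrat membership (quadrats are deployed haphazardly
  anew each campaign), drawing fresh colonies from the evolved
  per-genus category distribution;
* daily SST is a seasonal sinusoid plus optional heat-event plateaus and
  Gaussian noise.

The default scenario mirrors the surveyed seascape's shape: 6 sites,
11 stations (one site has a single station), 20 quadrats of 1 m² per
station, ~18 colonies per quadrat, 9 dominant genera plus a pooled
"Others" community, with branching taxa given heavier bleaching mass.
The genus mix is illustrative of such a reef community, not fitted to
any particular survey.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParameterError, ValidationError
from .survey_io import (
    CATEGORY_CODES,
    CATEGORY_WEIGHTS,
    SiteDesign,
    SurveyDataset,
    SurveyDesign,
)
from .thermal import SSTSeries

__all__ = [
    "GenusProfile",
    "SimulationConfig",
    "default_profiles",
    "default_design",
    "default_config",
    "expected_bri",
    "evolve_category_probs",
    "gen_survey",
    "gen_sst",
    "config_to_yaml",
    "config_from_yaml",
]

_PROB_TOL = 1e-8


@dataclass(frozen=True)
class GenusProfile:
    """Per-taxon simulation parameters.

    ``category_probs_during`` is the C1..C6 distribution a colony of this
    genus is observed in during the event; ``recovery_prob`` and
    ``death_prob`` are the per-colony probabilities that a bleached
    (C2–C5) colony has returned to C1, or progressed to C6, by the
    after-event survey.
    """

    genus: str
    rel_abundance: float
    category_probs_during: tuple[float, ...]
    recovery_prob: float
    death_prob: float

    def __post_init__(self) -> None:
        p = np.asarray(self.category_probs_during, dtype=float)
        if p.size != 6 or (p < 0).any() or abs(p.sum() - 1.0) > _PROB_TOL:
            raise ValidationError(
                f"{self.genus}: category_probs_during must be 6 non-negative "
                f"values summing to 1"
            )
        for name in ("rel_abundance", "recovery_prob", "death_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.genus}: {name} must be in [0, 1], got {v}")
        if self.recovery_prob + self.death_prob > 1.0 + _PROB_TOL:
            raise ValidationError(
                f"{self.genus}: recovery_prob + death_prob must not exceed 1"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of the synthetic survey generator."""

    design: SurveyDesign
    genus_profiles: tuple[GenusProfile, ...]
    quadrat_mean: float = 18.0
    quadrat_dispersion: float = 8.0  # negative-binomial size parameter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.quadrat_mean <= 0:
            raise ValidationError("quadrat_mean must be positive")
        if self.quadrat_dispersion <= 0:
            raise ValidationError("quadrat_dispersion must be positive")
        rel = sum(p.rel_abundance for p in self.genus_profiles)
        if abs(rel - 1.0) > 1e-6:
            raise ValidationError(f"genus rel_abundances must sum to 1, got {rel}")


def expected_bri(category_probs: Sequence[float]) -> float:
    """Expected BRI of the category distribution: 20 · Σ weight_k · p_k.

    Equals the index formula applied to expected percentages 100·p_k.
    """
    p = np.asarray(category_probs, dtype=float)
    if p.size != 6 or abs(p.sum() - 1.0) > 1e-6:
        raise ParameterError("category_probs must be 6 values summing to 1")
    weights = np.array([CATEGORY_WEIGHTS[c] for c in CATEGORY_CODES], dtype=float)
    return float(20.0 * np.dot(weights, p))


def evolve_category_probs(profile: GenusProfile) -> tuple[float, ...]:
    """After-event category distribution under the recovery/death transitions.

    Per colony: C2–C5 → C1 with recovery_prob, → C6 with death_prob, else
    retained; C1 and C6 persist.  Applying these independent Bernoulli
    moves to a multinomial population yields this evolved multinomial.
    """
    p = np.asarray(profile.category_probs_during, dtype=float)
    r, d = profile.recovery_prob, profile.death_prob
    bleached = p[1:5].sum()
    out = p.copy()
    out[0] = p[0] + r * bleached
    out[1:5] = p[1:5] * (1.0 - r - d)
    out[5] = p[5] + d * bleached
    return tuple(out)


# ----------------------------------------------------------------------
# Default "paper-like" scenario


def default_design() -> SurveyDesign:
    """6 sites × 1–2 stations (11 total) × 20 quadrats of 1 m²."""
    sites = (
        SiteDesign("SiteA", ("A1", "A2")),
        SiteDesign("SiteB", ("B1", "B2")),
        SiteDesign("SiteC", ("C1s", "C2s")),
        SiteDesign("SiteD", ("D1", "D2")),
        SiteDesign("SiteE", ("E1", "E2")),
        SiteDesign("SiteF", ("F1",)),  # single inner-reef station
    )
    return SurveyDesign(sites, ("during", "after"))


def default_profiles() -> tuple[GenusProfile, ...]:
    """Illustrative community: 9 dominant genera plus pooled Others.

    Branching, thermally sensitive taxa (Acropora, Pocillopora,
    Seriatopora, Stylophora) carry more bleaching mass and higher
    mortality; massive/encrusting taxa (Galaxea, Favites, Echinopora,
    massive Porites, Montipora) are tolerant.  Relative abundances follow
    the usual dominance ranking of such assemblages (Acropora-led).
    """

    def probs(c1, c2, c3, c4, c5, c6):
        return (c1, c2, c3, c4, c5, c6)

    return (
        GenusProfile("Acropora", 0.25, probs(0.40, 0.15, 0.15, 0.10, 0.15, 0.05), 0.70, 0.10),
        GenusProfile("Galaxea", 0.14, probs(0.78, 0.08, 0.06, 0.03, 0.02, 0.03), 0.60, 0.05),
        GenusProfile("Pocillopora", 0.13, probs(0.30, 0.12, 0.18, 0.12, 0.22, 0.06), 0.75, 0.10),
        GenusProfile("Stylophora", 0.06, probs(0.55, 0.12, 0.12, 0.06, 0.10, 0.05), 0.50, 0.15),
        GenusProfile("Favites", 0.06, probs(0.75, 0.10, 0.07, 0.03, 0.02, 0.03), 0.65, 0.04),
        GenusProfile("Echinopora", 0.04, probs(0.76, 0.09, 0.07, 0.03, 0.02, 0.03), 0.60, 0.04),
        GenusProfile("Seriatopora", 0.03, probs(0.15, 0.10, 0.18, 0.15, 0.32, 0.10), 0.70, 0.12),
        GenusProfile("massive Porites", 0.04, probs(0.65, 0.14, 0.10, 0.04, 0.04, 0.03), 0.70, 0.03),
        GenusProfile("Montipora", 0.04, probs(0.80, 0.08, 0.05, 0.03, 0.02, 0.02), 0.60, 0.04),
        GenusProfile("Lobophyllia", 0.02, probs(0.10, 0.08, 0.15, 0.20, 0.37, 0.10), 0.55, 0.25),
        GenusProfile("Pavona", 0.02, probs(0.25, 0.10, 0.15, 0.15, 0.25, 0.10), 0.60, 0.12),
        GenusProfile("Millepora", 0.02, probs(0.85, 0.06, 0.04, 0.02, 0.02, 0.01), 0.80, 0.02),
        GenusProfile("Other taxa", 0.15, probs(0.60, 0.12, 0.10, 0.06, 0.08, 0.04), 0.60, 0.08),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        design=default_design(),
        genus_profiles=default_profiles(),
        quadrat_mean=18.0,
        quadrat_dispersion=8.0,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Survey generation


def _nb_params(mean: float, dispersion: float) -> tuple[float, float]:
    """Negative binomial (n, p) from mean and size/dispersion k:
    var = mean + mean²/k."""
    n = dispersion
    p = dispersion / (dispersion + mean)
    return n, p


def gen_survey(config: SimulationConfig) -> SurveyDataset:
    """Generate a two-period survey dataset.  Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    profiles = config.genus_profiles
    rel = np.array([p.rel_abundance for p in profiles])
    p_during, p_after = config.design.periods
    cat_probs = {
        p_during: [np.asarray(p.category_probs_during) for p in profiles],
        p_after: [np.asarray(evolve_category_probs(p)) for p in profiles],
    }
    n_nb, p_nb = _nb_params(config.quadrat_mean, config.quadrat_dispersion)

    rows = []
    for period in config.design.periods:
        period_probs = cat_probs[period]
        for site in config.design.sites:
            for station in site.stations:
                n_colonies = rng.negative_binomial(
                    n_nb, p_nb, size=site.quadrats_per_station
                )
                for qi, n_col in enumerate(n_colonies, start=1):
                    if n_col == 0:
                        continue
                    genus_idx = rng.choice(len(profiles), size=int(n_col), p=rel)
                    for gi in np.unique(genus_idx):
                        n_g = int((genus_idx == gi).sum())
                        cats = rng.choice(6, size=n_g, p=period_probs[gi])
                        codes, counts = np.unique(cats, return_counts=True)
                        for ci, cnt in zip(codes, counts):
                            rows.append(
                                {
                                    "site": site.name,
                                    "station": station,
                                    "period": period,
                                    "quadrat": f"q{qi}",
                                    "genus": profiles[gi].genus,
                                    "category": CATEGORY_CODES[ci],
                                    "count": int(cnt),
                                }
                            )
    records = pd.DataFrame(
        rows, columns=["site", "station", "period", "quadrat", "genus", "category", "count"]
    )
    return SurveyDataset(records, config.design)


# ----------------------------------------------------------------------
# SST generation


def gen_sst(
    baseline_mean: float = 26.5,
    seasonal_amplitude: float = 2.5,
    anomaly_events: Sequence[tuple[str, int, float]] = (),
    noise_sd: float = 0.15,
    years: int = 2,
    seed: int = 0,
    location: str = "synthetic-reef",
    start: str = "2023-01-01",
    peak_doy: int = 46,
) -> SSTSeries:
    """Daily SST: seasonal sinusoid + heat-event plateaus + Gaussian noise.

    Each anomaly event is (start date ISO-8601, duration days, peak °C):
    a flat plateau of the given height added to the seasonal cycle, the
    simplest shape whose DHW response has a closed form.  ``peak_doy``
    places the warm season (default mid-February, a southern-hemisphere
    summer).  Deterministic per seed.
    """
    if years < 1:
        raise ParameterError("need at least one year of SST")
    dates = pd.date_range(start, periods=int(round(365.25 * years)), freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    sst = baseline_mean + seasonal_amplitude * np.cos(
        2.0 * np.pi * (doy - peak_doy) / 365.25
    )
    for ev_start, duration, peak in anomaly_events:
        if duration < 1:
            raise ParameterError("event duration must be >= 1 day")
        t0 = pd.Timestamp(ev_start)
        mask = (dates >= t0) & (dates < t0 + pd.Timedelta(days=int(duration)))
        sst = sst + np.where(mask, float(peak), 0.0)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sst = sst + rng.normal(0.0, noise_sd, size=len(dates))
    return SSTSeries(location, pd.Series(sst, index=dates))


# ----------------------------------------------------------------------
# Config (de)serialisation


def config_to_yaml(config: SimulationConfig, path: str) -> None:
    doc = {
        "seed": config.seed,
        "quadrat_mean": config.quadrat_mean,
        "quadrat_dispersion": config.quadrat_dispersion,
        "periods": list(config.design.periods),
        "sites": [
            {
                "name": s.name,
                "stations": list(s.stations),
                "quadrats_per_station": s.quadrats_per_station,
                "quadrat_area_m2": s.quadrat_area_m2,
            }
            for s in config.design.sites
        ],
        "genus_profiles": [
            {
                "genus": p.genus,
                "rel_abundance": p.rel_abundance,
                "category_probs_during": list(p.category_probs_during),
                "recovery_prob": p.recovery_prob,
                "death_prob": p.death_prob,
            }
            for p in config.genus_profiles
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def config_from_yaml(path: str) -> SimulationConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    design = SurveyDesign(
        tuple(
            SiteDesign(
                s["name"],
                tuple(s["stations"]),
                quadrats_per_station=int(s.get("quadrats_per_station", 20)),
                quadrat_area_m2=float(s.get("quadrat_area_m2", 1.0)),
            )
            for s in doc["sites"]
        ),
        tuple(doc.get("periods", ("during", "after"))),
    )
    profiles = tuple(
        GenusProfile(
            p["genus"],
            float(p["rel_abundance"]),
            tuple(float(x) for x in p["category_probs_during"]),
            float(p["recovery_prob"]),
            float(p["death_prob"]),
        )
        for p in doc["genus_profiles"]
    )
    return SimulationConfig(
        design=design,
        genus_profiles=profiles,
        quadrat_mean=float(doc.get("quadrat_mean", 18.0)),
        quadrat_dispersion=float(doc.get("quadrat_dispersion", 8.0)),
        seed=int(doc.get("seed", 0)),
    )
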