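"""Synthetic survey generator emulating a 12-site, 12-month sentinel-herd design.

The generator produces long-format tick collections with the statistical
structure the downstream analyses assume:

* per steer-month-taxon, adult counts are negative-binomial with a seasonal
  mean (ticks/steer/month) patterned on high/medium/low abundance levels —
  Boophilus-subgenus taxa peak in the late rainy season, the two/three-host
  taxa (Hyalomma, A. variegatum, Rhipicephalus spp) at its beginning;
* co-infestation acts multiplicatively on the mean: the presence of taxon j
  on a host multiplies taxon i's mean by m[j -> i] (default 1, no
  interaction), resolved by a two-pass draw (baseline presences first, then
  counts with multipliers applied) so that the joint law stays well defined;
* each count is spread over the five host body parts multinomially according
  to a per-taxon attachment preference (Rhipicephalus spp favours head and
  legs, the other taxa flank and perineum);
* per-area monthly rainfall/temperature series follow the regional season
  calendars (bimodal rains in the southernmost area, unimodal elsewhere,
  driest in the Sahelian area).

A truth ledger (per-cell baseline and adjusted means, pass-1 presences) is
returned alongside the survey so parameter-recovery tests can compare
estimates against the generating values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .survey_io import (
    ANALYSIS_TAXA,
    BODY_PARTS,
    BOOPHILUS_TAXA,
    SURVEY_COLUMNS,
    SurveyTable,
)

# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimulationConfig:
    """Full parameterization of a synthetic survey.

    ``schedule[(site, taxon)]`` is the tuple of baseline mean adult
    ticks/steer/month over the survey months (survey-relative indexing);
    ``multipliers[(j, i)]`` is the multiplicative effect of taxon j's
    presence on taxon i's mean; ``nb_size`` is the negative-binomial size
    (inverse-dispersion) parameter theta shared by all cells.
    """

    site_areas: dict[str, str]  # site -> area
    taxon_pools: dict[str, tuple[str, ...]]  # site -> taxa that occur there
    months: int = 12
    steers_per_site: int = 12
    schedule: dict[tuple[str, str], tuple[float, ...]] = field(default_factory=dict)
    nb_size: float = 1.5
    multipliers: dict[tuple[str, str], float] = field(default_factory=dict)
    attachment_preferences: dict[str, tuple[float, ...]] = field(default_factory=dict)
    area_start_month: dict[str, int] = field(default_factory=dict)  # calendar month of month_index 1
    rainfall: dict[str, tuple[float, ...]] = field(default_factory=dict)  # by calendar month 1..12
    temperature: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def validate(self) -> None:
        for taxon, prefs in self.attachment_preferences.items():
            if len(prefs) != len(BODY_PARTS) or abs(sum(prefs) - 1.0) > 1e-9 or min(prefs) < 0:
                raise ValueError(f"attachment preference for {taxon} is not a probability vector")
        if self.nb_size <= 0:
            raise ValueError("nb_size (theta) must be > 0")
        for key, means in self.schedule.items():
            if min(means) < 0:
                raise ValueError(f"negative mean in schedule for {key}")
        for key, m in self.multipliers.items():
            if m < 0:
                raise ValueError(f"negative multiplier for {key}")

    def calendar_month(self, area: str, month_index: int) -> int:
        start = self.area_start_month.get(area, 1)
        return (start - 1 + month_index - 1) % 12 + 1

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = {f"{s}|{t}": list(v) for (s, t), v in self.schedule.items()}
        d["multipliers"] = {f"{j}|{i}": v for (j, i), v in self.multipliers.items()}
        d["taxon_pools"] = {s: list(v) for s, v in self.taxon_pools.items()}
        d["attachment_preferences"] = {
            t: list(v) for t, v in self.attachment_preferences.items()
        }
        d["rainfall"] = {a: list(v) for a, v in self.rainfall.items()}
        d["temperature"] = {a: list(v) for a, v in self.temperature.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["schedule"] = {
            tuple(k.split("|")): tuple(v) for k, v in d.get("schedule", {}).items()
        }
        d["multipliers"] = {
            tuple(k.split("|")): float(v) for k, v in d.get("multipliers", {}).items()
        }
        d["taxon_pools"] = {s: tuple(v) for s, v in d.get("taxon_pools", {}).items()}
        d["attachment_preferences"] = {
            t: tuple(v) for t, v in d.get("attachment_preferences", {}).items()
        }
        d["rainfall"] = {a: tuple(v) for a, v in d.get("rainfall", {}).items()}
        d["temperature"] = {a: tuple(v) for a, v in d.get("temperature", {}).items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulationTruth:
    """Generating values kept for parameter-recovery tests.

    ``ledger``: one row per (site, month_index, steer, taxon) with the
    baseline mean, co-infestation-adjusted mean and realized count.
    ``presence``: pass-1 baseline presences (0/1) per steer-month-taxon.
    """

    ledger: pd.DataFrame
    presence: pd.DataFrame


# ---------------------------------------------------------------------------
# Default configuration: the reference 4-area / 12-site / 12-steer design

_SITES = {
    # South Benin (bimodal rains, Apr-Jul + Sep-Nov; survey starts February)
    "1A": "area1",
    "1K": "area1",
    "1O": "area1",
    # North Benin (rains May-Oct; starts February)
    "2G": "area2",
    "2O": "area2",
    # South-West Burkina Faso (rains Jun-Sep; starts April)
    "3F": "area3",
    "3K": "area3",
    "3O": "area3",
    # Central Burkina Faso (Sahelian, rains Jun-Sep; starts May)
    "4F": "area4",
    "4K": "area4",
    "4L": "area4",
    "4Z": "area4",
}

_AREA_START = {"area1": 2, "area2": 2, "area3": 4, "area4": 5}

# (high, medium, low) mean adult ticks/steer/month per taxon, magnitudes
# patterned on the seasonal abundance levels observed in such surveys.
_LEVEL_MEANS = {
    "HYALOMMA_SPP": (4.0, 1.8, 0.5),
    "A_VARIEGATUM": (6.0, 2.0, 0.4),
    "RHIPICEPHALUS_SPP": (6.0, 1.5, 0.3),
    "R_ANNULATUS": (3.0, 1.2, 0.2),
    "R_DECOLORATUS": (1.9, 0.8, 0.1),
    "R_MICROPLUS": (30.0, 10.0, 1.5),
    "R_GEIGYI": (1.0, 0.4, 0.1),
}

# Calendar months of the early-rainy-season abundance peak per area (two/
# three-host taxa) and of the late peak (Boophilus subgenus, one-host).
_EARLY_PEAK = {"area1": (4, 5), "area2": (5, 6), "area3": (3, 4), "area4": (6, 7)}
_LATE_PEAK = {
    "area1": (9, 10, 11),
    "area2": (9, 10, 11, 12),
    "area3": (9, 10, 11),
    "area4": (8, 9),
}

# Sporadic baseline: a trickle mean that leaves a taxon detected in <3
# months of a year at a site (the native Boophilus species outside North
# Benin show exactly this pattern).
_SPORADIC_MEAN = 0.01

# Annual rainfall (mm) by area; area4 is the most arid.
_ANNUAL_RAIN = {"area1": 1400.0, "area2": 1300.0, "area3": 1200.0, "area4": 900.0}
_RAINY_MONTHS = {
    "area1": (4, 5, 6, 7, 9, 10, 11),  # bimodal: long + short rainy season
    "area2": (5, 6, 7, 8, 9, 10),
    "area3": (6, 7, 8, 9),
    "area4": (6, 7, 8, 9),
}


def _neighbour_months(months: tuple[int, ...]) -> set[int]:
    out = set()
    for m in months:
        out.add((m - 2) % 12 + 1)
        out.add(m % 12 + 1)
    return out - set(months)


def _taxon_site_means(site: str, area: str, taxon: str, cfg_months: int, start: int) -> tuple[float, ...]:
    high, med, low = _LEVEL_MEANS[taxon]
    if taxon in BOOPHILUS_TAXA and taxon != "R_MICROPLUS" and area != "area2":
        # sporadic trickle outside North Benin
        return tuple([_SPORADIC_MEAN] * cfg_months)
    peak = _LATE_PEAK[area] if taxon in BOOPHILUS_TAXA else _EARLY_PEAK[area]
    shoulder = _neighbour_months(peak)
    means = []
    for mi in range(1, cfg_months + 1):
        cal = (start - 1 + mi - 1) % 12 + 1
        if cal in peak:
            means.append(high)
        elif cal in shoulder:
            means.append(med)
        else:
            means.append(low)
    return tuple(means)


def default_config(months: int = 12, steers_per_site: int = 12) -> SimulationConfig:
    """Reference design: 4 areas, 12 sites, 12 steers, 12 monthly collections.

    Taxon pools reproduce the regional absences (the Sahelian area lacks
    Rhipicephalus spp, R. annulatus and R. microplus; the South-West area
    lacks R. decoloratus).  Co-infestation multipliers default to 1.
    """
    pools: dict[str, tuple[str, ...]] = {}
    for site, area in _SITES.items():
        pool = list(ANALYSIS_TAXA)
        if area == "area4":
            for absent in ("RHIPICEPHALUS_SPP", "R_ANNULATUS", "R_MICROPLUS"):
                pool.remove(absent)
        if area == "area3":
            pool.remove("R_DECOLORATUS")
        pools[site] = tuple(pool)

    schedule: dict[tuple[str, str], tuple[float, ...]] = {}
    for site, area in _SITES.items():
        for taxon in pools[site]:
            schedule[(site, taxon)] = _taxon_site_means(
                site, area, taxon, months, _AREA_START[area]
            )

    prefs = {}
    for taxon in ANALYSIS_TAXA:
        if taxon == "RHIPICEPHALUS_SPP":
            prefs[taxon] = (0.35, 0.35, 0.10, 0.10, 0.10)  # head, legs favoured
        else:
            prefs[taxon] = (0.08, 0.10, 0.32, 0.35, 0.15)  # flank, perineum favoured

    rainfall = {}
    temperature = {}
    for area, total in _ANNUAL_RAIN.items():
        wet = _RAINY_MONTHS[area]
        # triangular profile over the rainy months, rectified to the annual total
        weights = np.zeros(12)
        for k, m in enumerate(sorted(wet)):
            weights[m - 1] = 1.0 + 0.5 * np.sin(np.pi * (k + 1) / (len(wet) + 1))
        weights = weights / weights.sum() * total
        rainfall[area] = tuple(round(float(w), 1) for w in weights)
        base = {"area1": 27.0, "area2": 28.0, "area3": 28.0, "area4": 29.0}[area]
        temp = base + 3.0 * np.cos(2 * np.pi * (np.arange(1, 13) - 4) / 12)
        temperature[area] = tuple(round(float(t), 1) for t in temp)

    cfg = SimulationConfig(
        site_areas=dict(_SITES),
        taxon_pools=pools,
        months=months,
        steers_per_site=steers_per_site,
        schedule=schedule,
        nb_size=1.5,
        multipliers={},
        attachment_preferences=prefs,
        area_start_month=dict(_AREA_START),
        rainfall=rainfall,
        temperature=temperature,
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# Simulation


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial draw parameterized by (mean, size); mean 0 -> 0."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_survey(
    config: SimulationConfig, seed: int
) -> tuple[SurveyTable, pd.DataFrame, SimulationTruth]:
    """Draw one complete survey; identical (config, seed) -> identical output.

    Two-pass scheme: pass 1 draws baseline counts (multipliers off) whose
    positivity defines the baseline presence of every taxon on every host;
    pass 2 redraws each taxon's count with the co-infestation multipliers of
    the *other* taxa's pass-1 presences applied to its mean.  Counts are then
    split across body parts multinomially.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    theta = config.nb_size
    n_steer = config.steers_per_site
    n_month = config.months

    rows: list[tuple] = []
    ledger_rows: list[tuple] = []
    presence_rows: list[tuple] = []

    for site in sorted(config.site_areas):
        area = config.site_areas[site]
        pool = list(config.taxon_pools[site])
        steers = [f"{site}-s{i + 1:02d}" for i in range(n_steer)]
        # baseline means: (steer, month, taxon)
        mu0 = np.zeros((n_steer, n_month, len(pool)))
        for t, taxon in enumerate(pool):
            mu0[:, :, t] = np.asarray(config.schedule[(site, taxon)])[None, :]

        c0 = _nb_draw(rng, mu0, theta)  # pass 1
        pres = (c0 > 0).astype(float)

        logm = np.zeros((len(pool), len(pool)))
        for j, tj in enumerate(pool):
            for i, ti in enumerate(pool):
                if i != j:
                    m = config.multipliers.get((tj, ti), 1.0)
                    logm[j, i] = np.log(m) if m > 0 else -np.inf
        adj = np.exp(pres @ logm)  # (steer, month, taxon) multiplier products
        mu1 = mu0 * adj
        # pass 2: redraw only cells whose mean changed; unchanged cells keep
        # their pass-1 count so a taxon's observed presence *is* the presence
        # the multipliers acted through (taxa without incoming interactions
        # are untouched, which keeps the conditional law well defined)
        redrawn = _nb_draw(rng, mu1, theta)
        counts = np.where(np.isclose(mu1, mu0), c0, redrawn)

        for s, steer in enumerate(steers):
            for mi in range(n_month):
                cal = config.calendar_month(area, mi + 1)
                presence_rows.append(
                    (site, mi + 1, steer)
                    + tuple(int(pres[s, mi, t]) for t in range(len(pool)))
                )
                for t, taxon in enumerate(pool):
                    cnt = int(counts[s, mi, t])
                    ledger_rows.append(
                        (
                            area,
                            site,
                            mi + 1,
                            steer,
                            taxon,
                            mu0[s, mi, t],
                            mu1[s, mi, t],
                            cnt,
                        )
                    )
                    if cnt == 0:
                        rows.append(
                            (area, site, mi + 1, cal, steer, taxon, np.nan, 0)
                        )
                    else:
                        split = rng.multinomial(
                            cnt, config.attachment_preferences[taxon]
                        )
                        for part, k in zip(BODY_PARTS, split):
                            if k > 0:
                                rows.append(
                                    (area, site, mi + 1, cal, steer, taxon, part, int(k))
                                )

        # pad presence rows to a uniform width later via per-site frames
        presence_rows[-n_steer * n_month :] = [
            r[:3] + tuple(dict(zip(pool, r[3:])).get(t, 0) for t in ANALYSIS_TAXA)
            for r in presence_rows[-n_steer * n_month :]
        ]

    data = pd.DataFrame(rows, columns=list(SURVEY_COLUMNS))
    roster = {
        site: tuple(f"{site}-s{i + 1:02d}" for i in range(n_steer))
        for site in sorted(config.site_areas)
    }
    months = pd.DataFrame(
        [
            (area, mi, config.calendar_month(area, mi))
            for area in sorted(set(config.site_areas.values()))
            for mi in range(1, n_month + 1)
        ],
        columns=["area", "month_index", "calendar_month"],
    )
    survey = SurveyTable(data=data, roster=roster, months=months)
    survey.validate()

    climate = _simulate_climate(config, rng)

    ledger = pd.DataFrame(
        ledger_rows,
        columns=[
            "area",
            "site",
            "month_index",
            "steer",
            "taxon",
            "base_mean",
            "adjusted_mean",
            "count",
        ],
    )
    presence = pd.DataFrame(
        presence_rows,
        columns=["site", "month_index", "steer"] + list(ANALYSIS_TAXA),
    )
    return survey, climate, SimulationTruth(ledger=ledger, presence=presence)


def _simulate_climate(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Monthly rainfall/temperature per area: seasonal curve + mild noise."""
    rows = []
    for area in sorted(set(config.site_areas.values())):
        for mi in range(1, config.months + 1):
            cal = config.calendar_month(area, mi)
            base_rain = config.rainfall[area][cal - 1]
            base_temp = config.temperature[area][cal - 1]
            rain = max(0.0, base_rain * rng.lognormal(0.0, 0.15)) if base_rain > 0 else 0.0
            temp = base_temp + rng.normal(0.0, 0.5)
            rows.append((area, mi, cal, round(rain, 1), round(temp, 1)))
    return pd.DataFrame(
        rows,
        columns=["area", "month_index", "calendar_month", "rainfall_mm", "temperature_c"],
    )
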