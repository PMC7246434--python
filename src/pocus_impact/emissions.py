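"""Avoided pollutant emissions via E = M x N x EF.

``E`` is the emitted mass (g), ``M`` the distance travelled (km), ``N``
the number of vehicles and ``EF`` a fleet-average emission factor in
g per vehicle-km. Every avoided round trip counts as one single-occupancy
private car journey. CO2 is deliberately absent from the factor set: it
is not part of the EMEP/EEA mandatory-reporting inventory the factors
come from.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator, Mapping

import pandas as pd
import yaml

from .classify import DEFAULT_WINDOW_DAYS
from .stats import stratum_summary
from .travel import TravelAssumptions, journey_table

_FACTOR_TOLERANCE = 1e-6


@dataclass(frozen=True)
class EmissionFactorTable:
    """Pollutant -> emission factor (g per vehicle-km) mapping.

    Validates physical consistency on construction: factors positive,
    PM2.5 <= PM10, and NO + NO2 equal to NOx within 1e-6 when all three
    are present.
    """

    factors: Mapping[str, float]

    def __post_init__(self) -> None:
        f = dict(self.factors)
        object.__setattr__(self, "factors", f)
        if not f:
            raise ValueError("empty emission factor table")
        for pollutant, ef in f.items():
            if ef <= 0:
                raise ValueError(f"non-positive factor for {pollutant}")
        if "PM2.5" in f and "PM10" in f and f["PM2.5"] > f["PM10"]:
            raise ValueError("PM2.5 factor exceeds PM10 factor")
        if {"NO", "NO2", "NOx"} <= f.keys():
            if abs(f["NO"] + f["NO2"] - f["NOx"]) > _FACTOR_TOLERANCE:
                raise ValueError("NO + NO2 factors inconsistent with NOx")

    @classmethod
    def default(cls) -> "EmissionFactorTable":
        """The packaged fleet-average factor set."""
        text = (
            resources.files("pocus_impact").joinpath("data/emission_factors.yaml")
        ).read_text()
        return cls(yaml.safe_load(text))

    @classmethod
    def from_yaml(cls, path) -> "EmissionFactorTable":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(self.factors)

    def __getitem__(self, pollutant: str) -> float:
        try:
            return self.factors[pollutant]
        except KeyError:
            raise KeyError(f"unknown pollutant code {pollutant!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self.factors)


def emission(distance_km: float, n_vehicles: float, factor_g_per_km: float) -> float:
    """Emitted mass in grams: E = M x N x EF."""
    if distance_km < 0 or n_vehicles < 0:
        raise ValueError("distance and vehicle count must be non-negative")
    if factor_g_per_km <= 0:
        raise ValueError("emission factor must be positive")
    return distance_km * n_vehicles * factor_g_per_km


def aggregate_emissions(
    register: pd.DataFrame,
    centres: pd.DataFrame,
    factors: EmissionFactorTable | None = None,
    assumptions: TravelAssumptions | None = None,
    window_days: int = DEFAULT_WINDOW_DAYS,
    n_vehicles_per_journey: float = 1.0,
) -> pd.DataFrame:
    """Stratified avoided-emission table (the study's pollutant table).

    Long-form frame with one row per (pollutant, stratum): per-journey
    ``mean``/``ci_low``/``ci_high`` grams and the stratum ``total`` grams
    over avoided journeys. Strata are ``rural``, ``urban`` and ``total``.
    """
    factors = factors or EmissionFactorTable.default()
    journeys = journey_table(register, centres, assumptions, window_days)
    if len(journeys) == 0:
        raise ValueError("no avoided journeys")
    rows = []
    groups = [("rural", journeys[journeys["rurality"] == "rural"]),
              ("urban", journeys[journeys["rurality"] == "urban"]),
              ("total", journeys)]
    for pollutant in factors:
        ef = factors[pollutant]
        for stratum, sub in groups:
            if len(sub) == 0:
                continue
            grams = sub["distance_km"] * n_vehicles_per_journey * ef
            s = stratum_summary(grams)
            rows.append(
                {
                    "pollutant": pollutant,
                    "stratum": stratum,
                    "n": s.n,
                    "mean_g": s.mean,
                    "ci_low_g": s.ci_low,
                    "ci_high_g": s.ci_high,
                    "total_g": s.total,
                }
            )
    return pd.DataFrame(rows)


def maintenance_overhead(
    trips_per_year: int,
    round_trip_km: float,
    factors: EmissionFactorTable | None = None,
) -> pd.Series:
    """Annual emissions (g per pollutant) of equipment-maintenance trips.

    Scanner upkeep generates its own car journeys (about ten per year for
    devices spread across primary-care centres versus two for a single
    specialised-service location). Reported separately so that
    ``net savings = patient savings - (PC overhead - specialised overhead)``.
    """
    if trips_per_year < 0 or round_trip_km < 0:
        raise ValueError("trips and distance must be non-negative")
    factors = factors or EmissionFactorTable.default()
    return pd.Series(
        {p: trips_per_year * round_trip_km * factors[p] for p in factors},
        name="grams_per_year",
    )


def maintenance_net_overhead(
    pc_trips_per_year: int,
    specialised_trips_per_year: int,
    round_trip_km: float,
    factors: EmissionFactorTable | None = None,
) -> pd.Series:
    """Extra maintenance emissions of the point-of-care deployment relative
    to a single specialised-service scanner (g per pollutant, per year)."""
    pc = maintenance_overhead(pc_trips_per_year, round_trip_km, factors)
    spec = maintenance_overhead(specialised_trips_per_year, round_trip_km, factors)
    return (pc - spec).rename("grams_per_year")
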