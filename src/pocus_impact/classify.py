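"""Categorical rules of the analysis: centre rurality and avoided consults.

A centre is *rural* when its assigned population density is below
150 inhabitants/km2 **and** its assigned population is below 10,000
(the Primary Care Information System criterion). A scan *avoided* a
face-to-face radiology consultation when no same-type radiology visit
followed it within the follow-up window (three months, fixed here at
90 days, boundary inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import SCAN_TYPES

RURAL_DENSITY_THRESHOLD = 150.0  # inhabitants / km2
RURAL_POPULATION_THRESHOLD = 10_000  # inhabitants
DEFAULT_WINDOW_DAYS = 90


def classify_rurality(
    population: float,
    density: float,
    *,
    population_threshold: float = RURAL_POPULATION_THRESHOLD,
    density_threshold: float = RURAL_DENSITY_THRESHOLD,
) -> str:
    """Classify a centre as ``"rural"`` or ``"urban"``.

    Rural iff density < 150 /km2 and population < 10,000 (both strict).
    """
    if population <= 0 or density <= 0:
        raise ValueError("population and density must be positive")
    if density < density_threshold and population < population_threshold:
        return "rural"
    return "urban"


@dataclass(frozen=True)
class CentreProfile:
    """One centre with its derived rurality label."""

    centre_id: str
    assigned_population: int
    population_density: float
    round_trip_distance_km: float
    round_trip_time_min: float

    def __post_init__(self) -> None:
        if self.round_trip_distance_km <= 0 or self.round_trip_time_min <= 0:
            raise ValueError("round-trip distance and time must be positive")
        if self.assigned_population <= 0 or self.population_density <= 0:
            raise ValueError("population and density must be positive")

    @property
    def rurality(self) -> str:
        return classify_rurality(self.assigned_population, self.population_density)


def add_rurality(centres: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the centre table with a derived ``rurality`` column."""
    out = centres.copy()
    out["rurality"] = [
        classify_rurality(pop, dens)
        for pop, dens in zip(out["assigned_population"], out["population_density"])
    ]
    return out


def is_avoided(
    scan_type: str,
    scan_date,
    radiology_visit_date=None,
    radiology_visit_type=None,
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> bool:
    """Whether a single scan avoided a face-to-face radiology consult.

    Returns ``False`` iff a same-type radiology visit exists with
    ``0 < visit_date - scan_date <= window_days``; ``True`` otherwise
    (no visit, different-type visit, or visit after the window).
    """
    if radiology_visit_date is None or pd.isna(radiology_visit_date):
        return True
    scan_date = pd.Timestamp(scan_date)
    visit_date = pd.Timestamp(radiology_visit_date)
    if visit_date < scan_date:
        raise ValueError("radiology visit precedes the scan")
    if radiology_visit_type != scan_type:
        return True
    delta = (visit_date - scan_date).days
    return not (0 < delta <= window_days)


def mark_avoided(
    register: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.DataFrame:
    """Vectorised avoidance flag; adds a boolean ``avoided`` column."""
    out = register.copy()
    scan = pd.to_datetime(out["scan_date"])
    visit = pd.to_datetime(out["radiology_visit_date"])
    if ((visit - scan).dt.days < 0).any():
        raise ValueError("radiology visit precedes the scan")
    delta = (visit - scan).dt.days
    blocking = (
        visit.notna()
        & (out["radiology_visit_type"] == out["scan_type"])
        & (delta > 0)
        & (delta <= window_days)
    )
    out["avoided"] = ~blocking
    return out


def avoided_fraction(
    register: pd.DataFrame, window_days: int = DEFAULT_WINDOW_DAYS
) -> pd.DataFrame:
    """Per-type and overall avoided-consultation percentages.

    Returns a frame indexed by scan type plus a ``"total"`` row with
    columns ``n_scans``, ``n_referred`` and ``avoided_pct``
    (= 100 * (n_scans - n_referred) / n_scans, rounded to one decimal;
    NaN for types with no scans).
    """
    if len(register) == 0:
        raise ValueError("empty register")
    flagged = mark_avoided(register, window_days)
    rows = {}
    for st in SCAN_TYPES:
        sub = flagged[flagged["scan_type"] == st]
        rows[st] = (len(sub), int((~sub["avoided"]).sum()))
    rows["total"] = (len(flagged), int((~flagged["avoided"]).sum()))
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["n_scans", "n_referred"]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (table["n_scans"] - table["n_referred"]) / table["n_scans"]
    table["avoided_pct"] = pct.round(1)
    table.index.name = "scan_type"
    return table
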