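"""Travel savings: fuel, cost, segment times and the stratified table."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocus_impact import (
    TravelAssumptions,
    aggregate_travel,
    format_day_hour_min,
    journey_cost,
    journey_fuel,
    journey_table,
    travel_time_from_segments,
)

A = TravelAssumptions()


class TestUnitConversions:
    def test_fuel_per_100km_definition(self):
        assert journey_fuel(100.0, A) == pytest.approx(6.9)
        assert journey_fuel(0.0, A) == 0.0
        assert journey_fuel(27_123.0, A) == pytest.approx(1871.487)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            journey_fuel(-1.0, A)

    def test_cost(self):
        assert journey_cost(0.0, A) == 0.0
        custom = TravelAssumptions(fuel_price_eur_per_l=1.50)
        assert journey_cost(1.0, custom) == pytest.approx(1.50)
        # price back-derived from the published fuel/cost totals
        assert journey_cost(1871.5, A) == pytest.approx(2658.1, abs=0.05)

    @pytest.mark.parametrize(
        "segments, minutes",
        [
            ((10, 0, 0), 20.0),
            ((0, 0, 0), 0.0),
            ((5, 12, 30), 37.0),  # 10 + 12 + 15 minutes
        ],
    )
    def test_segment_times(self, segments, minutes):
        assert travel_time_from_segments(*segments, A) == pytest.approx(minutes)

    def test_day_hour_min_rendering(self):
        assert format_day_hour_min(32_576) == "22:14:56"
        assert format_day_hour_min(0) == "00:00:00"


class TestAggregateTravel:
    def test_osona_totals_and_means(self, osona_register, osona_centres):
        table = aggregate_travel(osona_register, osona_centres).set_index(
            ["stratum", "measure"]
        )
        assert table.loc[("total", "distance_km"), "total"] == pytest.approx(27_123.0)
        assert table.loc[("total", "distance_km"), "mean"] == pytest.approx(
            27_123.0 / 1520
        )
        assert table.loc[("total", "fuel_l"), "total"] == pytest.approx(1871.487)
        assert table.loc[("total", "time_min"), "total"] == pytest.approx(32_576.0)
        # published one-decimal stratum means
        assert round(table.loc[("rural", "distance_km"), "mean"], 1) == 20.0
        assert round(table.loc[("urban", "distance_km"), "mean"], 1) == 13.6
        assert round(table.loc[("rural", "time_min"), "mean"], 1) == 24.2
        assert round(table.loc[("urban", "time_min"), "mean"], 1) == 15.8

    def test_additivity_full_precision(self, osona_register, osona_centres):
        table = aggregate_travel(osona_register, osona_centres).set_index(
            ["stratum", "measure"]
        )
        for measure in ("distance_km", "time_min", "fuel_l", "cost_eur"):
            assert table.loc[("rural", measure), "total"] + table.loc[
                ("urban", measure), "total"
            ] == pytest.approx(table.loc[("total", measure), "total"], rel=1e-12)

    def test_single_journey_mean_equals_total(self):
        register = pd.DataFrame(
            {
                "scan_id": ["s1"],
                "professional_id": ["P1"],
                "centre_id": ["C1"],
                "scan_type": ["abdomen"],
                "scan_date": pd.to_datetime(["2019-01-01"]),
                "radiology_visit_date": pd.to_datetime([None]),
                "radiology_visit_type": [None],
            }
        )
        centres = pd.DataFrame(
            {
                "centre_id": ["C1"],
                "assigned_population": [5000],
                "population_density": [40.0],
                "round_trip_distance_km": [10.0],
                "round_trip_time_min": [12.0],
            }
        )
        table = aggregate_travel(register, centres).set_index(["stratum", "measure"])
        assert table.loc[("total", "distance_km"), "mean"] == 10.0
        assert table.loc[("total", "distance_km"), "total"] == 10.0
        assert ("urban", "distance_km") not in table.index  # empty stratum omitted

    def test_no_avoided_journeys_rejected(self, osona_centres):
        register = pd.DataFrame(
            {
                "scan_id": ["s1"],
                "professional_id": ["P1"],
                "centre_id": ["U1"],
                "scan_type": ["abdomen"],
                "scan_date": pd.to_datetime(["2019-01-01"]),
                "radiology_visit_date": pd.to_datetime(["2019-01-20"]),
                "radiology_visit_type": ["abdomen"],
            }
        )
        with pytest.raises(ValueError, match="no avoided"):
            aggregate_travel(register, osona_centres)

    def test_unknown_centre_rejected(self, osona_register, osona_centres):
        with pytest.raises(ValueError, match="unknown centres"):
            journey_table(osona_register, osona_centres[osona_centres.centre_id != "R1"])

    @given(scale=st.floats(0.1, 10.0))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_linearity_under_distance_scaling(
        self, scale, osona_register, osona_centres
    ):
        scaled = osona_centres.assign(
            round_trip_distance_km=osona_centres["round_trip_distance_km"] * scale
        )
        base = aggregate_travel(osona_register, osona_centres).set_index(
            ["stratum", "measure"]
        )
        new = aggregate_travel(osona_register, scaled).set_index(
            ["stratum", "measure"]
        )
        for measure in ("distance_km", "fuel_l", "cost_eur"):
            assert new.loc[("total", measure), "total"] == pytest.approx(
                scale * base.loc[("total", measure), "total"], rel=1e-9
            )
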