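"""Unit-cost subunits, emissions and the unit-cost database."""

import numpy as np
import pandas as pd
import pytest

import patientcost as pc
from patientcost import bc_reference as bc
from patientcost.cost_engine import (
    VisitTime,
    build_unit_cost_database,
    calibrate_emission_factor,
    emissions_per_visit_kg,
    informal_caregiving,
    lost_productivity,
    out_of_pocket,
    report_view,
    telehealth_unit_cost,
    unit_cost,
)
from patientcost.errors import ConfigurationError
from patientcost.params import DEFAULT_AGE_BINS, ServiceType

CHILD, WORKING, SENIOR = DEFAULT_AGE_BINS.bands


def with_stay(params, days):
    prof = params.time_profiles[ServiceType.HOSPITALIZATION].model_copy(
        update={"length_of_stay_days": float(days)}
    )
    return params.model_copy(
        update={"time_profiles": {**params.time_profiles, ServiceType.HOSPITALIZATION: prof}}
    )


class TestLostProductivity:
    @pytest.mark.parametrize("band", [CHILD, SENIOR])
    def test_zero_outside_working_bin(self, band, params):
        vt = VisitTime(60, 60, 60)
        for st in ServiceType:
            assert lost_productivity(band, vt, params, st) == 0.0

    def test_two_hours_at_base_wage(self, params):
        vt = VisitTime(0, 60, 60)
        assert lost_productivity(WORKING, vt, params, ServiceType.PHYSICIAN) == (
            pytest.approx(61.08)
        )

    def test_hospital_cap_vs_uncapped_oracle(self, params):
        """A 3-day stay charges 3 x 8 h, not the uncapped 72 h."""
        p3 = with_stay(params, 3)
        vt = VisitTime(0, 0, 0)
        capped = lost_productivity(WORKING, vt, p3, ServiceType.HOSPITALIZATION)
        assert capped == pytest.approx(3 * 8 * 30.54)  # 732.96
        uncapped_oracle = 72.0 * params.hourly_wage
        assert uncapped_oracle == pytest.approx(2198.88)
        assert capped < uncapped_oracle

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError):
            VisitTime(-1, 0, 0)


class TestInformalCaregiving:
    def test_child_full_attendance(self, params):
        vt = VisitTime(0, 90, 90)  # 3 h
        assert informal_caregiving(CHILD, ServiceType.PHYSICIAN, vt, params) == (
            pytest.approx(91.62)
        )

    def test_senior_half_attendance(self, params):
        vt = VisitTime(0, 60, 60)
        assert informal_caregiving(SENIOR, ServiceType.ED_CTAS_I_III, vt, params) == (
            pytest.approx(30.54)
        )

    def test_hospitalization_prorated_to_daily_cap(self, params):
        p2 = with_stay(params, 2)
        got = informal_caregiving(WORKING, ServiceType.HOSPITALIZATION, VisitTime(0, 0, 0), p2)
        assert got == pytest.approx(0.25 * 2 * 8 * 30.54)  # 122.16

    def test_missing_attendance_entry(self, params):
        broken = params.model_copy(
            update={"caregiver_attendance": {"outpatient": {"child": 1.0}}}
        )
        with pytest.raises(ConfigurationError):
            informal_caregiving(WORKING, ServiceType.PHYSICIAN, VisitTime(0, 0, 0), broken)


class TestOutOfPocket:
    def test_physician_never_accommodation(self, params):
        for band in DEFAULT_AGE_BINS:
            oop = out_of_pocket(band, ServiceType.PHYSICIAN, 30.0, "urban", params)
            assert oop.accommodation == 0.0 and oop.meals == 0.0

    def test_ed_never_accommodation_even_far(self, params):
        oop = out_of_pocket(WORKING, ServiceType.ED_CTAS_I_III, 300.0, "rural", params)
        assert oop.accommodation == 0.0

    def test_hospitalization_accommodation_beyond_threshold(self, params):
        p = params.model_copy(update={"hotel_rate_by_scope": {"Northern": 150.0}})
        oop = out_of_pocket(WORKING, ServiceType.HOSPITALIZATION, 69.4, "Northern", p)
        assert oop.accommodation == pytest.approx(2 * 150 * 0.25)  # 75
        near = out_of_pocket(WORKING, ServiceType.HOSPITALIZATION, 30.6, "Northern", p)
        assert near.accommodation == 0.0

    def test_ed_itemisation_on_printed_urban_distance(self, params):
        oop = out_of_pocket(WORKING, ServiceType.ED_CTAS_IV_V, 18.94, "urban", params)
        assert oop.vehicle == pytest.approx(9.47)
        assert oop.parking == 10.0
        assert oop.meals == 15.0
        assert oop.total == pytest.approx(34.47)

    def test_hospital_parking_two_days_meals_attendance(self, params):
        oop = out_of_pocket(CHILD, ServiceType.HOSPITALIZATION, 10.0, "urban", params)
        assert oop.parking == 2 * params.default_parking_hospital_rate
        assert oop.meals == pytest.approx(6 * 15 * 0.75)

    def test_round_trip_doubles_vehicle_only_basis(self, params):
        rt = params.model_copy(update={"round_trip": True})
        one = out_of_pocket(WORKING, ServiceType.PHYSICIAN, 20.0, "u", params)
        two = out_of_pocket(WORKING, ServiceType.PHYSICIAN, 20.0, "u", rt)
        assert two.vehicle == pytest.approx(2 * one.vehicle)


class TestTelehealth:
    def test_geographically_invariant(self, params):
        a = telehealth_unit_cost(WORKING, None, params, region_scope="Northern")
        b = telehealth_unit_cost(WORKING, None, params, region_scope="urban")
        assert (a.lost_productivity, a.informal_caregiving, a.out_of_pocket) == (
            b.lost_productivity, b.informal_caregiving, b.out_of_pocket
        )

    def test_child_zero_productivity_full_attendance(self, params):
        uc = telehealth_unit_cost(CHILD, None, params)
        assert uc.lost_productivity == 0.0
        prof = params.time_profile(ServiceType.TELEHEALTH)
        hours = (prof.wait_minutes + prof.appointment_minutes) / 60.0
        assert uc.informal_caregiving == pytest.approx(
            1.0 * hours * params.hourly_wage, abs=0.01
        )

    def test_zero_data_rates(self, params):
        p = params.model_copy(update={"data_rate_phone": 0.0, "data_rate_internet": 0.0})
        assert telehealth_unit_cost(WORKING, None, p).out_of_pocket == 0.0


class TestEmissions:
    def test_zero_distance(self, params):
        assert emissions_per_visit_kg(0.0, params) == 0.0

    def test_linearity(self, params):
        one = emissions_per_visit_kg(10.0, params)
        assert emissions_per_visit_kg(30.0, params) == pytest.approx(3 * one)

    def test_calibrated_factor_reproduces_published_cells(self, params):
        ef = calibrate_emission_factor(
            bc.CALIBRATION_DISTANCE_KM, bc.CALIBRATION_EMISSIONS_KG
        )
        p = params.model_copy(update={"emission_factor_kg_per_l": ef})
        for scope, expected in {**bc.AUTHORITY_EMISSIONS_KG, **bc.STRATUM_EMISSIONS_KG}.items():
            table = pd.concat([bc.AUTHORITY_TRAVEL, bc.STRATUM_TRAVEL])
            d = float(table.set_index("scope").loc[scope, "distance_km"])
            assert emissions_per_visit_kg(d, p) == pytest.approx(expected, abs=0.01)

    def test_negative_distance_rejected(self, params):
        with pytest.raises(ValueError):
            emissions_per_visit_kg(-1.0, params)


class TestUnitCostDatabase:
    def test_cardinality(self, params):
        db = build_unit_cost_database(bc.STRATUM_TRAVEL, params)
        assert len(db) == 2 * len(ServiceType) * 3

    def test_total_decomposes_into_subunits(self, params):
        db = build_unit_cost_database(bc.AUTHORITY_TRAVEL, params)
        parts = db[["lost_productivity", "informal_caregiving", "out_of_pocket"]].sum(axis=1)
        assert np.allclose(db["total"], parts, atol=0.011)

    def test_age_linearity_for_outpatient_services(self, params):
        """UC(working) - UC(child) == UC(child) - UC(senior) within $1 for
        ED and physician rows (the attendance algebra: 1.5T vs 1.0T vs 0.5T)."""
        db = build_unit_cost_database(bc.AUTHORITY_TRAVEL, params)
        wide = db.pivot_table(
            index=["region_scope", "service_type"], columns="age_group", values="total"
        )
        outpatient = wide.loc[
            wide.index.get_level_values("service_type").isin(
                ["ED_CTAS_I_III", "ED_CTAS_IV_V", "PHYSICIAN"]
            )
        ]
        diff1 = outpatient["15-64"] - outpatient["0-14"]
        diff2 = outpatient["0-14"] - outpatient["65+"]
        assert np.allclose(diff1, diff2, atol=1.0)

    def test_telehealth_rows_identical_across_scopes(self, params):
        db = build_unit_cost_database(bc.AUTHORITY_TRAVEL, params)
        tele = db[db["service_type"] == "TELEHEALTH"]
        for _, grp in tele.groupby("age_group"):
            assert grp["total"].nunique() == 1

    def test_monotone_in_wage_distance_attendance(self, params):
        base = build_unit_cost_database(bc.AUTHORITY_TRAVEL, params)["total"]
        higher_wage = params.model_copy(update={"hourly_wage": params.hourly_wage + 5})
        assert (build_unit_cost_database(bc.AUTHORITY_TRAVEL, higher_wage)["total"]
                >= base - 1e-9).all()
        farther = bc.AUTHORITY_TRAVEL.assign(
            distance_km=bc.AUTHORITY_TRAVEL["distance_km"] * 1.5,
            duration_min=bc.AUTHORITY_TRAVEL["duration_min"] * 1.5,
        )
        assert (build_unit_cost_database(farther, params)["total"] >= base - 1e-9).all()
        att = {
            k: {r: min(1.0, v + 0.25) for r, v in d.items()}
            for k, d in params.caregiver_attendance.items()
        }
        fuller = params.model_copy(update={"caregiver_attendance": att})
        assert (build_unit_cost_database(bc.AUTHORITY_TRAVEL, fuller)["total"]
                >= base - 1e-9).all()

    def test_accommodation_triggers_only_beyond_threshold_scopes(self, params):
        """With the published authority distances, only the Northern scope
        (69.4 km one-way) crosses the 50 km accommodation threshold."""
        db = build_unit_cost_database(bc.AUTHORITY_TRAVEL, params)
        hosp = db[db["service_type"] == "HOSPITALIZATION"].set_index("region_scope")
        no_accom = params.model_copy(update={"accommodation_nights": 0})
        db0 = build_unit_cost_database(bc.AUTHORITY_TRAVEL, no_accom)
        hosp0 = db0[db0["service_type"] == "HOSPITALIZATION"].set_index("region_scope")
        delta = (hosp["out_of_pocket"] - hosp0["out_of_pocket"]).groupby("region_scope").sum()
        triggered = set(delta[delta > 0].index)
        assert triggered == {"Northern"}

    def test_report_view_rounds_half_up(self, params):
        db = pd.DataFrame(
            {
                "lost_productivity": [10.50], "informal_caregiving": [0.49],
                "out_of_pocket": [2.0], "total": [12.99],
            }
        )
        out = report_view(db)
        assert out.loc[0, "lost_productivity"] == 11
        assert out.loc[0, "informal_caregiving"] == 0
        assert out.loc[0, "total"] == 13

    def test_missing_travel_columns_rejected(self, params):
        with pytest.raises(ConfigurationError):
            build_unit_cost_database(pd.DataFrame({"scope": ["x"]}), params)

    def test_database_from_routed_synthetic_geography(self, agg_seed1, params):
        db = build_unit_cost_database(agg_seed1.rename(columns={}), params)
        assert set(db["region_scope"]) == set(agg_seed1["scope"])
        assert (db["total"] > 0).all()
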