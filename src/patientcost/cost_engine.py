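"""Per-visit unit costs and travel emissions.

A unit cost is the patient-paid cost of one visit for a given
(region scope x service type x age group) cell, decomposed into three
subunits:

* **lost productivity** -- foregone paid/unpaid work valued by the human
  capital method (hours x average hourly wage), accruing only to the
  working-age bin and capped at 8 h per 24 h for hospital stays;
* **informal caregiving** -- the accompanying caregiver's time at the same
  wage, scaled by an attendance probability that depends on age group and
  on whether the service is outpatient or a hospital admission (caregiver
  time is prorated to 8 h/day for admissions);
* **out-of-pocket** -- vehicle cost per km, parking, meals, caregiver
  accommodation for long-distance admissions, and telehealth data charges.

Travel emissions per visit are litres burned (distance x fuel efficiency)
times a kg CO2e per litre emission factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import ConfigurationError
from .params import (
    AgeBand,
    AgeBins,
    CostParameters,
    DEFAULT_AGE_BINS,
    ROLE_CHILD,
    ServiceClass,
    ServiceTimeProfile,
    ServiceType,
    round_cents,
    round_dollars,
)

__all__ = [
    "VisitTime",
    "OutOfPocket",
    "UnitCost",
    "visit_time_for",
    "lost_productivity",
    "informal_caregiving",
    "out_of_pocket",
    "telehealth_unit_cost",
    "unit_cost",
    "emissions_per_visit_kg",
    "calibrate_emission_factor",
    "build_unit_cost_database",
    "report_view",
]


@dataclass(frozen=True)
class VisitTime:
    """Time components of one visit, in minutes (travel on the configured
    one-way or round-trip basis)."""

    travel_min: float
    wait_min: float
    appointment_min: float

    def __post_init__(self) -> None:
        for name in ("travel_min", "wait_min", "appointment_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def total_h(self) -> float:
        return (self.travel_min + self.wait_min + self.appointment_min) / 60.0


@dataclass(frozen=True)
class OutOfPocket:
    """Itemised out-of-pocket expenses for one visit."""

    vehicle: float = 0.0
    parking: float = 0.0
    meals: float = 0.0
    accommodation: float = 0.0
    data: float = 0.0

    @property
    def total(self) -> float:
        return self.vehicle + self.parking + self.meals + self.accommodation + self.data


@dataclass(frozen=True)
class UnitCost:
    """Per-visit patient-paid cost for one (scope, service, age) cell."""

    region_scope: str
    service_type: ServiceType
    age_group: str
    lost_productivity: float
    informal_caregiving: float
    out_of_pocket: float

    @property
    def total(self) -> float:
        return self.lost_productivity + self.informal_caregiving + self.out_of_pocket


def visit_time_for(
    service_type: ServiceType, travel_duration_min: float, params: CostParameters
) -> VisitTime:
    """Assemble the visit time from the travel estimate and the service's
    wait/appointment profile.  Telehealth has zero travel; the round-trip
    flag doubles the travel leg."""
    profile = params.time_profile(service_type)
    if not service_type.is_in_person:
        travel = 0.0
    else:
        travel = travel_duration_min * (2.0 if params.round_trip else 1.0)
    return VisitTime(
        travel_min=travel,
        wait_min=profile.wait_minutes,
        appointment_min=profile.appointment_minutes,
    )


def lost_productivity(
    age_group: AgeBand,
    visit_time: VisitTime,
    params: CostParameters,
    service_type: ServiceType,
) -> float:
    """Foregone work time valued at the average wage.

    Zero outside the working-age bin.  For hospital admissions the charged
    hours are capped at ``productivity_cap_h_per_day`` per day of stay.
    """
    if not age_group.working:
        return 0.0
    if service_type is ServiceType.HOSPITALIZATION:
        stay = params.time_profile(service_type).length_of_stay_days
        raw_h = visit_time.total_h + stay * 24.0
        hours = min(raw_h, params.productivity_cap_h_per_day * math.ceil(stay))
    else:
        hours = visit_time.total_h
    return hours * params.hourly_wage


def informal_caregiving(
    age_group: AgeBand,
    service_type: ServiceType,
    visit_time: VisitTime,
    params: CostParameters,
) -> float:
    """Caregiver time at the wage rate, scaled by the attendance probability.

    For outpatient services the caregiver's time commitment equals the
    patient's (travel + wait + appointment); for admissions it is prorated
    to the daily cap times the length of stay.
    """
    attendance = params.attendance(age_group.role, service_type.service_class)
    if service_type is ServiceType.HOSPITALIZATION:
        stay = params.time_profile(service_type).length_of_stay_days
        hours = params.productivity_cap_h_per_day * stay
    else:
        hours = visit_time.total_h
    return attendance * hours * params.hourly_wage


def out_of_pocket(
    age_group: AgeBand,
    service_type: ServiceType,
    distance_km: float,
    region_scope: str,
    params: CostParameters,
    appointment_min: float | None = None,
) -> OutOfPocket:
    """Itemised direct expenses for one visit.

    Vehicle cost uses the configured distance basis; parking is one
    visit-day at the city-core rate for physician visits and at the
    hospital rate for ED visits, two days for admissions.  ED visits carry
    one patient meal; admissions carry 3 meals/day for 2 days for the
    caregiver, scaled by attendance, plus caregiver accommodation for two
    nights when the one-way distance exceeds the threshold.  Telehealth
    carries only data charges.
    """
    if distance_km < 0:
        raise ValueError("distance_km must be >= 0")
    if service_type is ServiceType.TELEHEALTH:
        if appointment_min is None:
            appointment_min = params.time_profile(service_type).appointment_minutes
        return OutOfPocket(data=params.blended_data_rate * appointment_min)

    basis_km = distance_km * (2.0 if params.round_trip else 1.0)
    vehicle = basis_km * params.vehicle_rate_per_km
    hosp_attendance = params.attendance(age_group.role, ServiceClass.HOSPITALIZATION)

    if service_type is ServiceType.PHYSICIAN:
        parking = params.parking_core_rate(region_scope)
        meals = 0.0
        accommodation = 0.0
    elif service_type.is_ed:
        parking = params.parking_hospital_rate(region_scope)
        meals = params.meal_value  # one patient meal, all CTAS levels
        accommodation = 0.0
    elif service_type is ServiceType.HOSPITALIZATION:
        parking = 2.0 * params.parking_hospital_rate(region_scope)
        # 3 caregiver meals/day on admission and discharge days
        meals = 6.0 * params.meal_value * hosp_attendance
        if distance_km > params.accommodation_distance_threshold_km:
            accommodation = (
                params.accommodation_nights
                * params.hotel_rate(region_scope)
                * hosp_attendance
            )
        else:
            accommodation = 0.0
    else:  # pragma: no cover
        raise ConfigurationError(f"unhandled service type {service_type}")
    return OutOfPocket(
        vehicle=vehicle, parking=parking, meals=meals, accommodation=accommodation
    )


def unit_cost(
    region_scope: str,
    service_type: ServiceType,
    age_group: AgeBand,
    distance_km: float,
    travel_duration_min: float,
    params: CostParameters,
) -> UnitCost:
    """Compute the full unit cost for one cell (subunits at cent precision)."""
    vt = visit_time_for(service_type, travel_duration_min, params)
    lp = lost_productivity(age_group, vt, params, service_type)
    cg = informal_caregiving(age_group, service_type, vt, params)
    oop = out_of_pocket(age_group, service_type, distance_km, region_scope, params)
    return UnitCost(
        region_scope=region_scope,
        service_type=service_type,
        age_group=age_group.label,
        lost_productivity=round_cents(lp),
        informal_caregiving=round_cents(cg),
        out_of_pocket=round_cents(oop.total),
    )


def telehealth_unit_cost(
    age_group: AgeBand,
    time_profile: ServiceTimeProfile | None,
    params: CostParameters,
    region_scope: str = "province",
) -> UnitCost:
    """Telehealth unit cost: wait + appointment time only, data charges in
    place of travel expenses.  Identical for every region scope."""
    if time_profile is not None:
        override = dict(params.time_profiles)
        override[ServiceType.TELEHEALTH] = time_profile
        params = params.model_copy(update={"time_profiles": override})
    return unit_cost(region_scope, ServiceType.TELEHEALTH, age_group, 0.0, 0.0, params)


def emissions_per_visit_kg(distance_km: float, params: CostParameters) -> float:
    """CO2-equivalent emissions (kg) for the travel of one in-person visit.

    Litres burned = distance x fuel efficiency (L/100 km); emissions =
    litres x emission factor (kg/L).  Linear and homogeneous in distance.
    """
    if distance_km < 0:
        raise ValueError("distance_km must be >= 0")
    basis_km = distance_km * (2.0 if params.round_trip else 1.0)
    return basis_km * params.fuel_l_per_100km / 100.0 * params.emission_factor_kg_per_l


def calibrate_emission_factor(
    distance_km: float, emissions_kg: float, fuel_l_per_100km: float = 7.06
) -> float:
    """Back out the kg CO2e/L emission factor from one known
    (distance, per-visit emissions) pair."""
    litres = distance_km * fuel_l_per_100km / 100.0
    if litres <= 0:
        raise ValueError("calibration requires positive distance and fuel use")
    return emissions_kg / litres


def emissions_per_km(params: CostParameters) -> float:
    """kg CO2e per one-way km implied by the configured fuel and factor."""
    return params.fuel_l_per_100km / 100.0 * params.emission_factor_kg_per_l


def build_unit_cost_database(
    travel_by_scope: pd.DataFrame,
    params: CostParameters,
    age_bins: AgeBins = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Assemble the unit-cost database.

    ``travel_by_scope`` carries one row per region scope with columns
    ``scope``, ``distance_km``, ``duration_min`` (e.g. the output of
    :func:`patientcost.routing.aggregate_travel`).  The result has one row
    per (scope x service type x age group) with the three subunits at cent
    precision, their total, and the per-visit travel emissions.
    """
    required = {"scope", "distance_km", "duration_min"}
    missing = required - set(travel_by_scope.columns)
    if missing:
        raise ConfigurationError(f"travel table missing columns {sorted(missing)}")
    rows = []
    for rec in travel_by_scope.itertuples(index=False):
        for service in ServiceType:
            dist = rec.distance_km if service.is_in_person else 0.0
            dur = rec.duration_min if service.is_in_person else 0.0
            for band in age_bins:
                uc = unit_cost(rec.scope, service, band, dist, dur, params)
                rows.append(
                    {
                        "region_scope": rec.scope,
                        "service_type": service.value,
                        "age_group": band.label,
                        "lost_productivity": uc.lost_productivity,
                        "informal_caregiving": uc.informal_caregiving,
                        "out_of_pocket": uc.out_of_pocket,
                        "total": round_cents(uc.total),
                        "distance_km": dist,
                        "duration_min": dur,
                        "emissions_kg": emissions_per_visit_kg(dist, params),
                    }
                )
    return pd.DataFrame(rows)


def report_view(db: pd.DataFrame) -> pd.DataFrame:
    """Report view of a unit-cost database: dollars rounded half-up."""
    out = db.copy()
    for col in ("lost_productivity", "informal_caregiving", "out_of_pocket", "total"):
        out[col] = out[col].map(round_dollars)
    return out
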