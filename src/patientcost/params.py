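"""Cost parameters, service time profiles and age bins.

Every monetary assumption of the costing model lives in
:class:`CostParameters` so that unit costs are a pure function of
(geography, parameters).  Defaults are the model's base case: 2023 CAD,
British Columbia average hourly wage $30.54, an 8 h/day productivity cap,
a compact reference vehicle at 7.06 L/100 km, and caregiver attendance
probabilities of 100%/50%/50% (child/working/senior) for outpatient
services and 75%/25%/25% for hospital admissions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigurationError

__all__ = [
    "ServiceType",
    "ServiceClass",
    "AgeBand",
    "AgeBins",
    "DEFAULT_AGE_BINS",
    "ALTERNATE_AGE_BINS",
    "ServiceTimeProfile",
    "CostParameters",
    "read_parameters",
    "round_cents",
    "round_dollars",
]


def round_cents(x: float) -> float:
    """Round a currency amount to the cent, half-up."""
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def round_dollars(x: float) -> int:
    """Round a currency amount to the whole dollar, half-up (report view)."""
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


class ServiceType(str, enum.Enum):
    """Health service types carrying distinct unit costs."""

    ED_CTAS_I_III = "ED_CTAS_I_III"
    ED_CTAS_IV_V = "ED_CTAS_IV_V"
    PHYSICIAN = "PHYSICIAN"
    HOSPITALIZATION = "HOSPITALIZATION"
    TELEHEALTH = "TELEHEALTH"

    @property
    def is_ed(self) -> bool:
        return self in (ServiceType.ED_CTAS_I_III, ServiceType.ED_CTAS_IV_V)

    @property
    def is_in_person(self) -> bool:
        return self is not ServiceType.TELEHEALTH

    @property
    def service_class(self) -> "ServiceClass":
        if self is ServiceType.HOSPITALIZATION:
            return ServiceClass.HOSPITALIZATION
        return ServiceClass.OUTPATIENT


class ServiceClass(str, enum.Enum):
    """Attendance-probability class: outpatient visits vs hospital admissions."""

    OUTPATIENT = "outpatient"
    HOSPITALIZATION = "hospitalization"


# Attendance roles: the child role takes the high caregiver-attendance
# coefficients; the working role is the only one accruing lost productivity.
ROLE_CHILD = "child"
ROLE_WORKING = "working"
ROLE_SENIOR = "senior"


@dataclass(frozen=True)
class AgeBand:
    """Half-open integer-year age interval [lower, upper).

    ``upper=None`` means unbounded above.  ``role`` selects the caregiver
    attendance coefficients; the productivity logic keys on ``working``
    (so alternate binnings need no code change).
    """

    label: str
    lower: int
    upper: Optional[int]
    role: str
    working: bool = False

    def contains(self, age: int) -> bool:
        return age >= self.lower and (self.upper is None or age < self.upper)


@dataclass(frozen=True)
class AgeBins:
    """An ordered partition of the non-negative integers into age bands."""

    bands: tuple[AgeBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ConfigurationError("age bins must contain at least one band")
        lowers = sorted(self.bands, key=lambda b: b.lower)
        if lowers[0].lower != 0:
            raise ConfigurationError("age bins must start at age 0")
        for a, b in zip(lowers, lowers[1:]):
            if a.upper is None or a.upper != b.lower:
                raise ConfigurationError(
                    f"age bins must tile the integers without gaps or overlap: "
                    f"{a.label!r} ends at {a.upper}, {b.label!r} starts at {b.lower}"
                )
        if lowers[-1].upper is not None:
            raise ConfigurationError("last age bin must be unbounded above")
        if sum(1 for b in self.bands if b.working) != 1:
            raise ConfigurationError("exactly one age bin must be flagged working")

    def band_for(self, age: int) -> AgeBand:
        for band in self.bands:
            if band.contains(age):
                return band
        raise ValueError(f"age {age} not covered")  # pragma: no cover

    def __iter__(self):
        return iter(self.bands)

    def labels(self) -> list[str]:
        return [b.label for b in self.bands]


DEFAULT_AGE_BINS = AgeBins(
    (
        AgeBand("0-14", 0, 15, ROLE_CHILD),
        AgeBand("15-64", 15, 65, ROLE_WORKING, working=True),
        AgeBand("65+", 65, None, ROLE_SENIOR),
    )
)

ALTERNATE_AGE_BINS = AgeBins(
    (
        AgeBand("0-19", 0, 20, ROLE_CHILD),
        AgeBand("20-59", 20, 60, ROLE_WORKING, working=True),
        AgeBand("60+", 60, None, ROLE_SENIOR),
    )
)


class ServiceTimeProfile(BaseModel):
    """Wait and appointment durations for one service type.

    Hospitalization additionally carries a length of stay in days; the
    telehealth profile implies zero travel.
    """

    service_type: ServiceType
    wait_minutes: float = Field(ge=0)
    appointment_minutes: float = Field(ge=0)
    length_of_stay_days: float = Field(default=0.0, ge=0)

    model_config = {"frozen": True}


def _default_time_profiles() -> dict[ServiceType, ServiceTimeProfile]:
    # Wait/appointment durations are package defaults chosen from typical
    # Canadian ED time-in-department and primary-care visit statistics;
    # all are configurable.  High-acuity ED visits (CTAS I-III) spend
    # substantially longer in department than CTAS IV-V.
    mk = ServiceTimeProfile
    return {
        ServiceType.ED_CTAS_I_III: mk(
            service_type=ServiceType.ED_CTAS_I_III,
            wait_minutes=90, appointment_minutes=135,
        ),
        ServiceType.ED_CTAS_IV_V: mk(
            service_type=ServiceType.ED_CTAS_IV_V,
            wait_minutes=90, appointment_minutes=60,
        ),
        ServiceType.PHYSICIAN: mk(
            service_type=ServiceType.PHYSICIAN,
            wait_minutes=30, appointment_minutes=15,
        ),
        ServiceType.HOSPITALIZATION: mk(
            service_type=ServiceType.HOSPITALIZATION,
            wait_minutes=120, appointment_minutes=0, length_of_stay_days=3,
        ),
        ServiceType.TELEHEALTH: mk(
            service_type=ServiceType.TELEHEALTH,
            wait_minutes=20, appointment_minutes=15,
        ),
    }


def _default_attendance() -> dict[str, dict[str, float]]:
    return {
        ServiceClass.OUTPATIENT.value: {
            ROLE_CHILD: 1.00, ROLE_WORKING: 0.50, ROLE_SENIOR: 0.50,
        },
        ServiceClass.HOSPITALIZATION.value: {
            ROLE_CHILD: 0.75, ROLE_WORKING: 0.25, ROLE_SENIOR: 0.25,
        },
    }


class CostParameters(BaseModel):
    """Every assumption of the costing model, with base-case defaults.

    Monetary fields are 2023 CAD.  Rates keyed "by scope" accept either a
    mapping from region-scope id (health authority or urban/rural stratum)
    to a rate, with ``default_*`` used for scopes not listed.
    """

    hourly_wage: float = Field(default=30.54, ge=0)
    productivity_cap_h_per_day: float = Field(default=8.0, ge=0)
    caregiver_attendance: dict[str, dict[str, float]] = Field(
        default_factory=_default_attendance
    )

    vehicle_rate_per_km: float = Field(default=0.50, ge=0)
    fuel_l_per_100km: float = Field(default=7.06, ge=0)
    # kg CO2e per litre of gasoline burned, calibrated once against the
    # reference per-visit emissions at 30.6 km (see cost_engine.calibrate).
    emission_factor_kg_per_l: float = Field(default=4.67 / (30.6 * 0.0706), ge=0)

    meal_value: float = Field(default=15.0, ge=0)
    accommodation_distance_threshold_km: float = Field(default=50.0, ge=0)
    accommodation_nights: int = Field(default=2, ge=0)

    default_hotel_rate: float = Field(default=150.0, ge=0)
    hotel_rate_by_scope: dict[str, float] = Field(default_factory=dict)
    default_parking_core_rate: float = Field(default=6.0, ge=0)
    parking_core_rate_by_scope: dict[str, float] = Field(default_factory=dict)
    default_parking_hospital_rate: float = Field(default=10.0, ge=0)
    parking_hospital_rate_by_scope: dict[str, float] = Field(default_factory=dict)

    telehealth_phone_weight: float = Field(default=0.8, ge=0, le=1)
    telehealth_internet_weight: float = Field(default=0.2, ge=0, le=1)
    data_rate_phone: float = Field(default=0.25, ge=0)  # $/min
    data_rate_internet: float = Field(default=0.05, ge=0)  # $/min

    # When True, vehicle cost, emissions and travel time all use the
    # round-trip (doubled) distance basis; the default one-way basis is the
    # one consistent with the calibrated per-visit emissions.
    round_trip: bool = False

    time_profiles: dict[ServiceType, ServiceTimeProfile] = Field(
        default_factory=_default_time_profiles
    )

    model_config = {"validate_assignment": True}

    @field_validator("caregiver_attendance")
    @classmethod
    def _attendance_valid(cls, v):
        for klass, by_role in v.items():
            if klass not in (c.value for c in ServiceClass):
                raise ValueError(f"unknown service class {klass!r}")
            for role, frac in by_role.items():
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(
                        f"attendance fraction {frac} for ({klass}, {role}) "
                        "outside [0, 1]"
                    )
        return v

    @field_validator(
        "hotel_rate_by_scope",
        "parking_core_rate_by_scope",
        "parking_hospital_rate_by_scope",
    )
    @classmethod
    def _rates_nonneg(cls, v):
        for scope, rate in v.items():
            if rate < 0:
                raise ValueError(f"negative rate {rate} for scope {scope!r}")
        return v

    @model_validator(mode="after")
    def _weights_sum_to_one(self):
        s = self.telehealth_phone_weight + self.telehealth_internet_weight
        if not math.isclose(s, 1.0, abs_tol=1e-9):
            raise ValueError(f"telehealth modality weights must sum to 1, got {s}")
        return self

    # -- scope-rate lookups ------------------------------------------------

    def hotel_rate(self, scope: str) -> float:
        return self.hotel_rate_by_scope.get(scope, self.default_hotel_rate)

    def parking_core_rate(self, scope: str) -> float:
        return self.parking_core_rate_by_scope.get(scope, self.default_parking_core_rate)

    def parking_hospital_rate(self, scope: str) -> float:
        return self.parking_hospital_rate_by_scope.get(
            scope, self.default_parking_hospital_rate
        )

    def attendance(self, role: str, service_class: ServiceClass) -> float:
        try:
            return self.caregiver_attendance[service_class.value][role]
        except KeyError as exc:
            raise ConfigurationError(
                f"no caregiver attendance entry for role {role!r}, "
                f"class {service_class.value!r}"
            ) from exc

    def time_profile(self, service_type: ServiceType) -> ServiceTimeProfile:
        try:
            return self.time_profiles[service_type]
        except KeyError as exc:
            raise ConfigurationError(
                f"no time profile configured for service {service_type.value}"
            ) from exc

    @property
    def blended_data_rate(self) -> float:
        """Telehealth data cost per appointment minute ($/min)."""
        return (
            self.telehealth_phone_weight * self.data_rate_phone
            + self.telehealth_internet_weight * self.data_rate_internet
        )


def read_parameters(path: str | Path) -> CostParameters:
    """Read a :class:`CostParameters` from a YAML mapping.

    Unspecified keys fall back to the base-case defaults; an empty file
    yields the defaults exactly.  Time profiles may be overridden per
    service type under a ``time_profiles`` key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"parameter file {path} must contain a mapping")
    if "time_profiles" in raw:
        profiles = _default_time_profiles()
        for key, fields in raw.pop("time_profiles").items():
            st = ServiceType(key)
            base = profiles[st].model_dump()
            base.update(fields)
            base["service_type"] = st
            profiles[st] = ServiceTimeProfile(**base)
        raw["time_profiles"] = profiles
    return CostParameters(**raw)
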