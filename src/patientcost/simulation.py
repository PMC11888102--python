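"""Annual population simulation: visits, costs, distance, emissions.

Per-person annual visit rates are applied to a simulated population
distributed over regions and age groups, and unit costs are applied per
(service x region x age) cell to obtain annual totals, including the
total one-way travel distance and its CO2e footprint.  Hybrid-care
scenarios divert a fraction of in-person visits to telehealth; an
ED-avoidance scenario reports the avoided share of emergency visits.

Default allocation is expected-value (deterministic); a seeded stochastic
mode draws multinomial allocations for uncertainty exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import bc_reference
from .cost_engine import emissions_per_km
from .errors import ConfigurationError
from .params import AgeBins, CostParameters, DEFAULT_AGE_BINS, ServiceType, round_dollars

__all__ = [
    "PopulationSpec",
    "VisitRates",
    "ServiceTotals",
    "SimulationResult",
    "default_bc_population",
    "allocate_visits",
    "annual_totals",
    "hybrid_scenarios",
    "ed_avoidance",
    "rebin_ages",
]

_MAX_AGE = 100  # year shares cover ages 0.._MAX_AGE inclusive


class PopulationSpec(BaseModel):
    """A simulated population: size, region shares and an age pyramid.

    The age structure is carried as per-year shares so that alternate age
    binnings can be applied without re-specifying the population.
    """

    size: int = Field(default=100_000, gt=0)
    region_shares: dict[str, float]
    age_year_shares: list[float]
    age_bins: AgeBins = DEFAULT_AGE_BINS

    model_config = {"arbitrary_types_allowed": True}

    @model_validator(mode="after")
    def _shares_valid(self):
        for name, shares in (
            ("region_shares", list(self.region_shares.values())),
            ("age_year_shares", self.age_year_shares),
        ):
            arr = np.asarray(shares, dtype=float)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in [0, 1]")
            if not math.isclose(arr.sum(), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} must sum to 1, got {arr.sum()!r}")
        if len(self.age_year_shares) != _MAX_AGE + 1:
            raise ValueError(
                f"age_year_shares must cover ages 0..{_MAX_AGE} "
                f"({_MAX_AGE + 1} entries)"
            )
        return self

    def band_shares(self, bins: AgeBins | None = None) -> dict[str, float]:
        """Aggregate the per-year age shares into the given bins."""
        bins = bins or self.age_bins
        out: dict[str, float] = {}
        for band in bins:
            out[band.label] = float(
                sum(s for age, s in enumerate(self.age_year_shares) if band.contains(age))
            )
        return out


class VisitRates(BaseModel):
    """Annual per-person visit rates by service."""

    physician_per_person_year: float = Field(default=2.7, ge=0)
    telehealth_per_person_year: float = Field(default=2.5, ge=0)
    ed_per_person_year: float = Field(default=0.42573, ge=0)
    ctas_i_iii_fraction: float = Field(default=0.60, ge=0, le=1)


def _bc_age_year_shares() -> list[float]:
    # BC-like pyramid: ~14% aged 0-14, ~65% 15-64, ~21% 65+, uniform within
    shares = np.zeros(_MAX_AGE + 1)
    shares[0:15] = 0.14 / 15
    shares[15:65] = 0.65 / 50
    shares[65:] = 0.21 / (_MAX_AGE + 1 - 65)
    shares /= shares.sum()
    return shares.tolist()


def default_bc_population(size: int = 100_000) -> PopulationSpec:
    """A BC-like simulated population over the five health authorities."""
    return PopulationSpec(
        size=size,
        region_shares=dict(bc_reference.AUTHORITY_POPULATION_SHARE),
        age_year_shares=_bc_age_year_shares(),
    )


#: services simulated annually (hospital admissions are per-visit costed
#: but have no published per-person annual rate)
SIMULATED_SERVICES = (
    ServiceType.ED_CTAS_I_III,
    ServiceType.ED_CTAS_IV_V,
    ServiceType.PHYSICIAN,
    ServiceType.TELEHEALTH,
)


def _service_totals_per_year(pop: PopulationSpec, rates: VisitRates) -> dict[ServiceType, float]:
    ed = pop.size * rates.ed_per_person_year
    return {
        ServiceType.ED_CTAS_I_III: ed * rates.ctas_i_iii_fraction,
        ServiceType.ED_CTAS_IV_V: ed * (1.0 - rates.ctas_i_iii_fraction),
        ServiceType.PHYSICIAN: pop.size * rates.physician_per_person_year,
        ServiceType.TELEHEALTH: pop.size * rates.telehealth_per_person_year,
    }


def allocate_visits(
    pop: PopulationSpec,
    rates: VisitRates,
    mode: str = "expected",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Distribute annual visits over (service x region x age group).

    ``expected`` mode returns the deterministic real-valued allocation
    (size x rate x region share x age share); ``stochastic`` mode draws a
    multinomial allocation per service with the given seed.  Both conserve
    the per-service total (exactly, or to integer rounding).
    """
    if mode not in ("expected", "stochastic"):
        raise ValueError(f"mode must be 'expected' or 'stochastic', got {mode!r}")
    band_shares = pop.band_shares()
    regions = list(pop.region_shares)
    cells = [
        (region, band, pop.region_shares[region] * share)
        for region in regions
        for band, share in band_shares.items()
    ]
    rng = np.random.default_rng(seed) if mode == "stochastic" else None
    rows = []
    for service, total in _service_totals_per_year(pop, rates).items():
        probs = np.array([p for _, _, p in cells])
        if mode == "expected":
            counts = total * probs
        else:
            counts = rng.multinomial(int(round(total)), probs / probs.sum()).astype(float)
        for (region, band, _), n in zip(cells, counts):
            rows.append(
                {
                    "service_type": service.value,
                    "region": region,
                    "age_group": band,
                    "visits": float(n),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ServiceTotals:
    """Annual totals for one service: visits, one-way km, t CO2e, cost."""

    visits: float
    distance_km: float
    emissions_t: float
    cost: float = float("nan")


@dataclass(frozen=True)
class SimulationResult:
    """Annual totals per (service x region), plus grand totals."""

    table: pd.DataFrame  # columns: service_type, region, visits, cost, distance_km, emissions_t
    scenario: str = "base"

    @property
    def total_cost(self) -> float:
        return float(self.table["cost"].sum())

    @property
    def total_distance_km(self) -> float:
        return float(self.table["distance_km"].sum())

    @property
    def total_emissions_t(self) -> float:
        return float(self.table["emissions_t"].sum())

    def by_service(self) -> pd.DataFrame:
        return self.table.groupby("service_type", sort=False)[
            ["visits", "cost", "distance_km", "emissions_t"]
        ].sum()

    def service_totals(self, service: ServiceType) -> ServiceTotals:
        sub = self.table[self.table["service_type"] == service.value]
        return ServiceTotals(
            visits=float(sub["visits"].sum()),
            distance_km=float(sub["distance_km"].sum()),
            emissions_t=float(sub["emissions_t"].sum()),
            cost=float(sub["cost"].sum()),
        )


def annual_totals(
    visits: pd.DataFrame,
    unit_cost_db: pd.DataFrame,
    travel_by_scope: pd.DataFrame,
    params: CostParameters,
    scenario: str = "base",
) -> SimulationResult:
    """Apply unit costs and travel distances to an allocation.

    Cost cell = visits x unit-cost total; distance cell = in-person visits
    x the scope's one-way distance; emissions follow from the configured
    per-km factor, reported in metric tons.
    """
    uc = unit_cost_db.set_index(["region_scope", "service_type", "age_group"])["total"]
    dist = travel_by_scope.set_index("scope")["distance_km"]
    per_km = emissions_per_km(params)
    rows = []
    grouped = visits.groupby(["service_type", "region"], sort=False)
    for (service, region), grp in grouped:
        st = ServiceType(service)
        cost = 0.0
        for rec in grp.itertuples(index=False):
            key = (region, service, rec.age_group)
            if key not in uc.index:
                raise ConfigurationError(f"no unit cost for cell {key}")
            cost += rec.visits * uc.loc[key]
        n_visits = float(grp["visits"].sum())
        if st.is_in_person:
            if region not in dist.index:
                raise ConfigurationError(f"no travel distance for scope {region!r}")
            distance = n_visits * float(dist.loc[region])
        else:
            distance = 0.0
        rows.append(
            {
                "service_type": service,
                "region": region,
                "visits": n_visits,
                "cost": cost,
                "distance_km": distance,
                "emissions_t": distance * per_km / 1000.0,
            }
        )
    return SimulationResult(table=pd.DataFrame(rows), scenario=scenario)


def hybrid_scenarios(
    base: ServiceTotals,
    in_person_fractions: Sequence[float],
    telehealth_unit_cost_total: Optional[float] = None,
) -> pd.DataFrame:
    """Scale a service's annual totals to hybrid in-person/telehealth mixes.

    Visits, distance and emissions scale linearly with the in-person
    fraction.  If a telehealth unit cost is supplied (and the base totals
    carry a cost), diverted visits are re-costed at the telehealth rate.
    """
    rows = []
    for f in in_person_fractions:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"in-person fraction must be in [0, 1], got {f}")
        row = {
            "in_person_fraction": f,
            "in_person_visits": round_dollars(base.visits * f),
            "distance_km": base.distance_km * f,
            "emissions_t": base.emissions_t * f,
        }
        if telehealth_unit_cost_total is not None and not math.isnan(base.cost):
            diverted = base.visits * (1.0 - f)
            row["cost"] = base.cost * f + diverted * telehealth_unit_cost_total
        rows.append(row)
    return pd.DataFrame(rows)


def ed_avoidance(base: ServiceTotals, avoided_fraction: float = 0.6) -> ServiceTotals:
    """The avoided share of ED activity under telehealth substitution.

    Reports the visits, distance and emissions *avoided* when the given
    fraction of ED visits shifts to telehealth (visits rounded half-up).
    """
    if not 0.0 <= avoided_fraction <= 1.0:
        raise ValueError(f"avoided_fraction must be in [0, 1], got {avoided_fraction}")
    return ServiceTotals(
        visits=round_dollars(base.visits * avoided_fraction),
        distance_km=base.distance_km * avoided_fraction,
        emissions_t=base.emissions_t * avoided_fraction,
        cost=base.cost * avoided_fraction if not math.isnan(base.cost) else base.cost,
    )


def rebin_ages(
    pop: PopulationSpec,
    bins: AgeBins,
    participation: Optional[dict[str, float]] = None,
) -> PopulationSpec:
    """Re-partition the population's age pyramid into alternate bins.

    The working flag travels with the bins, so downstream costing needs no
    change.  ``participation`` optionally reweights the per-year shares of
    named bands (e.g. to reflect labour-force participation below 1),
    renormalised to sum to 1.
    """
    shares = np.asarray(pop.age_year_shares, dtype=float)
    if participation:
        weights = {b.label: participation.get(b.label, 1.0) for b in bins}
        for age in range(len(shares)):
            shares[age] *= weights[bins.band_for(age).label]
        shares /= shares.sum()
    return pop.model_copy(
        update={"age_bins": bins, "age_year_shares": shares.tolist()}
    )
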