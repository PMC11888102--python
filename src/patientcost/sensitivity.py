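"""Deterministic one-way sensitivity analysis.

Each scenario varies exactly one parameter -- hourly wage, caregiver
attendance percentage, or a joint travel distance/duration scale -- while
holding everything else at base case, and recomputes the full unit-cost
database.  Scenarios are pure functions of (base inputs, overridden
value), so results are independent across grid points.

For the attendance dimension the scenario value *sets* every caregiver
attendance coefficient (all age groups, outpatient and admission alike),
matching the one-parameter reading of "percentage of appointments attended
by a caregiver"; deltas are reported against the grid's base-value
scenario so the base row is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost_engine import build_unit_cost_database
from .geo_model import Geography
from .params import AgeBins, CostParameters, DEFAULT_AGE_BINS
from .routing import StreetVsHaversine, compare_street_vs_haversine, route_all

__all__ = [
    "ScenarioGrid",
    "WAGE_GRID",
    "ATTENDANCE_GRID",
    "TRAVEL_GRID",
    "run_one_way",
    "routing_method_comparison",
]

_VALID_PARAMETERS = ("wage", "attendance", "travel_scale")
_KEY = ["region_scope", "service_type", "age_group"]


@dataclass(frozen=True)
class ScenarioGrid:
    """A one-way grid over a single parameter; must contain the base value."""

    parameter: str
    values: tuple[float, ...]
    base_value: float

    def __post_init__(self) -> None:
        if self.parameter not in _VALID_PARAMETERS:
            raise ValueError(
                f"parameter must be one of {_VALID_PARAMETERS}, got {self.parameter!r}"
            )
        if not any(np.isclose(v, self.base_value) for v in self.values):
            raise ValueError(
                f"grid for {self.parameter!r} must include the base value "
                f"{self.base_value}"
            )


WAGE_GRID = ScenarioGrid(
    "wage", (16.75, 20.0, 25.0, 30.54, 35.0, 40.0, 45.0, 50.0), base_value=30.54
)
ATTENDANCE_GRID = ScenarioGrid(
    "attendance", (0.0, 0.25, 0.50, 0.75, 1.00), base_value=0.50
)
TRAVEL_GRID = ScenarioGrid(
    "travel_scale", tuple(np.round(np.arange(0.5, 1.51, 0.1), 1)), base_value=1.0
)


def _apply_scenario(
    parameter: str,
    value: float,
    params: CostParameters,
    travel: pd.DataFrame,
    scale_distance: bool = True,
    scale_duration: bool = True,
) -> tuple[CostParameters, pd.DataFrame]:
    if parameter == "wage":
        return params.model_copy(update={"hourly_wage": float(value)}), travel
    if parameter == "attendance":
        att = {
            klass: {role: float(value) for role in by_role}
            for klass, by_role in params.caregiver_attendance.items()
        }
        return params.model_copy(update={"caregiver_attendance": att}), travel
    if parameter == "travel_scale":
        scaled = travel.copy()
        if scale_distance:
            scaled["distance_km"] = scaled["distance_km"] * value
        if scale_duration:
            scaled["duration_min"] = scaled["duration_min"] * value
        return params, scaled
    raise ValueError(f"unknown parameter {parameter!r}")  # pragma: no cover


def run_one_way(
    grid: ScenarioGrid,
    travel_by_scope: pd.DataFrame,
    params: CostParameters,
    age_bins: AgeBins = DEFAULT_AGE_BINS,
    scale_distance: bool = True,
    scale_duration: bool = True,
) -> pd.DataFrame:
    """Run every scenario in the grid and tabulate totals with deltas.

    Returns a long table with one record per (grid value x unit-cost row):
    columns ``parameter, value, region_scope, service_type, age_group,
    lost_productivity, informal_caregiving, out_of_pocket, total,
    delta_vs_base``.  The base-value scenario has delta 0 in every row.
    """
    base_params, base_travel = _apply_scenario(
        grid.parameter, grid.base_value, params, travel_by_scope,
        scale_distance, scale_duration,
    )
    base_db = build_unit_cost_database(base_travel, base_params, age_bins)
    base_totals = base_db.set_index(_KEY)["total"]

    frames = []
    for value in grid.values:
        sc_params, sc_travel = _apply_scenario(
            grid.parameter, value, params, travel_by_scope,
            scale_distance, scale_duration,
        )
        db = build_unit_cost_database(sc_travel, sc_params, age_bins)
        db.insert(0, "parameter", grid.parameter)
        db.insert(1, "value", float(value))
        db["delta_vs_base"] = (
            db.set_index(_KEY)["total"] - base_totals
        ).to_numpy()
        frames.append(db)
    return pd.concat(frames, ignore_index=True)


def routing_method_comparison(
    geo: Geography, threshold_km: float = 10.0
) -> tuple[pd.DataFrame, StreetVsHaversine]:
    """Street vs haversine distance per region, with the summary counts of
    regions within/beyond the threshold."""
    summary = compare_street_vs_haversine(geo, threshold_km=threshold_km)
    return summary.per_region, summary
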