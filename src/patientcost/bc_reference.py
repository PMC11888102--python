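"""Published British Columbia reference inputs.

Reproducing the full BC analysis requires the real 218-region geography
and emergency-department locations.  The published summary travel table
(population-weighted mean one-way distance and duration per health
authority, and per urban/rural stratum) is small enough to carry as an
input, letting the costing and simulation layers run BC-scale analyses
without any download.  All distances are one-way km, durations minutes.
"""

from __future__ import annotations

import pandas as pd

#: Population-weighted mean travel per health authority (one-way).
AUTHORITY_TRAVEL = pd.DataFrame(
    [
        {"scope": "Fraser", "distance_km": 30.6, "duration_min": 64.0},
        {"scope": "Interior", "distance_km": 42.8, "duration_min": 65.2},
        {"scope": "Northern", "distance_km": 69.4, "duration_min": 93.8},
        {"scope": "Vancouver Coastal", "distance_km": 12.06, "duration_min": 24.2},
        {"scope": "Vancouver Island", "distance_km": 24.4, "duration_min": 37.8},
    ]
)

#: Published per-visit CO2e (kg) per health authority, same rows as above.
AUTHORITY_EMISSIONS_KG = {
    "Fraser": 4.67,
    "Interior": 6.53,
    "Northern": 10.59,
    "Vancouver Coastal": 1.84,
    "Vancouver Island": 3.72,
}

#: Travel per urban/rural stratum (one-way); durations estimated from the
#: authority table's km/min ratios (the published stratum table prints
#: distance only).
STRATUM_TRAVEL = pd.DataFrame(
    [
        {"scope": "urban", "distance_km": 18.94, "duration_min": 33.0},
        {"scope": "rural", "distance_km": 91.2, "duration_min": 123.0},
    ]
)

#: Published per-visit CO2e (kg) per stratum.
STRATUM_EMISSIONS_KG = {"urban": 2.89, "rural": 13.92}

#: The (distance, emissions) pair used to calibrate the kg CO2e/L factor.
CALIBRATION_DISTANCE_KM = 30.6
CALIBRATION_EMISSIONS_KG = 4.67

#: Approximate BC population share per health authority.
AUTHORITY_POPULATION_SHARE = {
    "Fraser": 0.37,
    "Interior": 0.16,
    "Northern": 0.06,
    "Vancouver Coastal": 0.24,
    "Vancouver Island": 0.17,
}

#: Annual per-service base totals for a simulated population of 100,000
#: (in-person visits, total one-way km, metric tons CO2e) published for
#: the BC application; used as scenario baselines.
PHYSICIAN_BASE = {"visits": 270_000, "distance_km": 3_959_416.0, "emissions_t": 586.32}
ED_BASE = {"visits": 42_573, "distance_km": 624_311.0, "emissions_t": 92.45}
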