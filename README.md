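# patientcost

Even in single-payer health systems, patients pay to receive care: time
off work, a family member's time accompanying them, fuel, parking, meals,
hotel nights for distant hospital stays — and, for future generations,
the CO2 emitted driving to appointments. `patientcost` is a geospatial
costing toolkit for health-services researchers and policy analysts that
estimates these patient-paid costs and travel emissions per visit, and
aggregates them over an annual simulated population, for in-person,
telehealth and hybrid care.

## The model

For each small health region the street distance *d* and duration *t*
from the region centre to the nearest emergency department (the proxy for
the nearest point of care) is computed on a road network by
length-weighted shortest path, with duration from per-edge speed limits.
Region results aggregate to broader health authorities and to an
urban/rural stratification (class 1–4 urban, 5–7 rural) by
population-weighted mean.

The per-visit unit cost for a (region scope × service type × age group)
cell decomposes into three subunits:

- **Lost productivity** (human capital method):
  `LP = w · (t_travel + t_wait + t_appt)` for the working-age group, zero
  otherwise, with hospital stays capped at 8 h per 24 h
  (`LP = w · min(hours, 8 · days)`). Base wage *w* = $30.54/h (2023 CAD).
- **Informal caregiving**: `IC = a · w · h_caregiver`, where the
  attendance probability *a* is 100% (age 0–14) / 50% (15+) for
  outpatient visits and 75% / 25% for admissions; caregiver hours equal
  the patient's visit time, prorated to 8 h/day for admissions.
- **Out-of-pocket**: vehicle cost per km, parking (city-core rate for
  physician visits, hospital rate for ED, two days for admissions), one
  $15 patient meal per ED visit, caregiver meals (3/day × 2 days) and two
  hotel nights for admissions when the one-way distance exceeds 50 km,
  all attendance-weighted; telehealth visits carry only data charges
  (80% phone / 20% internet blend).

Per-visit emissions are `E = d · 7.06 L/100 km · EF`, with the emission
factor EF (kg CO2e/L) calibrated once from a published
(distance, emissions) anchor. Annual totals apply per-person visit rates
(2.7 physician, 2.5 telehealth, 0.42573 ED visits/person-year) to a
population distributed over regions and age groups; hybrid-care scenarios
divert a fraction of in-person visits to telehealth.

Service types: ED visits split by triage acuity (CTAS I–III vs IV–V),
physician visits, hospitalizations, telehealth.

## Worked example

```python
import patientcost as pc
from patientcost import bc_reference as bc
from patientcost.cost_engine import report_view

params = pc.CostParameters()                     # base-case assumptions
db = pc.build_unit_cost_database(bc.STRATUM_TRAVEL, params)
print(report_view(db))                           # dollars, rounded
```

selected rows:

```
region_scope service_type age_group  lost_productivity  informal_caregiving  out_of_pocket  total
       urban    PHYSICIAN      0-14                  0                   40             15     55
       urban    PHYSICIAN     15-64                 40                   20             15     75
       urban    PHYSICIAN       65+                  0                   20             15     35
       rural ED_CTAS_IV_V     15-64                139                   69             71    279
```

A working-age urban physician visit costs the patient $75: $40 of lost
work time, $20 of (half-probability) caregiver time, $15 of travel and
parking. Note the age-linearity the attendance rules imply:
75 − 55 = 55 − 35 = $20. Rural costs run much higher because the travel
leg (91.2 km vs 18.94 km one-way) enters all three subunits.

The same pipeline runs on generated geographies, end to end from a shell:

```sh
patientcost synth --n-regions 8 --seed 1 --out-dir geo/
patientcost routes --geo-dir geo/ --out routes.csv
patientcost unit-costs --geo-dir geo/ --out unit_costs.csv --dollars
patientcost sensitivity --geo-dir geo/ --parameter wage --out sens.csv
patientcost simulate --out-totals totals.csv --out-scenarios scenarios.csv
```

`routes.csv` for that seed spans 0 km (a region centred on its ED) to
300.26 km (a remote spoke road), the spread a sparse province shows.

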