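# Methods

## Scope and perspective

`patientcost` estimates the costs of attending health-care visits borne
by patients and their families (not the health system), plus the
CO2-equivalent emissions of the associated car travel. Costs are 2023
CAD, carried at cent precision and rounded half-up to whole dollars only
in report views. The analysis perspective covers three subunits — lost
productivity, informal caregiving, out-of-pocket expenses — for five
service types: ED visits at high (CTAS I–III) and low (CTAS IV–V)
acuity, physician visits, hospital admissions, and telehealth.

## Geospatial model

Each region contributes one representative trip: from its centre
(geometric centroid of the boundary polygon when one is supplied,
otherwise the stored point; population-weighted centres are not used) to
the nearest facility. "Nearest" is defined by minimum street distance on
a length-weighted shortest path; travel duration is derived on that same
path from per-edge speed limits, not optimised separately. Ties in
snapping break to the lowest node id, ties between facilities to the
lowest facility id, so results are reproducible. Regions aggregate to
authorities and to urban/rural strata (class 1–4 vs 5–7) by
population-weighted mean of distance and duration.

Per-visit travel quantities (vehicle cost, emissions, travel time) use
the **one-way** distance/duration by default: this is the basis under
which the calibrated emission factor reproduces the published per-visit
emissions. A `round_trip` flag doubles all three consistently.

## Cost formulas

With wage `w` ($/h), visit time `T` (h) = travel + wait + appointment,
stay `s` (days), daily cap `c` = 8 h, attendance `a(age, class)`:

| Subunit | Outpatient (ED/physician/telehealth) | Hospitalization |
|---|---|---|
| Lost productivity (working bin only) | `w·T` | `w·min(T + 24s, c·⌈s⌉)` |
| Informal caregiving | `a·w·T` | `a·w·c·s` |
| Out-of-pocket | vehicle + parking + ED patient meal (+ data for telehealth) | vehicle + 2-day parking + 6 caregiver meals·a + 2 hotel nights·a if one-way distance > 50 km |

Accommodation never applies to ED or physician visits. The ED meal is
charged once per visit to the patient at every acuity; caregiver meals
only arise for admissions. Telehealth visits have zero travel: lost
productivity and caregiving use wait + appointment only, and
out-of-pocket is a blended data charge
`(0.8·rate_phone + 0.2·rate_internet) × appointment minutes`, so
telehealth unit costs are identical in every region scope.

Emissions per visit are `d × f/100 × EF` with fuel efficiency
`f = 7.06 L/100 km` (compact reference vehicle). The emission factor
defaults to `EF = 4.67/(30.6 × 0.0706) ≈ 2.1617 kg CO2e/L`, calibrated
once against the Fraser-authority anchor; this single calibration
reproduces every other published authority and stratum per-visit
emission cell to ±0.01 kg. (The published annual scenario table implies
a slightly lower ≈0.148 kg/km versus the ≈0.1526 kg/km this factor
gives; we calibrate to the per-visit tables and note the discrepancy
rather than averaging it away.)

## Parameters

Base-case defaults, all configurable via `CostParameters` / YAML:
wage $30.54/h (BC average); productivity cap 8 h/day; attendance
100/50/50% (child/working/senior) outpatient and 75/25/25% admission;
meal $15; accommodation threshold 50 km one-way, 2 nights; telephone/
internet weights 0.8/0.2. Values the source appendix does not print in
the main text are package choices at realistic 2023 CAD levels: vehicle
$0.50/km, hotel $150/night, city-core parking $6/day, hospital parking
$10/day, phone data $0.25/min, internet data $0.05/min, hospital length
of stay 3 days. Wait/appointment profiles default to 90+135 min (CTAS
I–III), 90+60 (CTAS IV–V), 30+15 (physician), 120 min admission
processing, 20+15 (telehealth) — typical Canadian time-in-department and
primary-care figures. Because these durations are assumptions, tests
assert structural properties of the cost surface (decomposition,
age-linearity, monotonicity) rather than specific dollar values.

Age bins are half-open integer-year intervals; the `working` flag, not
the label, drives productivity, so the alternate 0–19/20–59/60+ binning
is a data change, not a code change. The caregiver-attendance role
(child/working/senior) travels with the bins the same way.

## Synthetic geography

The generator emulates a small province: a 5×5 urban street grid
(50 km/h, winding factor 1.15 over straight-line) hosting facilities and
urban centroids, and rural spoke roads (80 km/h, factor 1.25) whose
street lengths are spread geometrically from 8 to 280 km. One urban
region sits on a facility node, so default geographies span
nearest-facility distances from 0 to beyond 100 km — matching the
0.59–302 km spread of a real sparse province. Construction guarantees
connectivity and edge length ≥ straight-line distance, hence street ≥
haversine everywhere. It does not emulate ferries, seasonal closures,
congestion, or multiple competing facilities per urban block; passing
tests therefore demonstrate correctness of the computation, not the
realism of any particular jurisdiction's travel times.

## Sensitivity analysis

One-way deterministic scenarios vary a single dimension with everything
else at base: wage grid $16.75–$50, attendance grid 0–100% in 25%
steps, travel scale 0.5–1.5 in 0.1 steps (distance and duration scaled
jointly by default; flags separate them). Scenarios are pure functions
of (base inputs, overridden value) — no caching — so grid points are
independent. The attendance scenario *sets* every attendance
coefficient to the grid value, reading "percentage of appointments
attended" as a single model-wide parameter; deltas are therefore
reported against the grid's base-value scenario (50%), which makes the
base row exactly zero while keeping the 0% scenario's caregiving
identically zero. Totals are affine in wage and in the travel scale;
tests verify the slopes are row-constant.

## Population simulation

Defaults reflect the published application: 100,000 persons, region
shares matching the five BC health authorities' population shares, a
14/65/21% age pyramid (uniform within bands, ages 0–100), rates 2.7
physician and 2.5 telehealth visits/person-year and 42,573 ED
visits/100,000 (CTAS I–III share 0.60 — a package choice, the source
derives it from registry data it does not print). Expected-value
allocation is the default because published annual tables show no
sampling noise; a seeded multinomial mode supports uncertainty
exploration, and their totals agree within Monte-Carlo error (checked at
200 replicates, ±3 SE). Hybrid-care scenarios scale in-person visits,
distance and emissions linearly in the in-person fraction and re-cost
diverted visits at the telehealth unit cost; the ED-avoidance row
reports the *avoided* share (visits rounded half-up). Simulated annual
distance uses each scope's weighted-mean one-way distance per visit; the
published scenario table's implied physician km/visit is lower than the
authority means and is not forced.

## Numerical choices and limitations

Currency arithmetic rounds each subunit to the cent (half-up); totals
are sums of rounded subunits; dollar rounding happens only in report
views. Shortest paths use Dijkstra with float weights and a 1e-12 tie
band. Degenerate inputs fail loudly: empty networks, all-zero weights,
unreachable facilities, missing attendance entries or time profiles all
raise typed errors.

Known limitations: no health-system capacity feedback (ED closures),
no seasonal or congestion effects, no quality-of-care or emotional
burden costs, caregiver time assumed equal to patient time (no
drop-off/pick-up doubling), hotel and parking rates as flat per-scope
values.
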