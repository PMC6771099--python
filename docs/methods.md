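# Methods

## Scope and data model

The pipeline analyses one diagnosis group in one year (a census snapshot,
not a sample): admission records are filtered by exact match on a
diagnosis-group code (ICD hierarchy parsing is deliberately out of scope)
and optionally by year. Units (municipalities) carry pre-computed centroid
coordinates; no shapefile ingestion or polygon work is done. Records whose
residence or hospital unit is absent from the unit table are a hard error in
`strict` mode (the default) or dropped with a logged count in `lenient`
mode — registry-cleaning rules differ between studies, so both behaviours
are explicit rather than implicit.

## OD matrix and the significance filter

`build_od_matrix` counts records into a square origin × destination matrix
over the full unit universe; the grand total always equals the record count
(a conservation identity asserted in tests and auditable from the stage
logs). The significance filter retains an origin only when its **total**
flow into the study hospital set strictly exceeds `min_sent_patients`
(default 5): "more than 5" is read as ≥ 6, and the rule is applied at the
origin level, not per edge, because it delimits which municipalities belong
to the study at all. A `per_edge` variant is available via
`origin_filter_mode`; there the same strict threshold is applied to each
origin→hospital edge individually, with self-flows (local care) never
filtered. Hospital-set members are always retained as origins.

## LIFO / LOFI and classification

LIFO = (1 − inflow/H)·100 and LOFI = (1 − outflow/R)·100, with H the
hospitalizations inside the subject and R the subject residents' cases.
Conventions:

- **Sets aggregate before the ratio.** A municipality set is scored as one
  merged unit — flows internal to the set count as neither inflow nor
  outflow. Averaging member coefficients would weight small towns equally
  with the hub and is not what a market-delineation test means.
- **0/0 is Undefined, not 100%.** A unit with no hospital activity (H = 0)
  has no LIFO; a unit with no resident cases has no LOFI. An undefined
  coefficient can never yield a Sufficient label.
- **Classification is strict and unrounded.** Sufficient iff both
  coefficients are defined and strictly greater than the threshold,
  evaluated on full-precision values; reports print both the rounded
  integer percent and the exact value. A subject printing "75%" can thus be
  Sufficient (its unrounded value is above 75) — rounding is presentation,
  never logic.

## Successive enlargement

`frech_enlarge` evaluates the seed set; while Insufficient (or Undefined)
it annexes the external unit with the largest total exchanged flow
(in + out) with the current set, ties broken lexicographically by unit id,
re-evaluating after each annexation. It stops when Sufficient, when every
unit is in the set, or when no external unit has positive exchange (the
final label then stands as-is). The ranking criterion is genuinely open in
the literature; `exchange` is the default because sufficiency is violated by
boundary-crossing flows in either direction, and `inflow` and `distance`
rankings are exposed as configuration for sensitivity checks. The full
trace (added unit, set size, coefficients, label per step) is reported.

## Flow network

Cross-border entries become directed weighted edges residence → hospital;
diagonal entries are stored as a `self_flow` node attribute instead of
self-loops, so the graph isolates inter-municipal structure while the
identity Σ edge weights + Σ self-flows = record count still holds. Hubs are
ranked by in-strength (patients attracted), components are weak
(direction-ignored: the question is whether places are linked at all, not
mutual reachability), and hub removal is a plain node deletion on a copy.

Per-origin entropy is H_i = −Σ p_j ln p_j over the origin's destination
shares. Defaults: natural log, self-flows included as a destination, and
normalization by ln(m) over the m destinations actually used (0 when
m = 1), giving a [0, 1] index. All three choices are exposed because
entropy conventions vary between studies; absolute values are therefore not
comparable across differently configured analyses — only orderings within
one configuration are meaningful.

## Geometry

Distances are haversine on a sphere of configurable radius (default
6371.0088 km, the IUGG mean radius). At the 25–70 km scale of
intermunicipal displacement the ellipsoidal correction is sub-kilometre and
far smaller than the error already incurred by using centroids instead of
road travel. Displacement statistics weight each cross-border OD entry by
its patient count; self-flows involve no displacement and are excluded, and
a mean with no contributing flow is reported as undefined rather than zero.
Catchment quartiles are computed per destination over its own origins'
intensities (25/50/75 percentiles, linear interpolation, boundary ties to
the lower quartile); a pooled-quartile variant would mix incomparable
intensity scales across destinations and is not the default.

## Synthetic scenario

The generator emulates the statistical structure of a hub-dominated
regional hospital system so that every pipeline stage is testable without a
confidential registry. Defaults of `SyntheticScenario`:

| parameter | default | meaning |
|---|---|---|
| `n_units` / `n_designated` / `n_micro_regions` | 60 / 26 / 3 | functional universe, designated region, micro-regions |
| `hub_bed_share` | 0.75 | hub's share of designated-region beds |
| `hub_population_share` | 0.52 | hub's share of designated-region population |
| `population_range` | 2 000–80 000 | log-uniform non-hub populations |
| `birth_rate` | 0.015 /inhab/yr | drives case volumes |
| `episodes_per_birth` | 1.1 | pregnancy/puerperium episodes exceed births |
| `attraction_exponent` γ | 1.0 | beds^γ attractiveness |
| `decay_scale_km` δ | 30 | exponential distance decay exp(−d/δ) |
| `local_preference` λ | 25 | multiplier for staying in town |
| `hub_preference` η | 2 | multiplier for the hub |
| `hospital_unit_fraction` | 0.35 | share of units with any beds |
| `beds_per_thousand` | 2.5 | non-hub hospital size vs population |
| `bounding_box` | ~1.8° × 1.8° | ≈ 200 km main axes |

Design choices: **exponential decay** rather than power-law avoids the
d = 0 singularity at self-flows; **hospitals go to the hub and the most
populous other towns** (hospital presence correlates with town size;
smaller units have beds = 0 and are origins only); the hub sits at the
bounding-box centre with the designated region as its `n_designated`
nearest neighbours, split into micro-regions by angular sector; the hub's
population and beds are set from the share parameters so the stated
structure holds exactly. λ and η are preference calibration knobs, not
estimates from any dataset; with the defaults the designated region shows
roughly a quarter of resident hospitalizations as cross-border, a
Sufficient region with Insufficient micro-regions, and hub-bound trips
longer than other cross-border trips — the structure the analysis is meant
to detect. Seeding is hierarchical: a geometry stream plus one stream per
origin (derived from the global seed and a CRC of the unit id), so adding a
bed-less unit leaves the other origins' draws untouched.

What the generator does **not** emulate: temporal dynamics, severity mix,
road-network travel times, registry coding errors, or inter-annual
variation. Tests passing on synthetic data therefore demonstrate the
correctness and structural sensitivity of the pipeline, not empirical
claims about any real region.

## Numerical conventions and problem sizes

Counts are exact integers end to end; coefficients are computed in floating
point only at the final ratio, so identities such as the closed-system
LIFO = LOFI = 100 hold exactly. Intensity rows sum to 1 within 1e−12.
The test suite and the acceptance script run the full 60-unit scenario
(≈ 33 000 records per seed) across 20 seeds, which completes in a few
seconds; larger universes scale linearly in records and quadratically in
units through the distance matrix.

## Known limitations

- The significance filter's joint (origin-level) reading is a modelling
  choice; per-edge filtering changes which small towns enter the study.
- Entropy values are convention-dependent (see above).
- Centroid haversine distance understates true travel effort, especially
  for large municipalities.
- The catchment quartile construction is per destination; cross-destination
  comparisons of quartile labels are not meaningful.
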