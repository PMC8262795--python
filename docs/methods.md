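# Methods

This note documents the model behind `greentrack`, the parameters that
matter, the numerical and design choices made where the procedure was
genuinely open, what the synthetic generator does and does not emulate,
and known limitations.

## The data-generating regime

The pipeline targets GPS streams collected by a geofence-triggered app: the
device samples its position roughly every 10 s but fixes are stored only
while the device is within ~10 m of a greenspace boundary (a privacy and
battery measure). Consequences that shape every stage:

- there is no explicit trip structure — visits appear as bursts of fixes
  separated by silence;
- a large share of recorded movement is travel *along the outside* of
  greenspace boundaries (pavements and roads inside the 10 m buffer),
  including vehicular travel;
- civilian receivers scatter horizontally by roughly 5–20 m, and
  occasionally report corrupt altitudes (values near 0 m, or far above any
  plausible elevation) from bad satellite geometry.

All internal geometry is planar, in a local spherical transverse-Mercator
projection centred on the data (metres). At city scale the projection
distortion is ≲ 10⁻⁴ and the neglect of ellipsoidal flattening ≲ 0.3 %,
both far below GPS noise; the closed forms are exactly invertible, so
lon/lat round-trips are lossless. Altitude passes through unchanged — the
altitude filter is deliberately applied to raw reported values.

## Pipeline parameters

| parameter | default | role |
|---|---|---|
| `gap_s` | 600 s | silence longer than this splits a device's stream into trips; gaps equal to the threshold do **not** split (strict inequality). Shorter thresholds (2–5 min, typical for stop detection) over-fragment geofenced data, where signal loss inside a visit is common. |
| `alt_min_m`, `alt_max_m` | 19, 592 m | the study area's elevation range; fixes outside it are satellite errors |
| `alt_lower_buffer_m`, `alt_upper_buffer_m` | 1, 30 m | tolerance around the band; the lower buffer is tight because corrupt fixes cluster at ±1 m, the upper loose for ordinary error |
| `min_trip_duration_s`, `min_trip_points` | 70 s, 3 | below either, a burst more likely reflects passing within the geofence than a visit |
| `vmax_clean_ms`, `jump_allowance_m` | 7 m/s, 20 m | jump criterion for cleaning: a consecutive pair violates when 3-D displacement > `vmax·Δt + allowance`. 7 m/s bounds virtually all pedestrians, runners and most cyclists; the additive 20 m absorbs positional error at short Δt |
| `interp_interval_s` | 10 s | vertex spacing of the interpolated path; matches the app's sampling request |
| `ma_window_s` | 300 s | moving-average window for the inside-proportion and speed filters |
| `inside_min_frac`, `vmax_filter_ms` | 0.5, 7 m/s | window thresholds: vertices with window mean inside-proportion < 50 % or mean speed > 7 m/s are discarded |
| `flag_min_distance_m` | 25 m | trips not exceeding this length are flagged (stationary receiver or no meaningful trip) |
| `flag_entrance_max_m` | 25 m | endpoint further than this from every mapped entrance flags probable incomplete data |
| `flag_vmax_ms` | 5 m/s | average speed at or above this flags probable vehicular travel; stricter than the 7 m/s cleaning bound, which is deliberately permissive |
| `flag_building_max_frac`, `flag_inside_min_frac` | 0.5 | flag when more than half of time *or* distance is inside buildings, or less than half is inside greenspace |
| `geofence_buffer_m` | 10 m | simulation only: emission radius around greenspace polygons |
| `min_user_trips` | 5 | user-summary subset "users with ≥ 5 trips" |

## Algorithmic choices where the procedure was open

**Quality-segment removal.** The cleaning loop splits a trip at violating
pairs into *quality segments*, repeatedly deletes the shorter of the first
adjacent pair, and re-segments until a single segment remains. Two details
are not fixed by the procedure's description and are chosen here for
determinism: "shorter" means *fewer fixes* (ties delete the later
segment), and comparison is left-to-right with re-segmentation after every
deletion. A consequence worth knowing: after a deletion the junction pair
spans the deleted segment's whole time interval, so the displacement
criterion (`vmax·Δt + allowance`) usually accepts the junction — fast
vehicle tracks can therefore survive cleaning as sparse remnants. These
remnants are exactly what the certainty flags then mark (high speed,
endpoints far from entrances); the zero-flag subset is the pipeline's
final, credible visit set, and the recovery benchmark scores vehicle
elimination at that level (raw survival is reported alongside).

**Interpolation grid.** Vertices sit at `t₀ + k·interval` with the final
fix appended when off-grid; no extrapolation and no smoothing (smoothing
was found to bend outside paths across boundaries, and genuinely meandering
in-park movement should not be straightened). Under the nominal regime —
timestamps at 10 s multiples, as the app records — every source fix is a
grid vertex, so the interpolated polyline preserves the fix polyline's
length exactly; with irregular timestamps, off-grid corner fixes fall
between vertices and the polyline can shorten slightly. Vertices always
lie on the source polyline. Altitude is not interpolated: stages 4–5 are
purely planar.

**Moving-average window.** Centred, time-based (vertices with
|t − tᵢ| ≤ 150 s), truncated at path ends. A centred window avoids phase
lag at entrances and exits, where a trailing window would systematically
discard the entry minutes of a genuine visit. Both tests (inside
proportion, mean speed) are evaluated on the same pass over the annotated
path and their discard sets combined before runs are split, so the result
does not depend on evaluation order. Paths shorter than the window are
judged whole — inside proportion over all vertices and the mean of vertex
speeds (the same statistic the windowed filter averages) — and kept or
discarded in one piece. Surviving runs need ≥ 2 vertices; split pieces get
suffixed ids (`7 → 7.1, 7.2`) to preserve provenance.

**Membership and attribution conventions.** Point-in-polygon treats
boundaries as inside (an entrance point lies *on* the boundary and must
count as in-greenspace). Distance shares attribute each inter-vertex
segment by its midpoint's membership; time shares weight each vertex by
half its adjacent intervals, which sums exactly to the trip duration. For
a degenerate zero-length path the distance share falls back to the vertex
location's membership. With no mapped entrances, endpoint-entrance
distances are +∞ — the incomplete-data flag is then always raised, and the
audit distinguishes this data gap from a genuine distance.

**Flag polarity and boundaries.** A flag records *failure* of a validity
criterion; `n_flags = 0` is the highest-confidence class. The time/distance
criteria are conjunctive for validity (both must pass), so either failing
raises the flag. Boundary equalities follow the criteria literally: length
exactly 25 m and speed exactly 5 m/s are flagged; exactly 50 % shares pass.

**Summaries.** User-averaged statistics first average within device so
every user contributes equally. A user's recording period is the
first-to-last trip start date, inclusive in whole days (minimum one day);
visit frequency is trips per day over that period, and daily/weekly
exposure totals are `frequency × mean` and `7 × daily`. Medians use the
even-count midpoint convention; standard deviations are sample (n−1).
Destination tallies count each distinct greenspace type a trip touches
once per trip (so type totals may exceed the trip count), with a per-user
variant counting each (user, greenspace) pair once.

## The synthetic generator

`make_map` packs 100 m–1 km convex-ish polygons pairwise ≥ 30 m apart,
places 2–6 entrance points on each boundary and 0–2 rectangular buildings
strictly inside, with types drawn from a configurable typology. Agents
(`park_walker`, `park_runner`, `boundary_passerby`, `vehicle_passby`,
`building_visitor`, `stationary`) follow piecewise-linear waypoint routes
at a speed sampled once per track from the kind's band (walkers
0.7–1.5 m/s, runners 2–4 m/s, vehicles 8–20 m/s). Walker and runner tours
run entrance → interior waypoints → entrance and are extended until they
last at least ~3 minutes at the kind's top speed, emulating a genuine visit
(observed median visit durations are around 5 minutes); passers-by and
vehicles hug the boundary ~5 m outside. Emission follows the geofence
(true position within the 10 m buffered union), horizontal noise is
isotropic Gaussian (default sd 5 m, the optimistic end of the 5–20 m range;
mean displacement is therefore Rayleigh, sd·√(π/2)), altitude corruption
reproduces the two observed failure modes (values in [−1, 1] m and values
above the plausible band), and dropouts suppress geometric-length runs of
fixes. Every injection is recorded in a per-track ground truth with a
constructed `should_survive` label and expected flag set.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: urban-canyon multipath (spatially correlated,
non-Gaussian error), road networks and realistic route choice, multi-day
revisit behaviour, device heterogeneity, and real greenspace shapes
(concave, nested, or touching). Benchmark rates on synthetic scenarios
bound the pipeline's behaviour under its stated error model, not its field
accuracy.

## Problem sizes and determinism

The validation battery uses 1 000 random short trips for the
cleaning-vs-brute-force check, 200 paths for the window-filter check, 500
trips for interpolation geometry, 1 000 attribute vectors for the flag
table, 1 000 streams for segmentation properties, and 100 scenarios per
agent kind (60 in the acceptance script) for the recovery benchmark; the
whole suite runs in well under a minute on one core. All stochastic tests
and the acceptance script draw every random quantity from explicitly
seeded generators and are bit-reproducible under a fixed seed.

## Known limitations

- The quality-segment loop is order-dependent by construction; a different
  (but equally defensible) comparison order can keep a different remnant.
  The chosen order is documented above and enforced by an exact
  brute-force equivalence test.
- Entrance-distance flags inherit the completeness of the entrance layer;
  informal entrances (broken fences) make complete layers rare in practice.
- Interpolating linearly across long in-trip signal gaps can draw chords
  through space the user never crossed (including across greenspace
  interiors); the window filter bounds, but does not eliminate, the effect.
- Home distances are straight-line from the home point to the trip start,
  not network distances.
- The pipeline judges *visits*, not activities: it cannot distinguish a
  slow cyclist from a pedestrian, and does not attempt mode classification
  beyond the speed thresholds.
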