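# Methods

This note records the models, parameter defaults, and numerical choices
behind each stage of the toolkit, and what the synthetic-data tests do and
do not demonstrate about real sensor data.

## Data model and conventions

Coordinates are WGS84 decimal degrees; timestamps carry a UTC offset and
all day boundaries are evaluated on the participant's local clock (default
UTC+08:00, configurable via `lifespace.core.LOCAL_TZ`). Dwell intervals are
half-open `[arrive, depart)`. A participant diary is exactly 14 consecutive
days; a day is invalid when any fix falls outside the configured geographic
box (default lat 1.1–1.5, lon 103.55–104.15), when the participant declared
it invalid or carried no device, or when it has no data at all, with that
precedence. Participants lacking 14 valid days are excluded from cohort
metric output and listed separately. Runs of ≥ 3 consecutive no-data /
no-device days raise compliance alerts, mirroring field-monitoring
practice.

Duplicate fix timestamps within a participant collapse last-wins (sensor
resends are common); malformed rows are dropped and logged, never fatal.

The 14-code activity taxonomy (home, work, dining, shopping, market,
recreation, exercise, healthcare, social, religious, education, errand,
escort, other) is a configuration default, not a hard-coded truth: the
`Taxonomy` type accepts any 14 unique codes that include `home`.

## Fix filtering

Fixes are dropped for reported accuracy > 100 m, altitude > 300 m
(implausible at ground level in a low-lying city), or an implied speed from
the previous kept fix > 250 km/h. Each drop carries a reason code and the
drop log is exposed.

## Stay-node detection

A stop is a maximal run of consecutive fixes whose **minimum enclosing
circle** has diameter ≤ 50 m, spanning ≥ 60 s. "Within a 50-m area" is
deliberately read as an enclosing-circle condition rather than a
centroid-radius test: the circle test is the geometrically exact reading
and is what the brute-force oracle in the test suite enumerates. The MEC is
computed with Welzl's randomized incremental algorithm (deterministically
seeded); because enclosure is monotone as a window grows, greedy forward
extension finds the maximal window per start index, and the scan resumes
after an accepted window. A sequential scan was chosen over density
clustering because it preserves arrival/departure times, which every
duration metric needs.

Post-processing: candidates within 50 m of a **place signature** (a
validated home/office/amenity location) snap to its coordinates and type;
adjacent stops whose connecting gap contains no fix farther than the
cluster radius from their joint location merge (GPS jitter can split one
true stay); adjacent stops snapped to the same signature always merge.

## Trip segmentation and mode classification

Stops with dwell ≥ 300 s are activity stops; shorter ones are transfer
candidates. Movement between consecutive activity stops is one trip.
Transfer candidates split the movement into candidate segments, each
classified by **median inter-fix speed**: < 7 km/h walk, < 20 km/h bicycle,
otherwise motorized; a motorized segment with ≥ 80 % of fixes within 150 m
of a rail polyline is typed train. Bus vs car cannot be separated by speed
alone and is left to the diary-validation overlay, as in production travel
diary platforms where participants confirm each trip.

A **leg is a maximal run of one mode**, so adjacent same-mode segments
re-join. Across a transfer candidate that is *not* a known transit
signature, a boundary additionally requires a reliable mode change: when
either side has fewer than 10 fixes, its median speed is too noisy to
assert a distinct mode (one inflated interval shifts a 4-sample median),
so the combined path is classified and absorbs the short side when the
combined mode agrees with either side. This makes leg counts robust to
phantom micro-stops that GPS noise creates mid-walk, at the cost of
missing genuine mode changes flanked by very short segments at unknown
locations — a case real deployments resolve through the signature database
or user validation. The 300-s transfer threshold sits below any plausible
activity dwell and is configurable.

Each leg carries `linear_m` (geodesic endpoints) and `path_m` (summed
geodesic along fixes); `path_m ≥ linear_m − 25 m`, the slack absorbing GPS
noise on short legs.

## Node, trip, and complexity metrics

Counts and durations support five time segments: all, day ([06:00, 22:00)),
night (complement), weekday, weekend. Stops are clipped to segment windows
(so day + night durations exactly equal the total); a visit counts in a
segment if it intersects it; a trip belongs to the segment of its start
time, preventing double counting across the day/night boundary. Home stays
are excluded from activity-node metrics by default (home dwell would swamp
every duration-weighted quantity); a flag includes them.

**Diversity** is the number of distinct non-home types visited (≤ 13 with
home excluded). **Normalized entropy** of a weight vector is
H = −Σ pᵢ ln pᵢ over positive weights, divided by ln K with K fixed at the
taxonomy size (14) so values are comparable across participants regardless
of observed support.

**Complexity** operationalizes cross-period variability of the node-type
(or transport-mode) mix: the mean pairwise Jensen–Shannon divergence
between per-day distributions, in nats, divided by ln 2. It is symmetric,
permutation-invariant, 0 iff all days share one distribution, and 1 when
days have disjoint support. Both visit-count and dwell-duration weightings
are exposed, since variability can live in frequency, type, or time spent.

## Extent geometry

All planar work runs in a **local equirectangular projection** centred on
the input points (longitude scaled by cos of the centroid latitude). At a
30-km city scale near the equator this agrees with a Lambert azimuthal
equal-area projection within 0.5 % on hull areas (asserted in the test
suite), and it keeps the geometry stack to shapely + numpy. Great-circle
distances use the haversine formula with R = 6 371 000 m.

* Convex hull via shapely; **concave hull** as a Delaunay alpha-shape
  keeping triangles with circumradius ≤ 500 m (a metric alpha, so the
  parameter has units a practitioner can reason about). Fewer than 3
  non-collinear points yield area 0 with a degenerate flag, never an
  exception.
* **Standard deviational ellipse**: population (divide-by-total-weight)
  covariance of projected points, optionally dwell-weighted; σ₁, σ₂ are
  eigenvalue square roots, θ the major-axis bearing, area π σ₁ σ₂.
* **Daily path area**: union of leg polylines buffered by 100 m
  (quad_segs = 64, keeping the end-cap area error ≪ 0.1 %); overlap is not
  double-counted. The 100-m buffer is a reporting convention, configurable
  and always reported alongside the area.
* **Radius of gyration**: RMS geodesic distance from the (optionally
  dwell-weighted) centroid.

Hull/ellipse input defaults to stay-node centroids rather than raw fixes
(the raw-fix variant is available by passing fix coordinates); both are
legitimate definitions and the choice is reported with the result.

## Home and vertical life space

The GPS home node (GPN) is inferred from the stay node occupied at 03:00
local on each observed night; nights cluster by 100-m proximity and the
plurality cluster wins (ties broken by total overnight dwell and flagged).
Fewer than 7 observed nights leaves the GPN unresolved. Reconciliation
against the geocoded self-declared address (SDN) keeps the SDN as the home
point in all cases — matching the field practice in which nearly all final
home points are declared addresses — and raises a review flag when the
deviation exceeds 100 m, the machine analogue of manual map inspection.

Vertical trips use the linear sea-level pressure-height coefficient
8.43 m/hPa instead of the full hypsometric formula: at residential tower
heights (≤ ~70 floors) the linearization error is under 1 %, far below the
3-m floor quantization. A maximal single-sign run of pressure intervals
with |ΔP| ≥ 0.1 hPa per 10 s becomes an event when the nearest-in-time fix
places the phone within 30 m of home; floors = round(−ΔP·8.43 / 3.0).
Slow weather drift falls below the rate gate; detection is restricted to
the home location by default because elsewhere the building context needed
for validation is absent. An empty pressure channel returns a
capability-flagged empty result rather than an error, since only a
minority of handsets carry barometers.

## Meso-environment and PTAL

Amenity layers are GeoJSON point collections; nearest-amenity distance and
1-km buffer counts use geodesic (not network) distance, matching the
linear-distance convention of the reported home-environment metrics. The
PTAL follows the London-methodology arithmetic: walk time at 80 m/min to
each stop within 640 m (bus) / 960 m (rail); average wait = half headway
plus a reliability penalty (2.0 / 0.75 min); equivalent doorstep frequency
EDF = 30/(walk + AWT); per-mode index = best EDF + 0.5 × the rest; total
index banded to levels 1–6 at edges (2.5, 5, 10, 15, 20). Every constant
is config-exposed because local recalibrations of the method adjust
exactly these values.

## Instruments

The composite life-space score is Σ over attained levels of
level × independence × frequency with the standard weights (personal
assistance 1, equipment only 1.5, independent 2; frequency 1–4), maximum
120, restricted below 60. Frailty screens count 5 items: 0 robust, 1–2
prefrail, 3–5 frail. IPAQ-SF MET-minutes/week multiply 8.0 / 4.0 / 3.3 by
minutes/day and days/week per intensity, with sitting time reported
separately. The social-network scale totals 12 items (0–5) with an
isolation flag strictly below 20; the 15-item depression screen scores
keyed yes/no answers (bands: 5–9 suggestive, ≥ 10 indicative; the positive
item keying is a config table defaulting to the standard instrument); the
3-item loneliness scale totals 0–12. EQ-5D-5L support is profile-string
construction only — index values require a national value set, an external
artifact.

Correlation power uses the Fisher-z normal approximation,
power = Φ(|atanh r|·√(n−3) − z₁₋α/₂); solving for n inverts the formula,
rounds up, and then adjusts to the smallest integer meeting the target.
At r = 0.1, α = 0.05, n = 783 this gives 80.0 % power, and the minimal-n
solver returns 783.

## Synthetic cohort generator

The generator emulates the *structure* of a smartphone travel-diary study:
each day anchors at home across 03:00; activity visits are Poisson-drawn
per type from a small abstract city (near amenities 0.3–1.5 km, far ones
3–5 km); destinations under 2 km from home are walked at 4.8 km/h, farther
ones become three-leg walk–bus–walk journeys (bus 30 km/h) with 180-s
transfer stops at fixed bus-stop locations; activity dwells are uniform in
30–120 min. Fixes are sampled every 30 s with isotropic Gaussian noise
(σ = 10 m) and indoor stay samples dropped with probability 0.1; the
barometer renders a 1013-hPa baseline, a ±0.3 hPa diurnal drift, and
elevator ramps at ~1.5 m/s on every home entry/exit for participants with
a nonzero floor. Cohort strata follow the quota ratios 40:60 (age
bracket), 20:80 (private:public housing), 30:70 (prefrail-frail:robust),
matched exactly by largest-remainder allocation whenever n divides the
ratio. All randomness flows from one scenario seed.

Ground-truth metric values are computed directly from the schedule — an
independent path from the detection pipeline — so recovery tests are true
oracle comparisons, not self-comparisons. What the generator does **not**
model: urban-canyon multipath (heavier-than-Gaussian noise), tunnel and
basement outages, battery-driven sampling gaps, route curvature, bus
dwell-at-stop dynamics, and behavioral realism of activity choice. Passing
recovery tests therefore demonstrates correctness of the measurement
chain under idealized-but-noisy conditions, not field accuracy on real
streams, where the diary-validation overlay carries more weight.

## Problem sizes and determinism in the test suite

The suite runs single-threaded in well under a minute: oracle-equivalence
streams are ≤ 200 fixes (the brute-force enclosing-circle check is cubic);
stop recall/precision uses 20 seeds × 2-day diaries; end-to-end recovery
uses full 14-day diaries on a handful of seeds. Recall ≥ 0.95 and
precision ≥ 0.90 are evaluated without the signature overlay (the harder
condition); recovery of trip/leg/stop counts is exact with signatures
available, as in the validated-diary setting. Hypothesis-based property
tests are bounded to ≤ 50 examples each and all randomness is seeded.

## Known limitations

* Mode inference is a speed-threshold surrogate; it cannot separate bus
  from car, and walk/bicycle confusion is possible near 7 km/h. The design
  assumes a diary-validation overlay as the correction channel.
* Within-leg mode changes without an intervening detected stop are not
  split (no accelerometer fusion).
* Stops shorter than the 60-s minimum dwell are invisible by construction;
  drop-off/pick-up events below a minute are therefore not counted.
* The equirectangular projection is not suitable far from the configured
  origin or at high latitudes; the implementation asserts city-scale use.
* PTAL constants default to the London calibration; local adaptations
  should override the config rather than reinterpret the output.
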