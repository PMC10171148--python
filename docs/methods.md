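# Methods

This note documents the models, defaults and design choices behind
`crowdcontact`: what the pipeline computes, what the synthetic generator
does and does not emulate, and where the genuinely open decisions were
settled.

## Pipeline model

**Records.** The atom is one observation of one anonymized user:
(user id, UTC timestamp, WGS84 lat/lon, accuracy in meters, OS). Records
appear in daily files keyed by *arrival* date, which may trail the
record's own local date.

**Cleaning.** Coordinates that are non-finite or physically impossible
are dropped with a warning; points outside the study rectangle are
dropped and counted. Local dates come from fixed per-CBG UTC offsets
(minutes); daylight-saving transitions are not modeled. A record with
local date d is kept iff it arrives in the file for d or d+1 — the feed's
own behavior is that ~99.5% of records arrive within that window — and
later arrivals are dropped and counted. Ingestion conserves records
exactly: input = kept + invalid + out-of-bounds + late + unassigned.

**Partitioning.** Records are bucketed per (county, CBG) by
point-in-rectangle tests; a point on a shared edge goes to the
lexicographically smallest CBG id (a deterministic tie-break). Clustering
runs per (CBG, local date) partition; as a known edge effect, crowds
straddling a CBG border or local midnight are split.

**Clustering.** Points are records projected to planar meters
(equirectangular about the CBG rectangle center; exact inverse, error
far below record accuracy at CBG scale) with time in minutes. The
ε-neighborhood is the *conjunction* of a spatial disc (≤ 15 m) and a time
window (≤ 20 min), boundaries inclusive — not a single ball on scaled
axes; a scaled-Euclidean variant is available behind
`ClusterParams(metric="scaled_euclidean")` for sensitivity work. A point
is core iff at least M = 10 *other* points lie in its neighborhood; note
the common DBSCAN convention counts the point itself, this one does not,
so the smallest cluster has M+1 coincident points. Clusters are connected
components of the core graph; each non-core point joins the cluster of
its nearest core neighbor (nearness in the scaled max-norm, ties to the
smallest cluster id) or is noise. Cluster ids are canonical: components
ordered by their minimal member under (t, x, y) lexicographic order.

The production implementation is a time-sorted sweep with union-find,
compiled with numba; an exhaustive O(n²) oracle (pairwise matrices +
`scipy.sparse.csgraph.connected_components`) implements the same
semantics independently and must agree exactly on every test instance
(it refuses n > 5000).

**Weighting.** Weekend nights are the Fri→Sat and Sat→Sun nights:
[23:00, 24:00) of Friday/Saturday and [00:00, 09:00) of Saturday/Sunday,
local time (the window is config-overridable). Per month, a user's home
CBG is the modal CBG of their weekend-night records; ties break by total
record count across all hours, then by smaller CBG id. Users with no
weekend-night records that month get no weight; where a later stage needs
one, they take the scope median (dropping them would bias crowd sizes
down). The raw weight pop(g)/users(g) conserves population exactly per
CBG. Winsorization clamps to the 5th/95th percentiles (linear
interpolation) over all assigned users of the processed region-month —
the percentile scope is a package decision, since the index is defined
over whatever region is being processed.

**Contact index.** Per cluster: N = Σ winsorized weights over unique
users; A = axis-aligned bounding-box area (projected m²); T = duration
(reported but not part of S); N_C = max(1, ceil(A/(πC²))) with C = 15 m —
the floor at 1 covers coincident-point clusters where the plain ceiling
would give 0 and leave persons-per-circle undefined; T_u =
records/(users·rate) in minutes, with the rate the CBG-date's records per
user per minute averaged over hours weighted by hourly record counts;
N_P = ceil(N/N_C); S = N·T_u·(N_P−1), and clusters with S ≤ 0 are
dropped. In the uniform large-crowd limit the ceilings vanish and
S → N·T_u·(NπC²/A − 1); the suite asserts 5% agreement at N = 10⁴. The
printed formula counts each contact from both sides; no pair
de-duplication is applied, matching the source convention. T_u is not
capped at T; T_u > T occurs for single-burst clusters and is logged, not
clipped. SCI = 10⁶ · S / (reference-date total S); the reference date is
configurable (default: the run's first date) because the historical
normalization total is a property of the unavailable vendor feed.

**Aggregation.** Cluster-to-POI attribution uses the exact area of
bbox ∩ disc via signed corner decomposition into rectangle + circular-
segment terms (a quasi-Monte-Carlo sampling oracle cross-checks it to
1e-3 in tests). A zero-area bbox counts as wholly inside a disc iff its
midpoint is. POIs are discs of a per-type standard radius. Overlapping
POIs of different types each receive their own fraction (possible double
counting; the attribution is deliberately per-POI with no
de-duplication). Per (date, ZCTA, POI type): SCI is the fraction-weighted
sum; sizes are √(overlap area) per contributing cluster-POI pair with
sample variance (n−1, configurable); `Avergage_Time` — the published
header misspelling is reproduced verbatim — is the unweighted mean T_u
over contributing clusters. Size distributions can be fitted by MLE
(`scipy.stats`, location pinned at 0) for the F, chi-square, Weibull,
lognormal, gamma and power-lognormal families, ranked by the KS
statistic; constant samples are refused.

## Synthetic world and feed

The generator emulates the *statistical structure* of a commercial LBS
feed on a small, exactly-testable stage:

- Geography: a grid of axis-aligned CBG rectangles (default 6×6 cells of
  ~1.1 km, one county per row, 2×2-cell ZCTAs) instead of real census
  shapes — point-in-region tests are exact and need no shapefiles.
  Populations are uniform on [500, 2000]. One POI disc per CBG from a
  five-type catalogue (radii 20–60 m), rejection-placed with ≥ 200 m
  pairwise separation and ≥ 200 m clearance from CBG centroids so that
  planted gatherings never abut the home point-mass.
- Users: homes at the CBG centroid (emulating vendor obfuscation of
  residential coordinates), sampled ∝ population so each real person is
  equally likely to be in the panel.
- Records: per reporting user per day, a Poisson count with mean 120
  (one per ~12 min); times from an hourly profile with night hours
  (23:00–09:00) at half rate — the within-day distribution is not
  documented for the real feed, so thinned-Poisson with diurnal
  modulation is an assumption, flagged as such. Night records sit at the
  home centroid with 10 m Gaussian jitter (GPS-scale noise); gathering
  participants sit at N(POI center, spread) during the plan window;
  everything else scatters uniformly over the home CBG. Accuracy ~
  N(10 m, 2 m), one OS label per user.
- Panel churn: each user reports on a given day with a probability from a
  daily-activity profile. The default profile emulates a study month with
  a mid-period intervention — two near-full weeks (0.95), a week-long
  decline, a suppressed plateau (0.55), plus a ±0.04 weekly ripple. This
  matters: the contact index is deliberately invariant to the sampling
  *rate* (doubling cadence doubles records and the rate estimate,
  leaving T_u and S fixed), so day-to-day variation in the index can only
  come from behavioral variation — who is present and who gathers. With
  an identical-days panel the daily series is quasi-constant and any
  correlation across parameter settings measures only ceiling-
  quantization noise of the dominant home-centroid clusters; with churn,
  all parameter settings track the same large common signal, which is the
  regime the sensitivity analysis describes. Cadence is defined per
  *reporting* user and is unaffected.
- Defects: a configurable fraction of records (default 0.5%) arrives a
  day late (with an optional geometric tail beyond one day), and a small
  fraction (default 0.1%) carries out-of-bounds coordinates; planted
  defect row indices are returned for tests.

Not emulated: road networks or realistic movement between POIs,
demographic attributes, multiple vendors, daylight saving, accuracy-
circle clipping at region borders (records are dropped on the point test
only). Passing tests therefore demonstrate correctness of the *pipeline
arithmetic and recovery behavior* under a plausible feed, not fidelity to
any particular real panel.

## Reference studies and problem sizes

- *Sensitivity grid*: 2000 users, 30 days, ~8 gatherings/day (12–24
  participants, 40–90 min, 3–7 m spread) on the default world; the full
  pipeline runs at ε ∈ {10, 15, 20, 25} m (clustering reused across C
  values) and the daily-total SCI series are correlated against the
  (15, 15) baseline. About 7M records; minutes on one CPU.
- *Gathering recovery*: 50 gatherings (10/day × 5 days, 14–22
  participants, ≤ 7 m spread, ≥ 40 min) on a sparser 6×6 world of ~3.3 km
  cells with a full (churn-free) panel of 2000 users. The sparser stage
  is deliberate: the study compares each recovered cluster's N against
  the *planted participants only*, so the uniform background must be thin
  enough that passersby — who legitimately join a crowd and are counted
  by the estimator — rarely touch the isolated gatherings, while ~55
  users/CBG keep the persons-per-user weights stable. Recovery asserts
  exactly one cluster per gathering and N within 15% of
  participants × (population / panel size).
- *Cadence*: 1000 users, one day; mean records per reporting user.

## Numerical notes

- Percentiles: `numpy.percentile` linear interpolation; deterministic.
- Population conservation is an exact identity in real arithmetic;
  floating-point summation of k copies of pop/k is asserted at 1e-9
  relative.
- Equirectangular projection constants: R = 6371008.8 m; one degree of
  latitude ≈ 111.195 km; verified against a haversine oracle to 0.1%.
- The two DBSCAN implementations use identical floating-point expressions
  for distances and tie-break keys, so their label arrays match exactly,
  not merely as partitions.
- All randomness flows from `numpy.random.default_rng` on a single run
  seed; derived stage seeds are drawn once from that seed and recorded in
  the run manifest, which suffices to replay a run byte-for-byte.

## Known limitations

- Residential (home-centroid) clusters dominate absolute SCI levels, as
  they must when homes are obfuscated to a shared point; the index is
  therefore most meaningful as a *relative, temporal* measure and in its
  per-POI rollups, which exclude the home point-mass by geometry.
- Clusters cannot span CBG borders or midnight (partitioning artifact).
- A cluster overlapping POIs of different types is counted toward each
  (no de-duplication), and POIs are discs, not footprints.
- With few users per CBG the persons-per-user weights are noisy;
  winsorization bounds but does not remove this.
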