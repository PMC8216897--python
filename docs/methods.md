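# Methods

This note records the model, the parameter defaults and the numerical and
design choices behind `ehacube`, in the order the pipeline runs.

## Input model

The raw input is a single-band integer raster of *first* loss years: 0
means the pixel was never seen lost, v ∈ 1..T means first loss in year
2000+v (T = 18 by default, years 2001–2018). A pixel is lost at most once;
there is no regrowth. All geometry is Euclidean on a local metric grid
(square pixels, metres); the package performs no geodesy and no
reprojection, so inputs must already share one planar CRS. Rasters travel
as GeoTIFFs (ModelPixelScale/ModelTiepoint tags plus the GDAL nodata
convention), vectors as GeoJSON.

## Space–time cube

Pixels aggregate into square bins of `bin_size` metres (default 5,000 m —
half the neighborhood radius; the method itself fixes only the 10 km
neighborhood, not the cube's bin size, so the bin size is an explicit,
configurable modelling choice). `counts[r, c, t]` is the number of pixels
in bin (r, c) first lost in year t. Partial bins at the right/bottom edges
keep their true pixel counts.

**Analysis mask.** By default only locations with at least one loss event
over all T years enter the statistics (`mask_mode="any-loss"`), mirroring
how cubes built from event points behave: locations that never saw an
event do not exist in the cube. The alternative `"all"` keeps every
location with valid pixels. The mask determines n, the number of
space–time bins used in the global standardisation, and which bins can be
neighbors.

**Annual series.** Per-year loss area is count × pixel area, in km². Mean
annual rates are truncated toward zero to whole km² by default; this
reproduces headline island-scale rates computed from 18-year totals
(67,104/18 = 3,728 exactly; 88,504/18 = 4,916.9 → 4,916).

## Getis-Ord Gi*

For masked bin i,

    z_i = (Σ_j w_ij x_j − X̄ W_i) / (S √((n W_i − W_i²)/(n−1)))

with binary weights w_ij ∈ {0,1} (the focal bin included), W_i = Σ w_ij,
and X̄ and S = √(Σx²/n − X̄²) the mean and population SD over **all n
masked space–time bins of the cube** (global standardisation). The
per-time-slice alternative is deliberately not used: the statistic asks
whether a bin-plus-neighborhood sum is large against the cube-wide
background, which is what makes year-to-year z-series comparable for the
trend test. p-values are two-sided normal; hot means z above the two-sided
critical value (1.96 at α = 0.05), cold below its negative. A constant
cube (S = 0) yields z = 0 everywhere. Degenerate inputs: fewer than two
masked locations are rejected.

**Neighborhood.** Spatial: all masked bins whose centroid lies within
`neighborhood_distance` (default 10,000 m) — binary contiguity-by-
distance, no kernel decay, which is the plainest reading of "neighborhood
distance = 10 km". On a 5 km bin grid this is the 13-cell disc of offsets
with hypot ≤ 2. Temporal: `neighborhood_time_steps` τ (default 1).
The default window is **backward** — the current step plus the τ previous
steps, clipped (not wrapped) at the series start. Backward windows are the
convention of emerging-hotspot tooling and are load-bearing for the
category semantics: with a symmetric window a hotspot that exists only in
the final year leaks significance into year T−1 and can never classify as
"new" ("never a hotspot before"). A symmetric |t−t′| ≤ τ window remains
available (`time_window="symmetric"`).

The fast path computes neighbor sums by 2-D convolution per time slice; a
brute-force neighbor-enumeration oracle in the test suite checks it bin by
bin to 1e-9 on random cubes.

## Mann–Kendall trend

S = Σ_{i<j} sgn(x_j − x_i); Var(S) = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18
over tie groups g; z uses the ±1 continuity correction; p two-sided
normal. Series shorter than 4 are rejected (the normal approximation is
unreliable). A direction (increasing/decreasing) is reported only when
p < α.

**What is the trend taken over?** A single bin is one time point, so "the
trend in each bin" can only mean a per-*location* series. The default
tests the location's Gi* z-score series — the intensity of clustering,
which is the quantity the intensifying/diminishing category definitions
speak of. Testing the raw count series instead is available as
`trend_on="counts"`. The choice is a genuine ambiguity in the method
description; both modes are first-class.

## Eight-category classification

Rules are evaluated in a fixed precedence order (first match wins), with
`min_hot_steps = floor(hot_fraction · T)` (0.90 · 18 → 16 — the floor
reproduces the "16 of 18 years" operationalisation even though 16/18 is
88.9%, i.e. the published "more than ninety percent" wording and the
printed 16 cannot both hold; the printed count wins):

1. **new** — final step hot, exactly one hot step ever;
2. **consecutive** — uninterrupted terminal hot run ≥ 2, nothing before
   it, fewer than `min_hot_steps` hot steps;
3. **intensifying** — final hot, ≥ `min_hot_steps` hot, significant
   increasing intensity;
4. **diminishing** — final hot, ≥ `min_hot_steps` hot, significant
   decreasing intensity;
5. **persistent** — final hot, ≥ `min_hot_steps` hot, no significant
   trend;
6. **oscillating** — final hot with ≥ 1 cold step, < `min_hot_steps` hot;
7. **sporadic** — final hot, never cold, < `min_hot_steps` hot;
8. **historical** — final step *not* hot, ≥ `min_hot_steps` hot;
9. none.

Design choices where the published row definitions under-determine the
rules:

- *persistent requires a final-step hot.* Without it, any ≥ 16/18-hot
  location with a cool final step and no trend would classify persistent
  and the historical category ("most recent time period is not hot") would
  be unreachable; the final-step condition is what separates the two rows.
- *new demands exactly one hot step*; a terminal run of ≥ 2 with no prior
  history is consecutive — this separates the two rows' "never … before"
  clauses.
- *sporadic requires a final-step hot* (the row text omits it, but without
  it sporadic swallows historical-like sequences).
- The "less than ninety percent of all bins" clause in the consecutive row
  is read as the location's own steps, not the whole cube.
- Cold-spot mirror categories are not emitted — only hotspot patterns are
  of interest here; cold labels matter solely inside the oscillating rule.

Classification is vectorised over locations; a scalar rule-walk
implementation exists alongside and the tests check the two agree.

## Synthetic data generator

The generator emulates the pipeline's real inputs on a local metric grid:
per-pixel annual first-loss with spatially clustered, temporally patterned
elevation of loss probability (planted patches, one category template
each); smooth Gaussian-bump elevation with Horn slope downstream; a human
footprint index decaying exponentially from straight "roads" (clipped to
the 0–50 index range); Poisson plantation point sets; rectangular or disc
protected areas with IUCN labels from the nine standard values.

**Hazard semantics.** In `"rate"` mode a patch amplitude adds directly to
the Bernoulli hazard of still-standing pixels. Because pixels are lost at
most once, a constant elevated rate depletes the patch: counts decay
geometrically, so a "persistent" rate produces a *diminishing* count
profile. In `"mass"` mode (used by the planted-truth scenario) the
amplitude is the expected per-pixel loss mass per year, and the generator
divides by the deterministic expected survival to form the conditional
hazard, so expected counts track the template shape despite depletion. A
cumulative mass approaching 1 drives the hazard above 1 and is rejected.

**Templates.** Each of the nine templates (the eight hotspot patterns plus
a pure cold patch) is a deterministic per-year intensity vector plus
suppression flags. Suppressed years force the within-patch rate to zero —
*below* the surrounding background — because Gi* cold bins require
below-average neighborhoods, not merely quiet ones. Two template-level
choices compensate for the τ = 1 temporal smoothing of the detector:
oscillating alternates blocks of 2 on / 3 suppressed years (a single
suppressed year can never yield a cold bin, since every window would touch
an on-year), and the ramps of intensifying/diminishing run 0.3→1 and
1→0.3 rather than touching zero, so the patch stays detectably hot in
every year while its intensity trends. The historical template is on for
the first T−2 years: the smoothing makes year T−1 hot as well (17 hot
steps) while the final step stays cool.

**The standard recovery scenario** plants one 5×5-bin patch per hotspot
template, well separated on a 160×160-bin grid (3,200×3,200 pixels of
250 m; 400 pixels per 5 km bin), background rate 0.0025 per pixel-year,
amplitude 0.05 in mass mode (an expected 20 extra lost pixels per bin and
fully-on year against a background expectation of 1). The sizing is
deliberate on three axes: patch bin-years are ~0.5% of the cube, so the
global X̄/S stay anchored to the background process; 400 pixels per bin
make planted contrasts large against Bernoulli noise; and the planted
signal variance inflates S enough that *background* bins essentially never
cross ±1.96 by chance — which is what makes the count-sensitive categories
recoverable (new tolerates no prior hot step; sporadic tolerates no cold
step; at the Gi* null rate of ~2.5% per bin-year such chance crossings
would otherwise be near-certain somewhere in an 18-year history). Smaller
casual scenarios are fine for every other purpose; unit tests use grids
down to a few hundred pixels.

**What the generator does not emulate:** cloud/shadow artifacts, sensor
reflectance, a tree-cover baseline, regrowth, spatially correlated
background noise, or real road-network topology. Passing recovery tests
therefore demonstrate the detector's correctness on its own model of the
world — clean first-loss processes with piecewise-deterministic hazards —
not its robustness to sensor noise or to drivers that violate the model.

## Protected-area overlay

A location belongs to a PA iff its bin centroid falls inside the polygon —
no fractional-area weighting, because categories live on the cube's
location grid and sub-bin splitting would invent information; this
quantizes shares by one bin at PA edges and is the known limitation of the
overlay. Overlapping PAs resolve to the first listed. Per-PA shares are
percentages over the PA's masked locations (undefined — NaN, not 0 — for a
PA covering none); island-level tables count category locations inside vs
outside any PA. Boundary profiles bin signed centroid-to-boundary
distances (negative inside) into rings of `ring_width` metres.

## Driver attribution

The sampling unit is one analysis location. Covariates: elevation and
Horn-slope (3×3 finite differences, edge-replicated windows, degrees),
block-averaged from pixel to bin resolution; human footprint likewise; and
Euclidean distances from bin centroids to the nearest plantation feature
(exact shapely distances rather than a grid transform, so points, lines
and polygons all work; an empty feature set is rejected since the distance
is undefined).

Kruskal–Wallis runs per covariate across category groups with the
tie-corrected H and a χ²(k−1) p-value; an all-identical pooled sample
returns H = 0, p = 1.

CART is authored here (greedy exhaustive search over covariates ×
midpoint thresholds, Gini by default, cross-entropy available; ties in
impurity break toward the lowest covariate index then lowest threshold;
descent rule "left iff value < threshold", ties at the threshold go
right). Defaults max_depth = 4 and min_leaf = 5% of samples keep trees at
the shallow, readable scale the method calls for. scikit-learn's
implementation is used in the test suite as an independent cross-check
only. Leaves carry class distributions and the percentage of the data
reaching them; leaf percentages sum to 100.

## Determinism and problem sizes

Every stochastic step consumes a `numpy.random.default_rng` seeded from
the scenario or run config; identical config + seed reproduces rasters
byte-for-byte and the run report verbatim. The shipped test suite and the
acceptance script use the standard recovery scenario (160×160 bins × 18
steps, ~25,600 masked locations), a 10,000-replicate Mann–Kendall
calibration, and 100 random 6×6×4 cubes for the Gi* oracle — sizes chosen
so brute-force oracles remain exact and the full suite runs in well under
a minute of CPU apart from the simulations.

## Known limitations

- No multiple-testing correction across bins (the classical workflow
  applies none); the per-bin α is nominal.
- Normal approximations throughout; no Monte-Carlo p-values.
- The Gi* background (X̄, S) is cube-global by default; per-slice
  standardisation is not implemented.
- Centroid-membership overlay quantizes PA shares at bin resolution.
- The synthetic generator's background is spatially iid; real loss
  processes are autocorrelated, which would widen the null z distribution
  and inflate chance categories relative to what the tests show.
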