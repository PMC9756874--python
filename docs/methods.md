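# Methods

`rewildscape` re-implements, as a tested pipeline, the analysis chain used
to evaluate reintroduced wild-ungulate populations as a landscape-management
tool: camera-trap density estimation, habitat-suitability thresholding,
land-cover succession classification, grazer-density association statistics,
and a stochastic population projection.  This note documents the models, the
defaults and the numerical choices, and what the synthetic-data tests do and
do not demonstrate.

## Random encounter model

Density is estimated from unmarked camera-trap detections with the random
encounter model (REM), which treats animals as ideal-gas particles crossing
a sector-shaped detection zone:

    D = (y / t) · π / (v · r · (2 + θ))

with `y` independent capture events, `t` trap-days, `v` daily movement
(km/day), `r` detection radius (stored in metres, converted to km inside the
formula) and `θ` detection angle (rad).  The trapping rate enters the
formula as events per trap-day; a "×100" rescaling sometimes seen in field
reports is a presentation convention and is never applied inside the
estimator (doing so would inflate densities one-hundred-fold).

Movement speeds are taken from the literature catalogue bundled in
`rem.SPEED_KM_PER_DAY`: roe deer 1.99, red deer 2.88, cattle 4, sheep 6,
horses 7.2 km/day.  Camera geometry defaults to r = 20 m (12 m for the
Uovision UV575 model) with per-model angles between 0.77 and 2.09 rad.

*Independence filter.*  Within each (camera, species) stream, a detection is
kept iff it is ≥ 10 minutes after the last **kept** detection.  Measuring
from the last kept record (rather than the previous raw record) makes the
thinning idempotent; the boundary case of exactly 10 minutes counts as
independent.  A record's group-size `count` is metadata: each independent
record contributes one event to `y`.

*Survey design.*  The extent is tiled into 10 × 10 km quadrats; quadrats
intersecting suitable habitat are eligible, one 2 × 2 km cell is drawn per
selected quadrat, and four cameras sit at the cell corners inset by half a
grid cell.  When camera models are mixed within a quadrat, `r` and `θ` are
averaged unweighted.

*Uncertainty.*  The per-cell SE is a nonparametric bootstrap over cameras
(default B = 1000; the pipeline uses B = 200 to keep runs short): cameras
are resampled with replacement together with their events and effort, and
the SE is the SD of the resampled REM estimates.  A single-camera cell has
no resampling variance and reports SE = 0 with a warning.

## Habitat suitability

The species distribution model itself is an external input; the package
consumes any continuous suitability raster in [0, 1].  Predictor
preparation provides Euclidean-distance rasters (cell centre to nearest
feature, via an STR-tree) and a Pearson collinearity screen.  The screen's
drop rule — repeatedly remove, from the worst offending pair above the
|r| threshold (default 0.7), the variable with the larger mean |r| against
the retained set, name order breaking ties — is made explicit so the
procedure is deterministic.

Two presence-based thresholds discretise the suitability surface:

* **p10** — the 10th percentile of presence scores, computed with linear
  interpolation between order statistics (the variant must be pinned for
  reproducibility);
* **maxSSS** — the candidate threshold (union of unique presence and
  background scores) maximising sensitivity + specificity, ties resolved to
  the lowest threshold.

Cells ≥ maxSSS are *high* suitability, cells in [p10, maxSSS) *medium*, the
rest unsuitable.  Medium + high is the total suitable area and serves as
the clipping mask downstream; p10, the more inclusive threshold, defines
"suitable" wherever a single cut is needed.

## Land-cover change

Two CLC level-III epochs are overlaid (geometric intersection for vector
layers; cell-wise comparison with connected-component grouping for
rasters).  Polygons smaller than 0.25 ha are removed as misalignment
slivers (strictly smaller; 0.25 ha exactly is kept).  Succession ranks
within class 3: bare/open (331–335) = 0, grassland (321) = 1,
shrub/transitional (322–324) = 2, forest (311–313) = 3.  A class-3 →
class-3 transition to a higher rank is Spontaneous Succession (forest
encroachment), to a lower rank Inverse Succession (landscape opening);
within-rank moves and any transition touching class 1/2/4/5 are unlabelled.
Transitional woodland-shrub (324) is grouped with shrub because no finer
ordering is defensible.  Classified changes are rasterized at 100 m by the
cell-centre rule (boundary centres count as covered), so reported areas are
always cell count × (resolution/1000)².

## Association statistics

* **IDW.**  Cell value = Σ w_i z_i / Σ w_i with w_i = d_i^−power
  (default power 2, all samples, no neighbour cutoff); a cell coincident
  with a sample takes its value exactly; output clipped to the suitability
  mask.  IDW output is bounded by the sample range by construction.
* **Cumulative grazer density** is the cell-wise sum of the species
  surfaces, nodata counting as zero wherever any layer is valid.
* **GLM.**  Density ~ distance-from-release, gamma or inverse-Gaussian
  family with canonical links (inverse, 1/μ²).  Under a canonical inverse
  link a *positive* slope means density *decreases* with distance, which is
  why opposite-signed slopes across species can describe the same decaying
  pattern.  Zeros (outside both families' support) are shifted by half the
  smallest positive value (logged).  Pseudo-R² = 1 − D_res/D_null
  (deviance-based, family-generic).
* **Welch's t** (Satterthwaite df, two-sided) compares grazing density
  between succession classes with unequal pixel counts; degenerate
  zero-variance inputs return t = 0, p = 1 rather than NaN.
* **χ²** on the 2 × 2 table of SS/IS pixels inside/outside suitable
  habitat: Pearson statistic without Yates correction (counts are in the
  thousands), df = 1, algebraically equal to N(ad−bc)²/Π(marginals).
* **Elevation control.**  SS vs IS elevations compared only over cells
  outside the deer-suitable mask; a null result argues against elevation
  as the driver of the succession contrast.

## Population projection

The PVA is a two-sex individual-based annual cycle —
breeding → survival → aging → ceiling truncation at K — with a birth-pulse
pre-breeding census.  Breeding females are a binomial draw among adult
females (age ≥ `first_breeding_age`), suppressed only when no adult male is
alive (polygyny); litter sizes follow a configurable distribution; sex at
birth is Bernoulli.  Newborns are age 0, survive the age-0 class rate, and
first appear in the census at age 1.  The terminal age class is open-ended
(individuals stay in it at its survival rate).  Density dependence is a
ceiling only: individuals beyond K are removed at random.  An iteration is
extinct — permanently, N = 0 — from the first census at which either sex
has no individuals (the two-sex extinction threshold).  Default 100
iterations; per-iteration seeds spawn from one root seed.

`deterministic_lambda` builds the female Leslie matrix under exactly this
census convention (fecundity row b·E[litter]·(1−sex ratio)·s₀ for breeding
ages; sub-diagonal survivals; terminal self-loop) and returns its dominant
eigenvalue.  Because conventions match, the stochastic mean growth can be
checked against log λ — the suite verifies agreement within 2% at 1000
iterations starting from the stable age distribution.

The example configuration in `examples/roe_deer_pva.yaml` is synthetic:
literature-plausible rates for a mid-size temperate cervid, shipped because
published projections of this kind rarely deposit their parameter files.
It is not calibrated to any specific published output.

## Synthetic study system

The generator produces what the estimators assume, nothing more:

* **Mosaic land cover** — multi-seed region growing (nearest-seed
  allocation, the uniform-growth-rate limit) over the CLC code table, with
  an Apennine-like mixture of forest, shrub, grassland and agricultural
  patches.
* **Density surfaces** — exponential distance-decay from a single release
  point, masked to suitable habitat and rescaled to integrate exactly to
  the planted abundance (checked to 0.1%).
* **Detections** — per-camera Poisson counts with mean
  t·D·v·r·(2+θ)/π, the exact inverse of the REM formula; timestamps
  uniform then pushed apart beyond the 10-minute window so the
  independence filter is a no-op on clean streams, with optional sub-window
  "bursts" to exercise the filter.
* **Epoch-2 land cover** — class-3 cells advance one succession rank with
  probability expit(a₀ − a₁·grazer density) and revert with probability
  expit(b₀ + b₁·grazer density), planting the grazing-suppresses-
  encroachment effect the statistics should recover.

Deliberately absent: animal movement (detections are generated from the
camera's local cell density, not from trajectories), activity cycles and
detection heterogeneity, camera failures, spatial autocorrelation beyond
the planted gradient, and observation error in land-cover maps.  Passing
tests therefore demonstrate the *estimators and statistics are correct
under their own assumptions*, not that those assumptions hold in any field
system.

## Problem sizes and determinism

The default end-to-end run uses a 20 × 20 km landscape at 100 m resolution
(200 × 200 cells), 4 quadrats × 4 cameras, 100 trap-days, bootstrap
B = 200, and 100 PVA iterations — sizes chosen so a full run completes in
seconds while leaving every stage statistically identifiable.  Estimator
calibration checks use larger effort (e.g. 700 trap-days × 4 cameras for
the REM bias check, ≈ 1000 expected events per survey).  All stages draw
from substreams spawned from one root seed (`numpy.random.SeedSequence`);
identical configuration and seed reproduce results bit for bit.

Geospatial I/O is plain text by design: ESRI ASCII grids for rasters,
GeoJSON for vectors, CSV for tables, YAML for configs and reports — all
readable by standard GIS software without binary dependencies.

## Known limitations

* The REM variance is bootstrap-only; no analytic variance or activity
  correction is provided.
* Raster-derived change polygons are unions of cell boxes, so their
  boundaries are blocky at the source resolution.
* The GLM does not correct for spatial autocorrelation of pixels (the
  pixel-level t and χ² tests likewise treat cells as independent), so
  p-values on real rasters are anti-conservative.
* The PVA omits inbreeding, catastrophes and supplementation scheduling;
  it is a desk-scale projector, not a replacement for a full PVA program.
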