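# Methods

This note records the models, conventions and numerical choices behind
`octfoci`, and what the synthetic phantom does and does not establish about
real OCT data.

## Coordinate and depth conventions

A volume is indexed `(b-scan, a-scan, depth)`; the depth index increases from
the vitreous (inner retina) toward the choroid, so the ILM height is always
smaller than the RPE height. Surface heights are 0-based *fractional*
depth-voxels: slab boundaries can fall between voxels without any intensity
resampling. Normalized depth is

    d = (z − z_ILM) / (z_RPE − z_ILM),

0 at the ILM and 1 at the RPE inner border; values outside [0, 1] are
extra-retinal. Surfaces with `z_ILM ≥ z_RPE` anywhere are rejected outright
("gross segmentation error") at load time — no downstream stage ever sees an
inverted surface.

## Slab geometry

K equidistant slabs (default K = 5) partition [0, 1]; slab `j` covers
`[(K−j)/K, (K−j+1)/K)`, numbered so **slab 1 is outermost** (RPE-adjacent),
the convention used in clinical reports of IHRF distribution. Intervals are
half-open at their inner edge and slab 1 is closed at `d = 1`, so every
retinal depth belongs to exactly one slab (a property test draws random
surface/depth triples and asserts unique membership). Interval bounds are
computed as `(K−j)/K` rather than `1 − j/K`: algebraically identical, but
exact in binary floating point for the decimal boundaries.

Voxel membership is decided by the normalized depth of the voxel *center*;
there is no sub-voxel intensity splitting. This makes slab extraction exactly
invertible in tests and gives a strong invariance: shifting the volume and
both surfaces by the same integer depth offset leaves every max-projection
slab image bit-identical. (For the mean projector the same values are summed
in a different order along the depth axis, so equality holds to floating
tolerance, about 1e-12 relative, rather than bitwise.)

The default projector is **maximum intensity**: the pipeline's purpose is
detecting bright punctate foci, and a max projection preserves them however
thin the slab; the mean projector is provided for visualization parity and
satisfies a thickness-weighted sum-consistency check against the full-retina
mean. If a slab has no voxel at some lateral position (retina thinner than K
voxels), it takes the intensity of the retinal voxel nearest the slab center
and the event is logged.

## Detection

Each slab image is binarized, artifact regions are removed, and connected
components with at least `min_area` pixels survive as foci.

* **Threshold.** Two methods are provided and recorded in the output
  provenance. *Otsu* (per slab, computed over non-artifact pixels) is
  parameter-free and exact on clean or clearly bimodal slabs; on a constant
  image no threshold separates anything, so the result is an empty foreground
  with a warning. *mean + k·SD* (default k = 4) is the robust choice when
  lesions occupy a tiny fraction of a speckled image — Otsu then splits the
  background mode instead and floods the image with foreground. k = 4 keeps
  the expected number of spurious supra-threshold pixels on a 32 × 128 slab
  well below one under an approximately Gaussian background, and isolated
  survivors are removed by the ≥ 3-pixel rule. The library default is Otsu;
  the end-to-end pipeline default config uses mean + k·SD because its phantoms
  are speckled.
* **Size rule.** The clinical criterion "well-circumscribed lesion ≥ 3 pixels"
  is applied as a ≥ 3-pixel en-face component area (configurable): the
  quantification happens on en-face slabs, and one consistent rule is needed.
* **Connectivity.** 8-connectivity by default, matching common
  particle-analysis behavior; 4-connectivity is available and every
  4-connected component is provably contained in exactly one 8-connected one.
* **Artifact masking.** Manual artifact removal is replaced by a programmatic
  union of (i) a vessel mask — the inner-retina (d < 0.4) en-face max
  projection thresholded at a robust multiple of its *median* (default 1.4×)
  and dilated by 1 px; (ii) a drusen mask — lateral positions where the RPE
  surface sits more than 3 voxels inward of its large-kernel
  (Gaussian, σ = 10 px) smoothed fit, dilated by 2 px; and (iii) an optional
  user-supplied binary TIFF. A mean + k·SD vessel threshold was rejected
  because it flags a fixed ~2 % of speckle maxima laterally; after dilation
  this can exclude a fifth of the grid and silently suppress unrelated foci.
  The median-multiple rule fires only on structures substantially brighter
  than the background mode. All exclusions are counted and logged.
* **No cross-slab deduplication.** A lesion spanning a slab boundary may
  appear in two slab images and is counted in each; the eye total is the sum
  over slabs, mirroring per-slab en-face counting. An optional centroid-based
  deduplication exists but is off by default.

## Phantom

The phantom emulates the statistical structure the analysis assumes, not OCT
physics. Geometry: a smooth RPE (bowl curvature; drusen as inward Gaussian
elevations up to 8 voxels, σ = 3 px, with RPE-band brightening) and an ILM
derived by subtracting a thickness field (foveal pit as ILM-side thinning,
low-frequency lateral variation). The fovea deliberately shapes the inner
retina only — a foveal bump on the RPE would be anatomically wrong and would
confound the drusen detector. Tissue: a piecewise reflectivity profile over
normalized depth (bright nerve-fiber layer, dark outer nuclear layer, bright
ellipsoid zone, RPE band, choroid). Vessels: bright inner-retina
(d ∈ [0.10, 0.32)) meandering lines casting multiplicative shadow columns
(transmission 0.45) beneath. Foci: ellipsoids (lateral radius ≥ axial radius,
defaults 1.3 / 1.0 px) with additive intensity (default 1.8 × base) followed
by clipping; a lateral radius ≥ 1 px guarantees an en-face footprint of at
least 5 pixels, safely above the counting rule — smaller foci must be flagged
sub-threshold explicitly. Speckle is multiplicative log-normal (unit mean,
default σ = 0.10), applied last.

All randomness flows from one seeded generator per call (surface, foci and
noise substreams are spawned from the config seed); identical (config, seed)
gives bit-identical volumes, surfaces and ledgers. Follow-up rendering of the
same eye reuses the anatomy seed with an independent noise seed.

Foci placed by per-slab target counts keep a normalized-depth margin
(≈ 0.03–0.04) from slab boundaries, a minimum lateral separation (8 px,
relaxed to 4 px on crowded grids, never lower so that default footprints
cannot touch under 8-connectivity), and avoid the phantom's own vessel and
drusen footprints. This makes the ledger an exact oracle: each implanted
focus is detectable, belongs to exactly one slab, and cannot merge with a
neighbor. The ledger's `expected_slab` is recomputed from `d` through the
slab engine, never stored independently of it.

The **follow-up simulator** draws Bernoulli persistence per baseline focus
(default 0.9, with 1 px lateral jitter) and per-slab Poisson counts of new
foci. The default rates (3, 2, 1, 0.2, 0 for slabs 1–5) encode the
outer-slab-biased accrual observed clinically, with the innermost slab never
gaining foci. Counts are drawn unconditionally — placement rejection only
moves positions — so empirical per-slab means are exactly the configured
Poisson means (verified to 3 standard errors over 200 replicates).

Default problem sizes are desk-scale: 32 × 128 × 192 voxels over a 6 × 6 mm
field, so a full generate-and-detect cycle takes a fraction of a second and
the recovery studies (20 phantoms each) run in seconds; a
`PhantomConfig.full_size()` mode provides the clinical 128 × 512 × 1024
geometry.

What the phantom does **not** emulate: point-spread function and sensitivity
roll-off, true speckle correlation structure, subretinal drusenoid deposits,
segmentation error on real pathology, motion artifacts, or realistic lesion
morphology (real IHRF vary in size, shape and reflectivity). Passing the
recovery criteria therefore shows the *pipeline arithmetic* is correct and
robust to the modeled confounders at the modeled contrast — not that the
detector matches human graders on clinical scans.

## Cohort statistics

Per-eye change is `month24 − baseline` per slab and in total; categories are
by sign, with "no change" meaning exactly zero (counts are integers).
Descriptive statistics use sample (n − 1) SD and midpoint medians.
Percentages are rounded half-up to one decimal for display (the reporting
convention of the clinical literature); raw counts and proportions are kept
alongside. The paired t statistic is `mean(d)/(SD(d)/√n)`; its two-sided p
is computed through the regularized incomplete beta function,
`p = I_x(df/2, 1/2)` with `x = df/(df + t²)`, and is cross-checked in tests
against `scipy.stats.ttest_rel` and against direct numerical integration of
the t density (1e-8 agreement). Degenerate inputs follow documented
conventions: all-zero differences give p = 1; zero variance with nonzero mean
gives an infinite-t flag with p = 0. Per-slab p-values are reported raw
(default display) and Holm-adjusted. A single-eye cohort yields descriptive
output with the test columns set to NaN.

Eyes are treated as independent observations even when a subject contributes
both; this mirrors the convention of the clinical analyses this package
reproduces, but inter-eye correlation means the nominal p-values are
anti-conservative for cohorts with many bilateral subjects. A mixed-effects
extension is out of scope.

## Known limitations

* Lesion identity is not tracked across visits; only counts are compared.
* Area, reflectivity and shape of lesions are recorded per visit but not
  analyzed longitudinally.
* The detector is 2-D per slab; no 3-D (B-scan-space) component analysis.
* Proprietary device formats are not read; volumes are plain multi-page TIFF
  with surfaces supplied as CSV.
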