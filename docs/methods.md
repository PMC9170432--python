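# Methods

`histoseg` segments a grayscale medical image — typically a brain MRI slice
with a hyperintense lesion — by fitting a Gaussian mixture model (GMM) to
the image's intensity histogram with expectation–maximization (EM) and
using the fitted mixture's statistics, instead of image gradients, as the
force that drives and stops an implicit deformable contour.  This note
records the model, its numerical choices, the synthetic data the tests run
on, and the limits of what those tests show.

## 1. Intensity mixture model

The intensity density is modeled as a univariate mixture

    p(x) = Σ_{l=1..L} π_l · N(x; μ_l, σ²_l),   Σ_l π_l = 1,  0 ≤ π_l ≤ 1.

The model is univariate because the object of analysis is the image
histogram: a single intensity channel, so each component's covariance is a
scalar variance.

**Weighted samples.** Fitting operates on weighted samples. A histogram
enters EM as (bin center, count) pairs whose counts multiply every sum, so
fitting a histogram is exact for the binned data, not an approximate
resampling of it.  With 128 bins over a 0–255 range the discretization
error on component means is well below bin width (tested).

**E-step.** Responsibilities r_il = π_l N(x_i; μ_l, σ²_l) / Σ_k π_k N(x_i;
μ_k, σ²_k), computed in log space with log-sum-exp so that an outlying
sample whose density underflows in every component still receives a valid
(normalized) posterior.

**M-step.** The standard maximum-likelihood update: π_l ← Σ_i w_i r_il / M,
μ_l ← responsibility-weighted mean, σ²_l ← responsibility-weighted variance
about the *new* mean, floored (below).  A component whose effective count
vanishes is reseeded at the sample the current mixture explains worst,
with a small weight and pooled variance, rather than crashing; the event
is logged.

**Initialization.** Default is weighted k-means on the sample values
(seeded by `random_state`, hence deterministic).  Evenly spaced quantile
means are offered (`init='quantile'`) but are not the default: with a
minority class holding only a few percent of the mass — exactly the lesion
regime — no quantile lands near the minority mode and EM converges to a
local optimum that merges it into a neighbor.  Random seeding is available
for robustness experiments.

**Convergence and safeguards.** Iteration stops when the relative change
of the log-likelihood falls below `tol = 1e-6` or after `max_iter = 500`
iterations.  Variances are floored at `1e-6 · (data range)²` to prevent
singular collapse onto a single sample.  The per-iteration log-likelihood
is recorded and must be nondecreasing (to 1e-8 absolute slack); the test
suite asserts this on every fit it performs.  Components are reported in
ascending-mean order so "darkest"/"brightest" labels are stable.

**Choosing L.** The number of components is selected by the Bayesian
information criterion, BIC = −2 log L̂ + k log M with k = 3L − 1 free
parameters, over candidates {2, 3, 4, 5}; ties break toward smaller L and
infeasible candidates (more components than distinct values) are skipped.
The default candidate ceiling matters: partial-volume ramps reward
ever-larger L, and beyond ~5 the extra components fragment tissue modes
(observed as degraded phantom segmentations).  When the class count is
known — e.g. the three-class phantoms — passing an explicit L is
preferable and is what the phantom tests do.

## 2. From mixture statistics to contour evolution

The classical geometric deformable model advances a front with speed
modulated by an edge stopping function g = 1/(1 + |∇G_σ∗I|²), which fails
where boundaries are weak.  Here the stop information comes from the
fitted mixture instead.  Each pixel's speed is a log-evidence ratio
between an "object" hypothesis (a chosen subset of components, e.g. the
brightest for a FLAIR-hyperintense lesion) and a "background" hypothesis
(the rest):

    F(x) = log Σ_{l∈obj} p_l · N(I(x); μ_l, s²_l)
         − log Σ_{l∈bg}  p_l · N(I(x); μ_l, s²_l),

clipped to ±F_max (F_max = 10).  F > 0 exactly where the object hypothesis
dominates, so the contour expands over object-like intensities and
retreats elsewhere — region competition with mixture-derived statistics.

Three choices control p_l, s²_l and the background set; the standalone
`posterior_speed_field` defaults to the plain MAP rule (p_l = π_l, fitted
variances, all non-object components as background), while the end-to-end
pipeline defaults differ in three deliberate ways:

1. **Uniform priors** (`prior_mode='uniform'`).  The MAP rule weights each
   hypothesis by prevalence.  A lesion occupying ~2% of the image then
   pays a log-prior penalty of log(π_bg/π_obj) ≈ 2–3, which moves the
   zero-speed crossing off the class boundary into the lesion core and
   systematically under-segments minority classes.  Dropping the
   prevalence factor (maximum-likelihood classification) removes that
   bias; on the weak-edge phantom suite it raised mean Dice from ~0.89 to
   ~0.93.

2. **Pooled variance** (`variance_mode='pooled'`).  With fitted
   per-component variances, the crossing between a narrow and a broad
   component sits far from the midpoint of their means.  On blurred
   boundaries one side is always broad (whichever component absorbed the
   partial-volume ramp), and the front lands well off the true edge — in
   either direction, depending on which side is broad.  Evaluating all
   components with one weight-averaged variance turns the rule into the
   equal-variance (nearest-mode) discriminant, whose crossing is the
   midpoint of the competing mode means — the unbiased boundary estimate
   for a symmetric intensity ramp.  Weak-edge suite mean Dice ~0.95 with
   this rule; crisp and noisy phantoms are unaffected (Dice 1.0).

3. **Transition-component exclusion.**  Components whose standard
   deviation exceeds 2× the median component standard deviation are
   treated as partial-volume (transition) components: they model boundary
   mixels, not a tissue class, and are excluded from the background
   hypothesis (never from the object).  If the filter would empty the
   background set it is ignored.

All three are plain keyword arguments; setting
`prior_mode='mixture'`, `variance_mode='fitted'`,
`exclude_transition_components=False` recovers the textbook MAP region
competition.

## 3. Level-set numerics

The contour is the zero level of a signed field φ (negative inside).  The
evolution is

    φ_t = −(F − ν·κ) |∇φ|,

with curvature κ = div(∇φ/|∇φ|) weighted by ν (`curvature_weight`,
default 0.3) smoothing the front.  Discretization:

- **Upwind propagation.** Godunov differencing for the F|∇φ| term: the
  forward/backward one-sided differences are combined according to the
  sign of F.  Curvature uses central differences.  The same operators work
  unchanged in 2-D and 3-D.
- **Time step.** Explicit Euler with a CFL guard: configurations with
  dt · max|F| > 0.5 grid units are rejected with an explanatory error.
  With F clipped at 10 the default dt is 0.05 (≤ 0.5 px of front motion
  per step).
- **Reinitialization.** Every 10 iterations φ is rebuilt as the signed
  Euclidean distance to the current mask boundary
  (`scipy.ndimage.distance_transform_edt`, with a half-pixel offset so
  the zero crossing sits between pixels).  |∇φ| ≈ 1 then holds in the
  band (tested to tolerance 0.2 away from medial-axis kinks).
- **Narrow band.** Updates apply only where |φ| < band_width (default 6
  grid units); reinitialization re-centers the band on the moving front.
  A consequence worth knowing: sign changes can only propagate from
  existing fronts, so a region-competition force cannot carve a hole deep
  inside a large initial region.  Checkerboard initialization (below)
  seeds fronts everywhere and is the right choice when the object class
  does not form one compact blob — e.g. segmenting the *darkest* class,
  which surrounds the brain.
- **Stopping.** The front is declared stationary when the fraction of
  sign-changed pixels per iteration stays below `convergence_frac = 1e-4`
  for one full reinitialization cycle of consecutive iterations.  The
  cycle requirement exists because sub-pixel stepping flips signs in
  alternating bursts (…, 416, 0, 412, 4, …): a single quiet iteration is
  not stationarity.
- **Initialization.** `otsu-box` (default): the bounding box of
  above-Otsu pixels dilated by 2 — a generous region containing every
  bright structure, from which the region force carves the lesion;
  `checkerboard`: alternating blocks of period 8; `user-mask`: signed
  distance to a supplied mask.

## 4. Baselines

Two classical gradient-driven deformable models provide the comparison,
deliberately simple members of their families rather than reproductions of
any specific published variant:

**Geometric (GD): geodesic active contour.**  φ_t = g|∇φ|(c + κ) +
w ∇g·∇φ with constant balloon c (default −0.5: the contour shrinks from a
seed box around the brightest intensity class until edges stop it) and
edge attraction weight w = 2.5.  Two numerical details matter on raw
intensity scales: the image is divided by an edge-sensitivity scale
(default: robust range / 24) before computing g, since otherwise g
saturates at ~0 over a multi-pixel band and the front freezes on the
band's outer flank; and the weighted ∇g·∇φ advection is required to seat
the front in g's minimum after the balloon stalls.  Defaults were fixed on
a crisp-disk phantom (Dice ≥ 0.95 there).

**Parametric (PD): Kass-style snake.**  N ≥ 8 control points on a closed
polygon take implicit internal-energy steps — the cyclic pentadiagonal
system for elasticity α (first-derivative penalty, default 0.3) and
rigidity β (second-derivative penalty, default 0.5) — plus explicit
external steps along ∇|∇G_σ∗I|², bilinearly interpolated at the points.
The polygon is resampled to uniform arc length every 5 iterations (which
also repairs incipient self-intersections) and rasterized to a mask at the
end.  The default initialization is a circle circumscribing the brightest
connected intensity component plus a small margin; a box-corner radius is
deliberately avoided because it can place the circle nearer surrounding
structures' edges than the target's.

On crisp phantoms both baselines are competitive (Dice ≈ 0.95–1.0).  On
blurred ("weak-edge") boundaries the GAC's g-dip becomes too shallow to
hold the shrinking front, which frequently leaks through and collapses,
while the snake — whose external force peaks exactly at the gradient
ridge, i.e. the ramp midpoint — degrades more gracefully.  The
mixture-driven method needs no edge at all and depends only on the
histogram fit, which is the comparison the package is built to exhibit.

## 5. Synthetic data

`simulate_gmm_samples` draws component labels from π and values from the
assigned component, returning the true labels for recovery tests.

`generate_phantom` renders a brain-like 2-D scene on a 0–255 scale:
background (mean 20), an elliptical "brain" of parenchyma (110) with
radii 0.42/0.38 of the grid, and an elliptical or wobbly-blob lesion
(200) strictly inside it — FLAIR-like hyperintensity.  Corruptions, in
order: optional Gaussian blur of the class-mean image (partial-volume
ramps; the truth mask stays the exact pre-blur geometry), optional smooth
multiplicative bias field (seeded quadratic polynomial scaled to a given
amplitude fraction), additive Gaussian noise.  Everything is a pure
function of spec + seed.

`phantom_suite` draws per-image lesion geometry (radius 8–13% of the grid,
random offset, ellipse or blob) with per-image seeds derived from a master
seed, at three difficulties: *crisp* (noise σ ∈ [1, 4], no blur),
*weak-edge* (blur σ ∈ [2, 3.5] plus noise σ ∈ [4, 8]) and *noisy*
(noise σ = 20% of the smallest class contrast, i.e. σ = 18 for the
default means).

What the phantoms do **not** emulate: Rician noise statistics, anatomical
texture and heterogeneity, multi-sequence contrast, partial-volume physics
beyond a Gaussian blur, motion or susceptibility artifacts.  Passing the
phantom suites demonstrates algorithmic correctness of the pipeline under
controlled degradations — not clinical-grade performance on patient data,
which the package has never seen.

## 6. Evaluation machinery

Voxel confusion counts give sensitivity TP/(TP+FN), specificity
TN/(FP+TN) and overall performance (TP+TN)/total; a metric whose
denominator is zero is reported as NaN with a warning, never silently 0.
Overlap uses Dice = 2TP/(2TP+FP+FN), with two empty masks defined as 1.0
(flagged).  AUC uses the rank (Mann–Whitney) formulation with average
ranks, so a tie between a positive and a negative score counts one half;
the ROC curve itself comes from scikit-learn's threshold sweep.  Cohort
tables are summarized as percentages rounded to one decimal.

## 7. Problem sizes and determinism

Default problem sizes throughout the package and its tests: 128×128 or
96×96 phantoms, 128-bin histograms, EM on ≤ 10,000 samples, 20-image
comparison suites.  These are the sizes at which every quantity the tests
assert is stable across seeds; all randomness flows from explicit seeds
(`numpy.random.default_rng`), and repeated runs with equal seeds are
bit-identical, which the suite asserts for the full pipeline.

## 8. Known limitations

- Single-channel intensities only; no multi-sequence joint mixtures, no
  spatial priors (Markov random fields) and no bias-field correction —
  a strong bias field breaks the global histogram separability the method
  relies on.
- Two-hypothesis (object/background) competition; no multi-phase level
  set for three or more simultaneous regions.
- The level set cannot nucleate new fronts away from existing ones (see
  the numerics section above); topology changes are otherwise
  unrestricted, which also means
  nothing prevents the mask from splitting or merging.
- The snake baseline is 2-D only; the mixture pipeline and the GAC run in
  3-D but with the same isotropic grid assumptions.
- BIC-based L selection inherits BIC's bias toward more components on
  smoothly smeared histograms; the candidate ceiling of 5 is a pragmatic
  guard, not a theorem.
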