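# Methods

This note records the statistical model, the defaults and why they are what
they are, what the synthetic generator does and does not emulate, and the
numerical choices made where the design was genuinely open.

## Voxelwise test

At each tested voxel the cohort splits into lesioned-here (n₁) and
intact-here (n₂) groups and their scores are compared with the Mann–Whitney
rank test. We use the tie-corrected normal approximation of U without
continuity correction; ties are pervasive in ordinal motor scores, so the
tie term Σ(t³−t) is required. The statistic is signed so that z > 0 means
the lesioned group scores *worse* — lower FMA-UL, lower TSRT — and the
one-sided p is the upper normal tail, which makes z ≥ 2.09 correspond to
p ≤ 0.018 exactly. Degenerate voxels (all scores tied) carry no signal and
return z = 0, p = 0.5 rather than erroring.

Because every voxel pools the same cohort, the score ranks and tie term are
shared across voxels; the whole map reduces to one rank-sum matrix product
over the lesion matrix. The scalar per-voxel routine and the vectorized map
are cross-checked against each other, against `scipy.stats.mannwhitneyu`
(asymptotic, no continuity correction), and against exhaustive permutation
enumeration in the test suite.

Accuracy of the normal approximation at desk scale: the U statistic itself
matches brute-force pair counting exactly at any n. The approximate p
agrees with mid-p exhaustive enumeration to < 0.03 in the decision-relevant
tail (exact p ≤ 0.1) for total n ≤ 10, but in mid-range p the discrete null
at such group sizes sits up to ~0.07 from the normal curve regardless of
convention; nothing downstream consumes mid-range p values.

## Voxel inclusion

A voxel is tested when lesioned in at least ⌊coverage·n⌋ subjects
(coverage = 0.20: 8 of 41 — the floor, not rounding, reproduces that count)
and intact in at least 2, since the rank test is degenerate against a
single intact subject. The intact-group guard is unobservable on realistic
cohorts, whose maximum overlap is far below n−1.

## Multiple comparisons and the lenient criterion

Benjamini–Hochberg step-up runs over the tested voxels only (untested
voxels have no p values). The realized cutoff p\* (the largest p actually
rejected) and its z equivalent are recorded. When the second analysis is
under-powered, it is thresholded per-voxel at the minimum z that survived
FDR in the reference analysis (`derive_lenient_threshold`); a fixed z
(e.g. 2.09) is available for strict replication of a printed criterion.
Filters apply in the order threshold → connected components → minimum
extent (10 voxels). Adjacency defaults to 26-connectivity — the common
neuroimaging choice — and is switchable to 6 or 18; the corner-touching
case is covered by a test.

Cluster and structure tables report, among voxels attaining the maximum z,
the most superior (greatest world z), then most posterior (least world y),
then most left (least world x) voxel, in world mm after any hemisphere
flip. The centroid is deliberately not reported: it may not attain the
maximum or even be significant.

## Hemisphere flipping

`flip_to_left` mirrors voxel index i → X−1−i about the left–right axis
mid-plane — exact for even and odd axis lengths, volume-preserving, and an
involution. Masks are assumed to sit on a shared template grid, so index
mirroring is preferred to resampling through the affine. The cohort helper
`unify_hemisphere` applies the mirror only to masks whose lesion mass lies
at positive world x, which is the operation actually wanted before a
single-hemisphere analysis; keeping the unconditional mirror separate keeps
it an exact involution.

## Conjunction

Both z maps are thresholded at the *same* per-voxel criterion z\* (not each
analysis' own corrected cutoff), so the A-only / B-only / both categories
are comparable. Classification is per-voxel with no contiguity requirement,
which is why structures can appear in the conjunction table without ever
forming a reportable cluster. The per-structure row filter keeps structures
with ≥ 10 voxels in at least one category; the alternative summed reading
is exposed as `row_filter="sum"`.

## TSRT estimation

EMG chain: full-wave rectification, then a 20 ms causal (trailing) moving
average — causal so the envelope never anticipates a burst. Stretch start
is the first sample whose smoothed angular speed exceeds 5°/s sustained for
half the smoothing window, skipping the first (edge-contaminated) window.
Background statistics are the mean and SD of the **rectified raw** EMG over
the 200 ms before stretch start; onset is the first sample from stretch
start whose envelope stays above mean + 3·SD for 25 ms. Computing the SD on
the envelope instead would shrink it by roughly √(window), producing a
margin that autocorrelated envelope noise drifts across for 25 ms — we
observed exactly such false onsets at near-zero stretch velocity, which are
poison for the regression (high leverage at v → 0).

Angle processing: 50 ms centered moving average, then a centered difference
whose half-span equals half the smoothing window (25 ms at 1 kHz). A
single-sample-spacing stencil would amplify 0.2° goniometer noise to
several °/s; the wide stencil keeps velocity noise under ~1°/s and is exact
on linear ramps.

The TSRT is the OLS intercept of dynamic threshold angle on stretch
velocity. Trials with no detected burst or non-positive onset velocity are
excluded and tallied; at least 5 usable trials (configurable) are required
— fewer make the extrapolation fragile. An intercept above 180° is returned
as-is with `in_range=False`: it encodes a reflex threshold outside the
biomechanical range (a fully relaxable muscle), and clamping would destroy
that information. Note that a planted threshold moderately above 180° can
still be *dynamically* reached at fast stretches (threshold decreases with
velocity), yielding a legitimate out-of-range extrapolation rather than an
all-trials-excluded error.

## Synthetic cohorts

The generator emulates the statistical shape of a 41-subject
single-artery-territory stroke cohort at 4 mm isotropic resolution (2 mm is
supported; 4 mm keeps a full cohort build under ~2 s and the math is
resolution-agnostic):

- **Lesions**: one connected blob per subject, grown by randomized frontier
  expansion inside a left-hemisphere territory box, volume lognormal
  (ln-mean 2.909, ln-SD 1.046 ⇒ mean ≈ 32 cc, SD ≈ 45 cc) clipped to
  0.4–182.3 cc. Seeds scatter around two foci (anterior/posterior
  sub-territories) plus a 25% uniform component — a single focus makes all
  regional lesion loads collinear and every map smears over the whole
  tested core.
- **Planted regions**: a 294-voxel "paresis" region and a 150-voxel
  "spasticity" region sharing a 50-voxel overlap zone, both inside the
  high-coverage core, so a conjunction has all three categories by
  construction.
- **Scores**: score = clip(baseline − effect·coverage-fraction + Gaussian
  noise), FMA-like clipped to [0, 66]. Defaults (baseline 39.5/126.5,
  effect 40/84, noise SD 6/8) were set once so the cohort moments land on
  the emulated cohort's description (FMA ≈ 32.3 ± 12.2, TSRT ≈ 107.4 ±
  25.7°) with lesion effects ≈ 3× the noise SD.
- **Stretch trials**: 20 per series, velocities split equally across slow
  (40–80), moderate (90–150) and fast (160–240 °/s) bands in shuffled
  order; the reflex burst (amplitude 20× the unit background noise)
  switches on when the true angle crosses tsrt + slope·v perturbed by 3°
  trial noise; goniometer noise 0.2°.

What the generator does **not** emulate: vascular-territory anatomy or
hemorrhagic/ischemic morphology (lesion growth is isotropic frontier
expansion), spatial autocorrelation of behavior beyond what shared lesions
induce, non-Gaussian score noise, stretch-reflex habituation, or
EMG nonstationarity. Passing recovery tests therefore show the chain is
correct and well-calibrated under its own assumptions, not that real
cohorts will yield maps this clean — real VLSM inherits lesion-anatomy
confounds that no per-voxel test removes.

Validation properties measured by `evaluation.py` and the test suite: Dice
between each lenient significance map and its planted region (restricted to
tested voxels) reaches ≥ 0.5 in ≥ 8 of 10 seeds; the conjunction's shared
category intersects the planted overlap; zero-effect cohorts give empty FDR
selections in ≥ 90 of 100 seeds; the threshold regression recovers a
noiseless planted line to 1e−9 and has mean absolute intercept error
< 1.5° over 500 noisy replicates.

## Degenerate inputs and numerical conventions

- All-tied scores at a voxel → z = 0, p = 0.5 (no signal, not an error).
- Empty FDR selection → lenient derivation raises; the pipeline then falls
  back to the fixed z criterion and records which source it used.
- Atlas structures named but absent from the label volume → percent damage
  NaN (undefined), never 0.
- Zero-variance baseline EMG → error (degenerate recording).
- Angles in degrees, velocities in °/s everywhere; no radian conversion.
- Every stochastic routine takes an explicit seed; there is no hidden
  global random state, and identical seeds give byte-identical cohorts.

## Known limitations

- Mass-univariate mapping cannot separate voxels that are damaged together;
  multivariate lesion-symptom methods and lesion-volume covariates are out
  of scope.
- The normal approximation's p is conservative/discrete at extreme group
  splits (see above); exact permutation p is available in the tests but not
  used in the pipeline.
- Registration, normalization and lesion segmentation are upstream of this
  package: masks are consumed as given on a shared grid.
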