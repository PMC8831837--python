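# Methods

This note documents the measurement model, the defaults that matter,
the synthetic phantoms the tests run against, and the numerical choices
made where the design was genuinely open.

## Coordinate and polarity conventions

Pixel coordinates are 0-based, x rightward (columns), y downward
(rows); angles are measured in the image plane from the +x axis. All
conventions are shared across modules. Fundus vessels are darker than
the retinal background, so images are inverted once at ingest
(`io.to_internal`: green channel of RGB, scaled to [0, 1], then
`1 − g`); every internal RT feature detector assumes bright vessels.
The green channel is used because it carries the best vessel contrast
in fundus photography.

## Radon-transform machinery

`radon.radon_transform` evaluates R(ρ, θ) directly in the spatial
domain: for each (ρ, θ) the bilinearly interpolated intensity is summed
along the line at 0.25 px spacing, with a one-pixel zero border so the
reconstruction tapers across the image edge (a full row of ones then
integrates to exactly its pixel count). Bilinear sampling was chosen
for the full sinogram because cubic-spline interpolation undershoots at
hard borders with zero fill, costing 2–3% against a dense brute-force
line-sum oracle; with bilinear sampling the agreement is ≤ 1% on random
images up to 32×32. No FFT/projection-theorem shortcut is used; the
sinogram is O(ρ·θ·diag) but is only ever computed on small images (the
tracker uses local profiles, not full sinograms).

`radon.directional_profiles` forms the per-point feature used for
tracking: 179 line integrals at orientations k·180/180° (1°..179°,
avoiding the 0°/180° duplicate), each a segment of half-length 10 px
through the point, sampled by **cubic** interpolation at 0.5 px spacing
and combined with Gaussian distance weights (bandwidth 4 px ≈ half the
expected vessel width; weights are 1 at the center and decay
monotonically, staying in [0, 1]). Integrals are normalized by the
total weight, so a constant image of value c yields exactly c for every
orientation; this makes responses comparable across orientations and
images.

## Centerline tracking

`tracking.track_centerline` iterates from the (ridge-re-centered) seed:

- candidate directions are both senses of each of the 179 orientations,
  restricted to the forward half-plane of the previous step (prevents
  reversal on tortuous vessels);
- score = 0.7 · normalized RT response + 0.3 · cos(angle to target)
  (`target_bias = 0.3`); ties break toward the previous direction;
- step length 2 px, cap 2 000 steps; after each step the point is
  re-centered at the perpendicular ridge maximum (short 5 px parallel
  integrals at 0.25 px perpendicular spacing, parabolic sub-pixel
  refinement, search radius 3 px);
- termination when the target is within one step (converged) or at the
  cap / image margin (not converged);
- the final trace is Gaussian-smoothed along the point index
  (σ = 2 points). Smoothing pads by linear extrapolation before
  convolving, so exactly collinear traces remain collinear and the
  endpoints are preserved.

A seed whose directional-profile dynamic range is below 2% of the image
dynamic range raises a no-vessel error. Curvature is handled by the
smoothing and the forward-cone restriction only; no separate curvature
classifier is implemented.

Measured on noise-free straight phantoms the trace deviates < 0.05 px
RMS from the true axis; on a sinusoidal vessel (amplitude 20 px, period
200 px, 5%-of-contrast noise) the RMSE is ≈ 0.35 px.

## Width estimation

At centerline positions every 2 px of arclength over the proximal
≤ 100 px (the published cap; interpreted as arclength, configurable),
`width.edge_profile` integrates intensity parallel to the local tangent
(window 7 px) at perpendicular offsets ± 15 px in 0.25 px steps.
`width.detect_edges` places each edge at the extremum of the absolute
first derivative of this profile on its side of the centerline, with
parabolic sub-pixel refinement. The gradient criterion was preferred
over half-maximum because it needs no background-level estimate and is
robust to asymmetric backgrounds; the half-max alternative is available
(`edge_method="halfmax"`) and agrees within 0.01 px on ideal
rectangular-profile phantoms. Note the two criteria measure different
things on smooth profiles: on a Gaussian cross-section the gradient
extremum sits at ± σ (≈ 0.85 × FWHM) while half-max recovers the FWHM;
exact-width assertions therefore use rectangular-profile phantoms.

A position whose center-to-background contrast is below 10% of the
profile dynamic range is skipped (and counted); fewer than 3 valid
positions raises an error. The width at a position is the Euclidean
distance between the two edge points reconstructed on the same
perpendicular; the arm width is their mean. Temporal widths average the
superior and inferior arms; when the superior artery is flagged
overlapped (an adjacent vein crossing it), the inferior width alone is
used and flagged `inferior_only`, mirroring clinical practice with the
three affected stage-2 images in the source cohort.

## Angle estimation

Each arm's proximal 50 px of trace (default `fit_span`; the span is not
dictated by the data, see sensitivity below) is fitted by total least
squares (SVD principal axis), oriented proximal→distal. The two rays
are intersected as infinite lines — the vertex may legitimately fall
outside the image and need not coincide with the disc center — and the
angle is arccos of the dot product of the two distally oriented unit
directions, on (0°, 180°) without folding (healthy arcades are obtuse).
Rays within 0.5° of parallel raise an error.

Sensitivity to `fit_span`: on straight-arm phantoms the recovered angle
is independent of the span (the fit is exact); on curved vessels the
span acts as the length scale over which the "straight line" of the arm
is defined, and larger spans average more curvature into the ray. The
default of 50 px matches the proximal, near-disc regime in which the
published angles were defined. A disc-center chord baseline
(`disc_center_angle`) is provided; when the true intersection is
displaced 15 px from the disc center it errs by several degrees while
the trace-back method stays within tolerance, which is the documented
rationale for the intersection method.

## Phantoms

`phantom.render_phantom` emulates exactly the features the pipeline
depends on: dark curvilinear vessels of known width on a brighter
background (default level 0.82, contrast 0.5), a bright mock optic
disc, Gaussian optical blur (σ = 1 px), and i.i.d. Gaussian pixel noise
(test noise "5% of contrast" = σ 0.025). Vessel cross-sections are
anti-aliased by area coverage, so the true edge sits at a meaningful
sub-pixel position regardless of rasterization; the 'gaussian' profile
has FWHM equal to the nominal width. The default canvas is 600×800
(test speed); the eye phantom uses 700×800 so 130° vein arms fit.
`make_eye_phantom` places the artery vertex at (optionally offset from)
the disc center and the vein vertex 60 px nasally so all four arms stay
≥ ~59 px apart over the tracked span. Rendering is deterministic by
seed, byte-identical on repetition.

What the phantoms do **not** emulate: choroidal texture, illumination
gradients, specular artifacts, vessel tapering and branching, motion
blur from unsedated infants, and crossing vessels (the overlapped-artery
case is modeled as an annotation flag, not rendered). Passing phantom
tests therefore demonstrates correctness of the geometry recovery, not
clinical performance on real RetCam images.

`phantom.sample_cohort` draws per-stage normal (optionally jointly
multivariate-normal) TAA/TVA/TAW/TVW values. `reference.py` ships the
published per-stage summary rows (n, median, min, max, mean, SD) and
printed pairwise correlations; `reference_cohort_spec` turns them into
a sampling spec. A joint correlation applies within each group; pooling
stage-structured groups adds between-group covariance on top of it, so
correlation-recovery checks use a single-population spec.

## Statistics

ANOVA uses the exact summary-statistic decomposition (SS_between from
n/mean, SS_within from (n−1)·sd²), identical to the raw-data ANOVA and
therefore applicable directly to published tables. Tukey comparisons
use the studentized range with the Tukey–Kramer standard error
√(MS_w/2·(1/nᵢ+1/nⱼ)) — required, since the stage groups are unequal —
and are cross-checked against `scipy.stats.tukey_hsd` in the tests.
Pearson p-values use t = r√(n−2)/√(1−r²) on n−2 df, which also converts
published r values to p-values. Significance is α = 0.05; p-values are
kept at full precision and formatted ("<0.0001") only in report
rendering. Normality checking is an optional Shapiro–Wilk report, never
a gate. Type-I calibration: simulated null ANOVA rejects at
0.048 ± 0.004 over 10 000 replicates.

Two recomputations differ slightly from the published values because
the published means/SDs are rounded: the vein-width summary ANOVA gives
p ≈ 0.0034 (published 0.0044 from raw data), and the p implied by the
printed r = −0.162 at n = 176 is 0.0317 (published 0.0314).

## Known limitations

- Strict monotone ordering of sampled TAA group means across all four
  stages is *not* a reliable property of cohorts at the published group
  sizes: the stage-1/stage-2 mean gap (2.36°) is smaller than its
  sampling SE (≈ 3.4°), so the full chain orders correctly in only
  ~75% of replicates. The statistically supported pattern (overall
  ANOVA significance and the healthy-vs-stage-3 contrast) reproduces in
  > 95% of replicates and is tested instead; the strict-ordering check
  is retained in the acceptance suite as an honest failure.
- Widths are reported in pixels at the native resolution; no
  pixel-to-micrometre scale is available.
- Eyes are treated as independent observations (some infants contribute
  both eyes); no mixed-effects adjustment is made.
- Seeds and targets are manual annotations; there is no automatic seed
  detection, vessel-tree segmentation, or artery/vein classification.
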