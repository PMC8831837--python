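# ropvessel

Radon-transform measurement of retinal temporal vessel **width** and
**angle** from fundus photographs of preterm infants, with the cohort
statistics that relate both to retinopathy of prematurity (ROP) severity.

## The problem

ROP is a retinal vascular disease of preterm infants and a leading cause
of preventable childhood blindness. As the disease progresses,
fibrovascular traction stretches the major temporal arcade vessels: the
angle between the superior and inferior temporal arms narrows, while the
vessels dilate. Quantifying the temporal artery angle (TAA), temporal
vein angle (TVA), temporal artery width (TAW) and temporal vein width
(TVW) therefore provides objective, stage-sensitive markers for
screening. Neonatal fundus images are noisy and the vessels are thin and
incompletely developed, which defeats threshold-based segmentation; this
package instead uses Radon-transform (RT) line integrals, which average
pixel noise away along the vessel direction.

## Method

For an image intensity g(x, y) the Radon transform is

    R(ρ, θ) = ∬ g(x, y) δ(ρ − x cos θ − y sin θ) dx dy

the integral of g along the line with normal orientation θ and offset ρ.
The pipeline, per annotated eye:

1. **Centerline tracking** — from a manual seed near the optic-disc
   margin, 179 directional line integrals (1° spacing, cubic
   interpolation, Gaussian distance weights) are evaluated at each
   centerline point Cn; the tracker steps along the direction combining
   the strongest RT response with progress toward the distal target
   point, re-centers on the perpendicular ridge maximum, and Gaussian
   smooths the trace.
2. **Width** — at centerline positions over the proximal ≤ 100 px, a
   second RT with line integrals *parallel* to the vessel direction is
   computed at signed perpendicular offsets; each vessel edge is the
   steepest transition of that profile, and the width is the Euclidean
   distance between the top- and bottom-edge points. TAW/TVW average
   the superior and inferior arms (inferior-only fallback when the
   superior artery is overlapped by a vein).
3. **Angle** — each arm's proximal trace is fitted with a total
   least-squares ray; the two rays are traced back to their intersection
   (not assumed to be the disc center) and the angle is
   arccos(d̂_sup · d̂_inf), reported on (0°, 180°).
4. **Statistics** — one-way ANOVA across stage groups (raw data or
   published n/mean/SD summaries, which is exact), Tukey–Kramer multiple
   comparisons via the studentized range, and Pearson correlations with
   t-based p-values.

A `phantom` module renders synthetic fundus-like images (dark
anti-aliased vessels of known width and inter-arm angle, mock disc,
blur, Gaussian noise) with exact ground truth, and samples synthetic
per-stage measurement cohorts; all tests run against these phantoms.

## Worked example

```python
from ropvessel import make_eye_phantom, render_phantom, measure_eye
from ropvessel.io import to_internal

spec = make_eye_phantom(angle_artery=110.0, angle_vein=120.0,
                        width_artery=4.0, width_vein=6.0,
                        noise_sigma=0.025, seed=42)
image, truth = render_phantom(spec)
m = measure_eye(to_internal(image), truth.annotation())
print(f"TAA = {m.taa:.2f} deg   (design 110.00)")
print(f"TVA = {m.tva:.2f} deg   (design 120.00)")
print(f"TAW = {m.taw:.2f} px    (design 4.00)")
print(f"TVW = {m.tvw:.2f} px    (design 6.00)")
```

prints

```
TAA = 110.28 deg   (design 110.00)
TVA = 119.84 deg   (design 120.00)
TAW = 3.91 px    (design 4.00)
TVW = 5.93 px    (design 6.00)
```

i.e. with 5%-of-contrast pixel noise the pipeline recovers the designed
angles within ~0.3° and the designed calibers within ~0.1 px. On the
published per-stage summary rows:

```python
from ropvessel import anova_from_summary
from ropvessel.reference import reference_summaries
a = anova_from_summary(reference_summaries("taa"))
print(f"TAA ANOVA: F({a.df_between}, {a.df_within}) = {a.F:.2f}, p = {a.p:.3g}")
```

```
TAA ANOVA: F(3, 172) = 57.06, p = 1.18e-25
```

confirming the strong decrease of the artery angle across ROP stages;
the Tukey–Kramer analysis flags every stage pair as different except
stage 1 vs stage 2.

## Command line

```
ropvessel simulate --spec spec.json --out phantoms/ --seed 7
ropvessel measure phantoms/*.png --annotations phantoms/ --out results.csv
ropvessel stats results.csv --out report/
```

`simulate` renders phantom eyes and/or samples synthetic cohorts,
`measure` runs the full pipeline per annotated image into a results CSV,
and `stats` emits a per-stage Markdown report (median/min–max/mean ± SD,
ANOVA p, Tukey letters) plus a pairwise correlation CSV. `stats
--summary` accepts a published-style summary table (variable, stage, n,
mean, sd) instead of raw results.

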