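# Methods

## The measurement model

The quantity of interest is the local advance of a lesion border
between two visits.  Let `M0` and `M1` be the registered binary masks
of an eye's geographic-atrophy (GA) lesions at baseline and follow-up,
with `M1` resampled into the baseline pixel frame.  The Euclidean
distance map of the baseline,

    D(p) = min over q in M0 of ||p - q|| ,

is computed exactly (scipy's exact Euclidean distance transform, not a
chamfer approximation) between pixel centers and scaled to mm.  For
every pixel `p` on the border of `M1` — a lesion pixel with at least
one non-lesion 4-neighbor — the local border expansion rate is

    BER(p) = D(p) / Δt      [mm/y],

with `Δt` the visit interval in years (days/365.25).  The eye-specific
BER is the unweighted mean over all follow-up border pixels.  The
model's central assumption is that the border advances roughly normal
to itself by less than the lesion's feature size per interval, so the
shortest distance to the baseline set is the path the border actually
took; the quality-control rules below flag eyes where that assumption
breaks.

Three conventions are deliberate and consequential:

* **Distances between pixel centers**, with no half-pixel border
  offset.  This makes the EDM exactly verifiable against a brute-force
  all-pairs oracle and leaves a sub-pixel negative bias in measured
  advances (the follow-up border pixel center sits inside the true
  boundary), constant across eccentricity.
* **Follow-up border pixels inside the baseline lesion score 0**, not
  negative: the EDM is zero there.  Local regression and delineation
  jitter therefore truncate at zero; the count of such pixels is
  reported per eye (`n_inside_baseline`) as a QC signal.
* **Components present at only one visit are excluded** before
  measurement by overlap matching (a component with zero pixel overlap
  against the other visit's union is dropped and logged), since a new
  or vanished lesion is not border expansion.

## Coordinates, laterality, and zones

Physical coordinates are mm relative to the foveal center, +x temporal
and +y superior.  On the raster, superior is up; temporal is toward
decreasing column for right eyes (OD) and increasing column for left
eyes (OS) — the optic disc, which is nasal, sits on the opposite side.
Polar angle is measured counter-clockwise from temporal, so quadrant
membership (temporal/superior/nasal/inferior, bounded by the ±45°
diagonals) is laterality-correct by construction.

Ring schemes cover 0–3.5 mm of eccentricity: seven 0.5-mm-wide annuli,
or seven equal-area annuli of π·3.5²/7 = 5.50 mm² each with boundaries
r_k = 3.5·√(k/7).  The ETDRS quadrant grid spans 0.5–3.0 mm.  Ring
intervals are half-open at the inner radius, so a point at exactly
0.5 mm belongs to the second ring.  Percent-area-affected denominators
are analytic zone areas, not zone∩frame areas; a warning is logged
when the imaging frame clips a zone.  No statistic is computed beyond
3.5 mm.

## Morphometrics

Area is the pixel count times the pixel area.  Perimeter is the summed
length of sub-pixel iso-contours (marching squares at level 0.5) taken
per 8-connected component on a lightly smoothed field (Gaussian,
σ = 1 px): contouring the raw binary raster overestimates a disk's
circumference by ~5.5% from staircase bias, while the smoothed contour
is accurate to <1% on disks from 0.5 to 3 mm radius and ~1% on
squares.  Components too small to survive smoothing fall back to the
raw contour so no lesion silently loses its perimeter.  This matters
quantitatively: the circularity index 4πA/P² and the
perimeter-adjusted growth rate (ΔA / mean(P0, P1) / Δt) both divide by
perimeter.  Lesion counting uses 8-connectivity, border detection the
complementary 4-neighborhood, the standard pairing that avoids
foreground/background topological paradoxes.

## Registration

Three corresponding vessel-bifurcation landmarks per visit determine
the exact 6-degree-of-freedom affine map (not a least-squares
similarity fit); collinear or coincident triplets are rejected rather
than regularized.  Masks are warped with nearest-neighbor
interpolation so they stay binary, and all downstream geometry uses
the baseline fovea.  Visit intervals other than one year are
annualized — a deliberate generalization beyond paired annual visits.

## Quality control

Two exclusion rules, applied per eye and reported in every cohort
output:

* **Margin merging** — flagged when the follow-up component count
  drops below the baseline count (separate lesions fused) or when the
  follow-up mask encloses more background holes than the baseline (a
  margin folded onto itself, e.g. a C-shape closing into an annulus).
  Holes are counted with 4-connected background labeling, excluding
  components that touch the frame.
* **Nonlinear growth** — for each follow-up border pixel, the straight
  segment to its nearest baseline lesion pixel (first minimizer in
  row-major order; only feasibility matters, not the choice of
  minimizer) is rasterized and checked against the union of the two
  masks.  The eye is flagged when more than 1% (configurable) of
  segments leave the union, meaning the shortest-distance reading cut
  across retina that was never atrophic.

Both rules are algorithmic formalizations of criteria originally meant
for manual review; they are deterministic proxies, not a claim of
equivalence to human graders.

## Statistics

* Univariable associations between an eye-level growth outcome (area
  growth rate mm²/y, or eye-specific BER mm/y) and one baseline factor
  use a linear mixed model with the eye as the unit of analysis and a
  random intercept per patient (statsmodels MixedLM, REML, Wald 95%
  CIs; p-values to 3 significant figures, no multiple-testing
  correction).
* The eccentricity model regresses per-eye per-ring mean BER on
  eccentricity adjusted for baseline area, with patient-level random
  intercept and eccentricity slope (unstructured 2×2 covariance,
  intercept–slope correlation allowed) plus an eye-level random
  intercept nested in patients.  If the full structure is singular or
  fails to converge, the patient slope is dropped, the fit repeated,
  and the simplification reported — never silent.
* Two details of the zone-level rows protect the slope estimate from
  measurement-error artifacts.  (1) Border samples are binned into
  rings by the eccentricity of their *baseline anchor* (the nearest
  baseline lesion pixel).  Binning by the sample's own noisy position
  lets ring boundaries select on delineation error — outward-jittered
  border patches land in the outer ring with correspondingly larger
  measured advances — which in simulation produced a spurious
  +0.003 mm/y-per-mm slope and a ~50% rejection rate under a flat
  field.  (2) The eccentricity covariate is the mean observed
  eccentricity of the samples in the ring, not the ring midpoint; the
  midpoint acts as classical error-in-x and attenuates the slope by
  ~7% at these lesion scales.  In addition, ring rows supported by
  less than 0.25 mm of border arc (about one correlation length of
  delineation error) are dropped: a ring mean estimated from a
  handful of pixels is a single noisy patch, and such crumb rows
  concentrate exactly where a ring boundary clips a border, where
  their errors co-move with the covariate.  With these choices the
  estimator is calibrated (nominal type-I error, CI coverage ≈ 95%
  in the recovery experiments).  The descriptive zone profiles keep the plain
  definition — a border pixel belongs to the ring its own eccentricity
  falls in — so plotted profiles remain directly interpretable.
* Quadrant comparisons use the Friedman rank test (mid-ranks,
  chi-square approximation) on complete block-by-quadrant matrices;
  a matrix whose blocks are fully tied carries no ranking information
  and returns statistic 0, p = 1.
* Agreement metrics: Dice 2|A∩B|/(|A|+|B|) (defined as 1 when both
  masks are empty), and the intraclass correlation as the two-way
  random-effects, absolute-agreement, single-measurement form — the
  common reading of "two-way model with single measurements"; absolute
  agreement (not consistency) is chosen so systematic offsets between
  graders are penalized.

## Synthetic data generator

The generator inverts the measurement.  A growth field
`f(r, θ) = max(0, β0 + β1·r + quadrant offset)` in mm/y is evaluated
at every pixel, and the follow-up lesion is the EDM level set

    M1 = M0 ∪ { p : D(p) ≤ f(p)·Δt + ε(p) } ,

so for slowly varying fields the measured local BER at a follow-up
border pixel equals the field there up to discretization — parameter
recovery is a sharp end-to-end test.  Morphological dilation was
rejected as the growth engine because it cannot express smooth spatial
variation of the advance.

Defaults describe a plausible macular study: β0 = 0.10 mm/y at the
fovea and β1 = 0.04 mm/y per mm (0.10 → 0.24 mm/y across 0–3.5 mm),
no quadrant offsets; hierarchical Gaussian offsets to the intercept of
sd 0.03 mm/y between patients and 0.02 mm/y between eyes; delineation
error ε as a Gaussian random field of sd 0.02 mm/y.  The error field
is spatially *correlated* (Gaussian kernel, correlation length
0.25 mm, the scale of reported inter-grader marking discrepancies)
rather than independent per 10-µm pixel: human graders trace smooth
polylines, and i.i.d. pixel noise would both look unlike real
delineations and manufacture pixel-scale raggedness that no tracing
produces.  The threshold is truncated at 0, so the follow-up always
contains the baseline — the generator does not model regression or
new-onset lesions, matching the pipeline's exclusion of
single-visit components.  Baseline lesions are disks, lobulated blobs
(random low-order Fourier modulation of the radius), or two-component
multifocal sets, mixed 45/25/30% in cohorts; radii are uniform on
0.5–1.5 mm and lesion centers are displaced from the fovea by up to
1 mm (capped so the grown lesion stays inside the field of view).
The default frame is 860×860 px at 10 µm (≈8.6 mm, a 30° macular
field).  Every output is a pure function of (spec, seed).

What the generator does *not* emulate: photorealistic fundus texture,
grader-specific bias, drusen, foveal-sparing shape dynamics beyond
what the eccentricity gradient induces, incident lesions, or
correlated follow-up of more than two visits.  Passing the recovery
experiments therefore demonstrates that the pipeline measures what it
claims on lesions with known kinetics — not that real CFP delineations
are free of systematic grading error.

## Problem sizes and numerical choices

Cohort simulation studies run with 50-patient cohorts on scaled-down
frames: the slope-recovery and type-I calibration experiments at
15 µm pixels (427×427, a 6.4-mm field) — at 20 µm the per-cohort
discretization of small lesions biases individual slope estimates by
more than a CI width, while at 15 µm the estimator is calibrated —
and the morphology-independence contrast, which only needs eye-level
means, at 20 µm.  The single-eye validation cases (EDM oracle,
concentric growth, field recovery) run at the native 10 µm.  Landmark triplets are
rejected when their triangle area falls below 10⁻⁶ px².  The
EDM is exact, so the only discretization tolerances in the pipeline
are the ±1 px band on measured advances and the ~1% contour error on
perimeters.  CSV outputs use fixed float formatting and stable column
order; two identical runs produce byte-identical files.

## Known limitations

* Local BERs of adjacent border pixels are strongly correlated; the
  zone-level mixed model absorbs this only partially (eye and patient
  random effects), so its p-values are approximate for irregular
  lesions.
* The eye-specific BER weights every border pixel equally, so an eye
  with a long static border and one fast protrusion reads low; the
  perimeter-adjusted growth rate behaves differently in that case even
  though the two agree for uniform growth.
* Masks touching the imaging frame are measured but logged; border
  statistics at the frame edge reflect the field of view, not biology.
* The QC rules are proxies with a configurable threshold; borderline
  merge geometries (e.g. margins that approach without topological
  change) are not flagged.
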