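# gaber — local border expansion kinetics of geographic atrophy

Geographic atrophy (GA), the late atrophic stage of non-exudative
age-related macular degeneration, enlarges over time as its sharply
demarcated border advances into healthy retina.  Trials and natural
history studies usually track the growth rate of total lesion area
(mm²/y), but that number is confounded by baseline morphology: a large,
irregular, or multifocal lesion has more border available to advance,
so it gains more area at the same local speed.  `gaber` implements a
*distance-based* alternative for anyone analyzing serial GA
segmentations: measure how far each point of the border travels per
year, everywhere along the border.

## The measurement

Given a registered pair of binary lesion masks (baseline and follow-up
visit of one eye, default pixel size 10 µm):

1. Build the **Euclidean distance map (EDM)** of the baseline lesion
   union: every pixel holds its exact Euclidean distance (mm) to the
   nearest baseline lesion pixel, 0 inside the lesion.
2. Read the EDM at every pixel of the **follow-up border** and divide
   by the visit interval in years.  Each value is a **local border
   expansion rate** (local BER, mm/y) — the shortest distance that
   point of the border moved.
3. The **eye-specific BER** is the mean local BER over all border
   pixels of the eye,

       BER_eye = (1/N) Σ_i EDM(p_i) / Δt .

Around this core the package provides: per-visit morphometrics (area,
perimeter by sub-pixel contouring, lesion count, circularity
4πA/P², border–fovea distance); landmark-based affine registration of
visit pairs; topographic profiles over concentric rings (0.5-mm
equal-width or equal-area out to 3.5 mm) and ETDRS quadrants,
including the percentage of each zone affected by GA; automated
quality-control rules for margin merging and nonlinear growth; the
perimeter-adjusted growth rate (ΔA / mean perimeter / Δt); linear
mixed-effects models relating growth outcomes to baseline factors and
local BER to eccentricity; Friedman tests across quadrants; Dice and
ICC agreement metrics; and a synthetic lesion-growth simulator with
known ground truth for end-to-end validation.

## Worked example

Simulate a small cohort with a known eccentricity gradient
(0.10 mm/y at the fovea, +0.04 mm/y per mm) and run the pipeline:

```bash
gaber simulate --out demo --seed 5 --n-patients 4 --pixel-size 0.02 --frame 300
gaber report --manifest demo/manifest.csv --out demo_report
```

which prints

```
report written to demo_report (5 eyes, 0 QC-flagged)
```

and writes `cohort_table.csv` (one row per eye with morphometrics,
eye-specific BER, area growth rate, perimeter-adjusted rate, QC
flags), `zones_pooled.csv`, `table_one.csv`, `eccentricity_model.csv`,
and `run_log.json`.  The same steps from Python, for a single eye:

```python
import gaber
from gaber.synthetic import GrowthField, SyntheticEyeSpec, make_eye_pair

field = GrowthField(intercept_mm_per_yr=0.10, slope_per_mm=0.04)
pair = make_eye_pair(SyntheticEyeSpec(seed=17, radius_mm=1.0,
                                      lesion_center_offset_mm=(0.2, 0.6),
                                      frame_shape=(600, 600)), field)
eye = gaber.measure_pair(pair)
print(f"{eye.eye_specific_ber_mm_per_yr:.3f} mm/y "
      f"over {eye.n_border_samples} border pixels")
```

prints `0.145 mm/y over 648 border pixels` — the mean of a field that
runs from ~0.12 mm/y at the lesion's foveal edge to ~0.17 mm/y at its
far edge.  For perfectly concentric disks growing 1.0 → 1.2 mm in one
year, both the eye-specific BER and the perimeter-adjusted growth
rate evaluate to 0.200 ± 0.003 mm/y, as the geometry demands.

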