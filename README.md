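# fibroct

Quantification of myocardial fibrosis on **native (non-contrast) cardiac CT**.

Myocardial fibrosis — excess extracellular collagen — is normally assessed
with cardiac MR (late gadolinium enhancement, T1 mapping / ECV), which is
expensive and contraindicated in some patients. `fibroct` implements a
computer-assisted alternative that works directly on plain CT slices:

1. **Read** a DICOM slice and convert stored pixel values to Hounsfield
   units (HU) via the modality rescale transform
   `hu = raw * slope + intercept`.
2. **Detect the heart contour** with a classical active contour ("snake"):
   a closed curve minimising elastic (α = 0.15) and bending (β = 5) internal
   energy plus an edge-attraction external energy (squared gradient
   magnitude of the Gaussian-smoothed, σ = 3, min–max-normalised image),
   evolved with semi-implicit steps (γ = 0.001, 10 iterations by default).
3. **Derive the ROI** as the outward-rounded bounding rectangle of the
   evolved contour.
4. **Classify** every ROI pixel as fibrosis iff its HU value lies in the
   closed band **[60, 90] HU**, and report the fibrosis percentage
   `100 · n_fibrosis / n_ROI`.

The package also implements the statistics used to validate the
measurement — per-patient replicate mean/SD/CV, cohort CV (arithmetic and
root-mean-square), intraclass correlation ICC(A,1) with a 95% CI,
Pearson correlation with interpretation bands, paired *t*, KS normality,
the ECV formula and a Fisher-z sample-size calculator — plus a synthetic
DICOM **phantom generator** with exact ground truth, so the whole pipeline
is testable end to end without patient data. An Agatston-style calcium
lesion score (≥130 HU, ≥4 contiguous pixels, >1 mm²) is included as an
optional extra.

It is intended for imaging-methods researchers prototyping CT-based
fibrosis markers, not for clinical use.

## Worked example

```python
from fibroct import (PhantomSpec, SnakeConfig, generate_phantom,
                     detect_fibrosis, fibrosis_percentage_for_image,
                     icc, aggregate_cv, replicate_table_stats)
from fibroct.datasets import repeat_run_replicates

# a synthetic slice with a known planted fibrosis fraction
spec = PhantomSpec(fibrosis_fraction=0.10, seed=7)
ct, truth = generate_phantom(spec)
forced = detect_fibrosis(ct, truth.true_bbox)          # ROI = true heart bbox
auto = fibrosis_percentage_for_image(ct, SnakeConfig())  # full snake pipeline

# reliability statistics of an 8-patient repeat-run replicate table
table = repeat_run_replicates()
rows = replicate_table_stats(table)
res = icc(table)
agg = aggregate_cv(rows["cv_percent"].to_numpy())
```

prints (via the obvious `print` statements):

```
planted fraction in bbox: 7.85%
forced-ROI percentage:    7.85%  (1413 of 18000 pixels)
auto-ROI percentage:      6.76%
ICC(A,1) = 0.9967  (95% CI 0.9892-0.9993, p = 3.0e-17)
cohort CV: 1.52 +/- 1.65% (arithmetic), RMS 2.17%
```

Reading: with the ROI forced to the true bounding box the planted fraction
is recovered exactly (the phantom is noise-free); with the automatic
initialiser the snake's ROI is slightly larger than the tight box, so the
percentage is about one point lower. The replicate table's ICC rounds to
1.00 — single readings of the algorithm are essentially perfectly reliable
— and the average per-patient coefficient of variation is 1.52 ± 1.65%.

## Command line

```sh
fibroct phantom --out data --n 3 --fraction 0.10 --noise 0 --seed 42
fibroct quantify data/*.dcm --out results      # images.csv, patients.csv
fibroct repeat data/phantom-0-rep1.dcm --out rep.json --iteration-increment 10
fibroct stats replicates.csv                   # mean/SD/CV, cohort CV, ICC
fibroct segment data/*.dcm --out seg           # contour overlays (PNG)
fibroct report results/images.csv --out patients2.csv
```

Overlays show the initial contour as a red dashed line, the evolved contour
solid blue, and classified fibrosis pixels in a third colour. All commands
are fully deterministic for fixed inputs and seeds.

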