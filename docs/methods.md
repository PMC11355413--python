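# Methods

## Measurement model

The quantity produced for each CT slice is the fraction of pixels in a
heart-containing rectangular region whose native attenuation lies in a
fibrosis band:

    fibrosis % = 100 · |{(r,c) ∈ ROI : 60 ≤ HU(r,c) ≤ 90}| / |ROI|

The band is a closed interval; its endpoints were established empirically
(comparative measurements of normal vs pathological myocardium) and are
exposed as parameters (`hu_low`, `hu_high`). The band classifies *any*
tissue with that attenuation as fibrosis; microvascular ischaemia or other
processes in the same HU range are indistinguishable — this is a marker,
not a histological measurement.

HU values come from the DICOM modality rescale transform and are kept as
floats; stored values are integers, so a written-then-read slice reproduces
intended HU only to ±0.5 (quantisation). No re-quantisation is applied
after rescaling, avoiding edge artefacts exactly at the band boundaries.

### Denominator

The denominator is the full ROI rectangle, because the classification
traverses the rectangle pixel by pixel with no interior masking. A
non-canonical interior-only mode (denominator restricted to pixels inside
the evolved contour, rasterised by polygon fill) is available via
`detect_fibrosis(..., interior_mask=...)` for sensitivity analyses.

## Heart detection (snake)

A closed parametric contour with `n_points` samples (default 200; dense
enough that the bounding box is insensitive to sampling) minimises

    E_int = α Σ |Δx_i|² + β Σ |Δ²x_i|²   (periodic differences)

against an edge-attraction external energy. Parameters α = 0.15, β = 5,
γ = 0.001, σ = 3 and 10 iterations are the protocol defaults for cardiac
CT; all are configurable.

**External energy.** The image is min–max normalised to [0, 1] (so the
energy is invariant to positive affine HU rescaling), smoothed by a
Gaussian of std σ, and the energy is the squared gradient magnitude of the
smoothed field, **rescaled to unit peak**. The rescaling is a numerical
conditioning choice: the squared gradient of a smoothed unit edge is
O(10⁻²), too weak to balance the implicit internal step at γ = 0.001, and
without it the contour collapses through real edges. It changes only the
force scale, never its direction, and makes behaviour comparable across
images of different contrast. Gradients are central differences
(`np.gradient`); the force is sampled at contour points by bilinear
interpolation.

**Time stepping.** Each iteration solves

    (A + γ I) x_new = γ x + f_ext(x)

separately for rows and columns, where A is the periodic pentadiagonal
stiffness matrix assembled from α (first-difference penalty) and β
(second-difference penalty), LU-factored once per run. This is the
classical semi-implicit snake scheme: the internal term is treated
implicitly with an effective step of 1/γ, which is unconditionally stable;
small γ therefore means *strong* internal smoothing per iteration. The
per-step displacement is capped at `max_px_move` (default 1 px) by
uniformly scaling the step — uniform scaling keeps each step a proximal
descent step on the internal energy, so on a featureless image the
internal energy is provably non-increasing across iterations, and the cap
prevents the strongly damped early iterations from jumping across the edge
ridge. Points are clamped (not reflected) to image bounds. The solver
contains no randomness: results are bit-reproducible.

**ROI.** The region of interest is the outward-rounded bounding rectangle
of the evolved contour: `row_min = floor(min rows)`,
`row_max = ceil(max rows)` (likewise columns), clamped to the image, with
*inclusive* bounds.

**Initialisation.** Initial contours are per-image ellipses. In the
original protocol they were placed by manual testing; the package accepts
them via a YAML config (`images: {id: {center: [r,c], axes: [ar,ac]}}`)
and additionally provides an automatic fallback (ellipse at the centroid
of HU > −200 tissue, semi-axes 1.2× the tissue bounding half-widths) so the
tool runs unattended. The fallback is a convenience, not a reproduction of
the manual placement: with the default 10 iterations and the 1 px step cap
a far-away initial contour has not fully converged, which is visible as a
slightly inflated ROI (and is why repeatability experiments should use
initial contours near the boundary, as the manual protocol did).

## Phantoms

`generate_phantom` builds the minimal geometry the pipeline is sensitive
to: an elliptical "heart" (myocardium 40 HU, inner blood-pool ellipse at
45 HU, semi-axes 0.45× the heart's) on a −800 HU background, with
`round(fraction · heart pixels)` randomly chosen heart pixels set to 75 HU.
Tissue values sit deliberately just below the 60 HU edge to stress the
closed-interval boundary. Optional Gaussian HU noise is added *after* the
ground-truth masks are captured, so the expected classification error
under noise is the analytic normal band-crossing rate (e.g. myocardium
crossing into the band is a 4σ event at σ = 5 HU). Slices are encoded with
slope 1 / intercept −1024 into unsigned 16-bit DICOM with deterministic
UIDs: the same seed yields byte-identical files.

Replicate sets jitter the heart centre and axes by uniform offsets in
[−jitter, +jitter] px drawn from streams seeded `seed + image_index`; the
phantom's own placement seed stays the base seed, so jitter 0 reproduces
identical images while jitter > 0 emulates different slices of one
patient. Defaults (256×256, axes 60×75 px, 0.6 mm pixels, 10% planted
fraction in tests) were chosen once as a plausible desk-scale cardiac
geometry. What phantoms do **not** emulate: anatomical texture, partial
volume effects, beam hardening, contrast phases — passing phantom tests
demonstrates algorithmic correctness (geometry, counting, determinism),
not clinical accuracy.

## Reliability statistics

* `replicate_stats`: per-patient mean, **sample** SD (denominator k−1) and
  CV = 100 · **population** SD (denominator k) / mean. The estimator mix is
  deliberate: it is the only combination that reproduces both printed
  summary columns of the source replicate tables, and it is documented
  rather than silently "fixed". Reported values are rounded half-up to two
  decimals; full precision is available with `ndigits=None`.
* `aggregate_cv`: cohort summary of per-patient CVs, arithmetic mean ± SD
  by default (matching how the cohort value was reported) with the
  root-mean-square form also computed (matching how the method was named).
* `icc`: two-way ANOVA mean squares (subjects × occasions);
  single-measurement absolute agreement ICC(A,1) by default,
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))`, 95% CI by the
  F-distribution method with Satterthwaite degrees of freedom, p-value
  from F = MSR/MSE with (n−1, (n−1)(k−1)) df. ICC(C,1) (consistency) is
  available via `model="consistency"`. The variant choice (one observer,
  fixed occasions, reliability of a single reading) is a judgement call
  and is labelled in the result. Cross-checked against
  `pingouin.intraclass_corr` to 1e-10 in the tests.
* `pearson` / `interpret_r`: product-moment r with bands on |r| —
  < 0.1 none, [0.1, 0.3) low, [0.3, 0.5) medium, [0.5, 0.7] high,
  > 0.7 very high. The published band edges overlap at 0.7; the closed
  upper edge of "high" reproduces every published label.
* `paired_t_test`: identical vectors return t = 0, p = 1 (no difference to
  test); a non-zero constant difference has zero variance and raises.
* `ks_normality`: one-sample KS against a normal with the sample mean/SD.
  Parameters are estimated from the data, as in the desk-calculator
  workflow this mirrors; without a Lilliefors correction the p-value is
  mildly conservative.
* `ecv_fraction`: ECV = (1 − hct) · [(1/pT1m − 1/nT1m)/(1/pT1b − 1/nT1b)],
  in percent; T1 times in ms.
* `sample_size_correlation`: Fisher-z,
  n = ⌈((z₁₋α/₂ + z_power)/atanh r)² + 3⌉; r = 0.35 at α = 0.05, power
  0.80 gives n = 62.

## Problem sizes and numerical choices

Tests and examples run on 256×256 phantoms with 200-point contours;
snake convergence checks use up to 500 iterations (a few seconds — each
iteration is two 200×200 triangular solves plus bilinear sampling). The
replicate tables are 8 patients × 3 measurements, their published scale.
Ties and degenerate inputs: constant images yield zero external energy
(the snake then shrinks under internal energy alone); zero-variance
replicate tables, zero-mean CVs and zero-variance correlations raise
`ValueError` rather than returning NaN.

## Known limitations

* The HU band cannot separate fibrosis from other processes with similar
  attenuation, and its 60–90 HU calibration is not reproducible from first
  principles here.
* The rectangular-ROI denominator includes non-cardiac pixels; percentages
  are therefore sensitive to how far the evolved contour overshoots the
  heart.
* The automatic initialiser is not the manual placement used in the
  original protocol; with few iterations the result depends measurably on
  the initial ellipse.
* Single-slice processing only: no volume reconstruction, no contrast
  phases, no multi-chamber segmentation.
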