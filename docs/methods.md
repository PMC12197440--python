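# Methods

This note documents the models, conventions and design decisions behind
`tlcdens`: what each stage computes, which knobs matter, what the synthetic
plate generator does and does not emulate, and the known limitations.

## Imaging model

A developed silica F254 plate photographed under short-wave UV shows the
analyte as a dark quench spot on a bright green fluorescent background. The
densitometric assumption is that the locally *missing* green intensity,
integrated over the spot, is proportional to the amount of analyte: with a
quench depth `a` and an approximately Gaussian spot profile of spatial scale
`σs`, the integrated signal is `2π·a·σs²`, linear in `a` and hence — over the
assay's working range — linear in concentration. The calibration intercept
absorbs any uniform baseline offset.

## Detection chain

Input is an 8-bit RGB photograph plus the geometry tying pixel rows to the
chromatographic axes: the origin (application) line at the crop's bottom
boundary row, the solvent front at its top row. Coordinates are 0-based,
row-major, row 0 at the top, rectangles half-open.

1. **Resampling.** The crop is resampled to `standard_height` rows
   (default 400), preserving aspect ratio, because summed-intensity AUC units
   scale with pixel area — calibrations are only transferable between images
   processed at the same scale.
2. **Green channel**, scaled to [0, 1] by /255.
3. **Inversion + min-max normalization**: `out = (max − v)/(max − min)`, so
   quench spots become high signal with range exactly [0, 1]. A constant
   image maps to zeros with a warning rather than dividing by zero.
4. **Gaussian blur**, separable 5×5. With `sigma = 0` the width-derived
   value `σ = 0.3·((k−1)/2 − 1) + 0.8` is used (1.1 for k = 5), the kernel
   being a sampled, sum-normalized Gaussian; borders are mirror-reflected.
5. **Grayscale dilation**, a moving-window maximum over a 16×16 rectangle
   with replicated borders. An even kernel has no center pixel; the window
   spans offsets [−8, +7] around the anchor. Dilation inflates each spot
   into a near-peak plateau, which stabilizes the subsequent threshold and
   widens contours enough to capture spot tails.
6. **Threshold** (inclusive: mask = 1 where signal ≥ t), by default on the
   dilated image. Three methods:
   - `background` (default): robust sigma-clipping,
     `t = median + k·1.4826·MAD` with `k = 6`, floored at 4 quantization
     steps when the MAD collapses on effectively noiseless images. The
     median/MAD of a mostly-background plate estimate the background level
     and noise irrespective of how many spots are present or how bright they
     are, so a faint spot next to a strong one survives.
   - `otsu`: exhaustive maximization of between-class variance over 256
     evenly spaced candidates on [0, 1], ties to the smallest threshold
     (verified against a brute-force oracle). Otsu's two-class criterion is
     the right tool when all spots have comparable intensity, but on a
     calibration ladder spanning a 0.5–4 mg/mL amplitude range it places the
     threshold above the faintest spots — measured here as the reason it is
     not the default. Li's minimum-cross-entropy method was also evaluated
     and produced background false positives on spot-free plates.
   - `fixed`: a user-supplied threshold on the [0, 1] scale.
7. **Contours.** 8-connected foreground components; components whose filled
   area is below `min_spot_area` (50 px at 400 rows, scaling with
   (height/400)²) are discarded as noise. The centroid is the image-moment
   center of the filled component; the bounding box is tight; spots are
   returned sorted by centroid column, then row.
8. **AUC.** Summed over the filled component on the *pre-blur*
   inverted-normalized image, so smoothing/dilation shape only the detection
   mask, never the quantified signal. No background subtraction by default —
   a uniform baseline is absorbed by the calibration intercept. An optional
   annular mode subtracts the median signal of a rectangular ring
   (margin 6 px) around each spot times its area; this matters when the
   fitted *slope* itself must be compared across imaging conditions, because
   the uncorrected baseline contribution grows with spot area and inflates
   the slope (measured: ≈ +20% at pixel noise sd 0.01 uncorrected, ≈ +0.5%
   with annular correction).

The chain is fully deterministic: identical bytes and config produce
identical spot lists.

## Chromatography

`Rf = (origin_row − centroid_row)/(origin_row − front_row)`, computed from
the moment centroid (not the bounding-box center), carried at full precision
and rounded to 2 decimals only in reports. Lanes are formed by 1-D
single-linkage clustering of centroid columns: a new lane starts when the
gap to the previous sorted centroid exceeds a threshold (default crop width
/ (2 × expected lanes)). The principal spot of a lane is the one with the
largest AUC (ties: larger area, then nearer the solvent front). Identity:
`|Rf_sample − Rf_standard| / Rf_standard ≤ 0.10`, boundary inclusive. The
tolerance is relative rather than absolute in Rf units; for standards near
Rf 0.6 the two readings differ negligibly.

## Quantitation

Ordinary least squares of AUC on concentration (≥ 3 distinct levels);
`Sy = sqrt(SSE/(n−2))`; `LoD = 3.3·Sy/S`, `LoQ = 10·Sy/S` (so LoQ/LoD is
10/3.3 by construction). Inverse prediction `c = (AUC − b)/S`; outside the
calibrated range the policy is to warn and extrapolate or to reject;
negative estimates are clamped to zero with a warning. Quantitation
proceeds with a warning (rather than refusing) below LoQ, since screening
samples are prepared at a working concentration well inside the linear
range. API content per tablet is `c × dilution_factor_ml` (default 125 mL,
reconstructing one tablet dissolved in 25 mL followed by a 5× dilution to a
4 mg/mL working solution); the pharmacopeial band is
`label_claim·(1 ± 0.10)`, boundaries inclusive, 450–550 mg for the default
500 mg claim. Verdicts: `pass` iff identity and content both pass;
otherwise `identity_fail` (which takes precedence), `out_of_calibration`
(reject policy), or `substandard_content`.

A published calibration line can be loaded from a model file instead of
being fitted — calibration is data, not code.

## QC statistics

CV = 100·σ/μ with the sample (n−1) standard deviation; undefined for zero
mean. Recovery is per-replicate `100·measured/spiked` with mean ± sample sd.
Method agreement is a one-way fixed-effects ANOVA over two groups
(equivalent to a pooled two-sample t-test); when both groups have zero
within-group variance, F is defined as 0 (p = 1) for equal means and +inf
(p = 0) otherwise.

## Synthetic plates

The generator emulates UV-quench imaging: green channel = background −
Σ Gaussian quench spots + linear illumination gradient + Gaussian pixel
noise, clipped to [0, 1] and quantized to 8 bits *before* analysis, so tests
exercise the same precision regime as photographs. Red/blue carry a low
constant. Rendering is byte-deterministic given the seed. The manifest
records each spot's true centroid, Rf, and analytic AUC `2π·a·σs²` both in
raw green units and divided by the rendered image's min-max range — i.e. in
the units the pipeline's normalized signal reports.

Defaults, chosen once as realistic study conditions: 400-row development
region (the pipeline's standard height), background at 0.85 of full scale,
pixel noise sd 0.005 (≈ 1.3 of 255 counts), spot σs = 6 px, lanes 56 px
apart. Assay layouts map concentration levels to amplitudes through
`analytic AUC = gain·level + baseline` with gain 30 and baseline 21 raw-AUC
units — a baseline-to-gain ratio of 0.7 mg/mL-equivalents, matching the
positive intercepts real densitometric calibrations show. Levels span
0.5–4 mg/mL, the assay's linear range, with samples near the 4 mg/mL
working concentration.

Assay plates carry the standard ladder *and* the sample lanes on one image,
as in the bench workflow of spotting standards beside unknowns. This is
load-bearing: the min-max normalization scale is a whole-image quantity, so
same-plate calibration makes it cancel exactly between standards and
samples. Cross-plate model reuse works only when both plates contain the
same dynamic range (e.g. both include the top standard); this mirrors the
real-world caveat that densitometric calibrations are tied to imaging
conditions.

Not emulated: perspective/lens distortion, JPEG artifacts, spot tailing and
band broadening with migration (available but off), bleed between close
lanes, plate texture, or sensor nonlinearity. Passing tests therefore
demonstrate the correctness of the *analysis* under controlled optics, not
robustness to every field photograph.

## Validation problem sizes

The acceptance run uses 100 rendered assay plates (ladder + one random
sample lane at 1–4 mg/mL, Rf 0.55–0.65, amplitude/noise ≥ 5) for end-to-end
recovery, 500 Monte-Carlo refits of a six-level noisy calibration for slope
bias, 60 rendered ladders for pipeline-level slope recovery (annular mode),
and 10 random 64×64 images each for the dilation and Otsu brute-force
oracle equivalences. Measured outcomes: Rf recovered within ±0.002,
concentration within ±5% (typically ±3%), slope bias below 0.1%
(statistical) and ≈ 0.5% (pipeline), oracle residuals exactly zero.

## Known limitations

- AUC units are arbitrary and tied to the resampled scale and normalization;
  only same-conditions comparisons are meaningful.
- The 10% relative Rf rule and inclusive pharmacopeial boundaries are
  screening conventions, not assay-specific statistics; no measurement
  uncertainty is propagated into the verdict.
- Global thresholding (any method) assumes reasonably uniform illumination;
  severe gradients raise the background estimate and can suppress faint
  spots. No flat-field correction is attempted.
- Lane assignment is 1-D and assumes visibly separated lanes; overlapping
  lanes are merged.
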