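# Methods

This note documents the models, parameter choices and numerical decisions in
`chartcal`, and what the synthetic validation does and does not show.

## Colorimetry

All conversions use the 2° standard observer with the D65 white point
(X, Y, Z) = (0.95047, 1, 1.08883). The linear-sRGB↔XYZ matrix is derived at
import time from the sRGB primaries and the white point (not typed in as
rounded constants), so the matrix and its inverse are consistent to machine
precision. Colour difference is CIE76 dE\*ab — the plain Euclidean distance
in CIELAB; CIEDE2000 is deliberately not used, since the evaluation
statistics are defined on the Euclidean metric. Out-of-gamut linear values
are preserved through all internal computation and clipped only when
encoding to 8-bit sRGB, so least-squares fits are not biased by premature
clipping.

## Reference chart data

`src/chartcal/data/colorchecker24_d65.csv` ships the 24 patch L\*a\*b\*
values (D65/2°), frozen from the chart's widely published nominal sRGB
coordinates through a reference conversion (scikit-image). The grayscale
wedge is idealised to exact neutrality (a\* = b\* = 0): the chart's wedge is
spectrally flat by design, and an off-neutral grayscale reference would
contradict the tone-curve model's premise that those patches excite all
channels equally. The file is the single source of truth; sRGB values are
re-derived from Lab at load time and the loader enforces structural
invariants (24 unique indices, strictly decreasing wedge luminance,
near-zero wedge chroma). Every shipped patch survives the
Lab→linear→8-bit→Lab round trip within 0.5 dE, i.e. the dataset is in-gamut;
charts/editions with saturated cyans outside sRGB would be flagged by this
check at load time.

## Chart detection

* **Bright-region threshold** (default 230 on the per-pixel minimum
  channel): if no candidate passes all gates, the threshold relaxes in steps
  of 30 down to 140 and the search repeats. A fixed threshold cannot serve
  both correctly exposed and deliberately under-exposed images (at −1 EV a
  white patch encodes near 177); the relaxation schedule keeps the search
  deterministic.
* **Shape filter**: fill ratio = area / minimum-area-rectangle area ≥ 0.85
  (computed by rotating calipers over the component's convex hull), patch
  area within [0.005 %, 2 %] of the image. Candidate order: descending fill
  ratio, then descending area, then scanline position — fully deterministic.
* **Black partner**: probed five patch pitches from the white candidate
  along both rectangle side directions and their negatives. "Dark" is
  *relative*: maximum channel ≤ 0.35 × the white candidate's mean level. An
  absolute threshold fails at exposure extremes (an overexposed black patch
  encodes ~74 while remaining the darkest object in the frame).
* **Grid**: the white and black centres fix the grayscale-row axis; the two
  perpendicular side hypotheses (normal vs mirrored chart) are ranked by a
  colour-diversity score (mean pairwise distance of the 18 non-grayscale
  patch means — background yields near zero, and hypotheses under a floor of
  20 are rejected outright) and confirmed by the calibration quality gate.
  The grayscale row must decrease from white to black; steps may be flat
  within 2 code values because overexposure clips the brightest wedge
  patches to a common level, and the row must drop ≥ 20 codes overall.
* **Sub-pixel refinement**: the black-patch landmark is imprecise (it merges
  with the chart's dark frame), so the initial grid is refined twice by
  re-centring each patch at the centroid of the pixels in its cell matching
  the patch's central colour (RGB distance ≤ 25; frame gaps do not match)
  and refitting the affine map by least squares. On rendered ground truth
  this lands within ~0.01 px; the acceptance check requires < 1 px.
* **Sampling**: central 50 % of each cell, half-open integer windows, ≥ 25
  pixels. Saturation: channel mean > 255 − δ or < δ with δ = 3; default
  acceptance cap 5 saturated patches ("fewer than 6 of 24").

## Calibration

* **Tone curves**: one per channel, anchored at (mean device code,
  reference relative luminance Y) over the proper grayscale patches (≥ 4
  required) plus (0, 0). Y is CIE relative luminance (perfect diffuser = 1;
  the chart's white is ≈ 0.90, not 1). Interpolation is monotone PCHIP in
  log–log coordinates — exact for any pure gamma response and a close fit
  to sRGB-style curves; below the darkest anchor the curve continues as the
  power law through the origin matching that anchor's local log–log slope,
  and above the brightest anchor it clamps. Codes outside the anchored range
  are therefore extrapolations: the chart simply carries no information
  there, and tests assert LUT accuracy on the anchored range only.
* **Polynomial**: ordinary least squares from the LUT-linearised device
  triples to the reference linear-sRGB triples. Degree 1 (affine with
  offset, 4 terms) is the default — robust for 12–24 fit points; degree 2
  (10 terms) is available behind a minimum-patch precondition
  (≥ max(10, terms) proper patches). The fit space is linear sRGB: one
  colour-space transformation, no intermediate profile connection space.
  No chromatic adaptation step: illuminant mismatch is absorbed by the
  LUTs and the polynomial.
* **Quality gate**: pass requires median dE over fit patches ≤ 10 and over
  proper held-out patches (when any) ≤ 15. The gate is the callback given to
  detection, so a geometrically plausible but colorimetrically wrong
  candidate (e.g. the mirrored side hypothesis) sends the search onward.
* **Split-half accuracy**: the polynomial fits on patches 13–24 (the half
  containing the full grayscale wedge — the other split would leave the
  tone-curve fit under-determined) and accuracy is scored on patches 1–12.
  The split is configurable.

## Synthetic camera and scenes

The generator emulates studio acquisition of the chart on a grey background
under a factorial condition grid, and hand-held wound photography. It is a
flat-patch renderer, not a physically based one: uniform illumination, no
lens falloff, no demosaicing, no JPEG artefacts (a JPEG-robustness test
re-encodes losslessly rendered scenes at quality 90).

* **Illuminants** as per-channel linear scalings of scene colours relative
  to D65: TL84 ≈ (1.10, 1, 0.85), A ≈ (1.25, 1, 0.65) — chosen to match the
  qualitative casts of cool-white fluorescent (~4000 K) and tungsten
  (~2856 K); a spectral model is unnecessary to exercise the algorithm.
* **White balance** acts on the sensor channels before colour mixing.
  "Correct" uses the camera's discrete per-illuminant preset, close to but
  not exactly the tint inverse (a small residual cast remains, as with real
  presets); "mismatched" is a fixed cool preset (0.75, 1, 1.30) matching
  none of the three cabinet lights, so every grid cell is a genuinely
  distinct condition.
* **Default camera**: mild non-diagonal 3×3 channel mixing, encoding gamma
  1.8 (a contrasty in-camera JPEG curve, deliberately different from the
  sRGB curve so that even "normal" images need calibration), additive
  Gaussian noise of sd 2 code values (sd 1 for the identity-camera
  detection scenes), 8-bit clipping and quantisation. `CameraModel.identity`
  encodes exactly as sRGB for identity-recovery tests.
* **Condition grid**: 3 illuminants × {−1, 0, +1} EV × {correct,
  mismatched} WB = 18 cells; "normal" = 0 EV with correct WB. The ±1 EV and
  wrong-WB cells saturate up to ~10 patches; the experiment-1 configuration
  therefore raises the saturation cap to 14 (the clinical default stays 5),
  mirroring the original protocol in which heavily saturated stress images
  were still calibrated from their surviving proper patches.
* **Wound scenes**: a mottled ellipse (base colour L\*=48, a\*=32, b\*=18 —
  a desaturated red defined in Lab and converted through the colorimetry
  module), low-frequency multiplicative mottling (amplitude 0.15) from a
  seeded 8×8 noise grid, a rectangular ROI polygon inscribed in the
  ellipse, chart placed in the upper image half with a small random
  rotation (±4°), illuminant drawn per scene. 40 scenes per batch, matching
  the original sample size.

All randomness flows from explicit seeds through `numpy.random.default_rng`
(PCG64); identical seeds give bit-identical renders.

## Statistics

* **Pairwise precision**: all n(n−1)/2 pairs per patch; a pair counts only
  if the patch is included (e.g. proper) in both images.
* **Tukey five-number summary**: quartiles by exclusive median-of-halves
  (Moore–McCabe; the middle value is excluded from both halves when n is
  odd) — conventions differ, so this is stated explicitly; outliers beyond
  1.5·IQR from the quartiles.
* **Wilcoxon rank-sum**: midranks for ties; exact two-sided p by full
  enumeration of label assignments when the combined n ≤ 12, otherwise a
  normal approximation with tie correction and 0.5 continuity correction.
* **ECDF dominance**: strict every-point dominance by default; the
  experiment-level check uses the one-sided Kolmogorov–Smirnov form at
  α = 0.05 (the worst violation must be below KS sampling noise), since
  with thousands of pairwise values the literal minimum of either sample is
  a coin flip.
* **Rotation reproducibility**: each rotation is an *independent* run of
  detection and calibration; the ROI polygon is transformed exactly (90°
  multiples only), and ROI means are averaged in Lab after per-pixel
  conversion.

## Problem sizes and determinism

Default scenes are 640×480 with 40 px patches — large enough for ≥ 400-pixel
sampling windows, small enough that the full validation suite (18-cell grid
plus 40 wound scenes × 4 rotations) completes in well under a minute. The
acceptance script derives all seeds from its `--seed` argument.

## What passing tests do and do not show

The simulator covers the failure modes the algorithm is designed for
(exposure error, white-balance error, illuminant colour, sensor noise,
channel clipping, chart rotation/mirroring/scale, decoy bright objects). It
does not cover perspective distortion (the grid is affine; strongly oblique
charts are out of scope), non-uniform illumination across the frame (the
method assumes uniformity), demosaicing or JPEG artefacts beyond a
quality-90 re-encode, or the spectral metamerism of real camera sensitivity
curves. Quantitative results on synthetic scenes (e.g. rotation-induced ROI
variability ≈ 0.03 dE median) are accordingly cleaner than the sub-1-dE
figures achievable on real photographs; the validation claims are
directional and structural, not magnitudes transferable to any particular
camera.

## Known limitations

* Tone curves are extrapolated below the black patch and clamped above the
  white patch; shadow regions darker than the chart's black are mapped by a
  power-law guess.
* The affine grid assumes a near-frontal chart.
* Degree-2 polynomial fits can overfit with few proper patches; the
  precondition guards the count but not the conditioning of extreme inputs.
* A single chart per image is assumed; with several, the first candidate
  passing all gates wins deterministically.
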