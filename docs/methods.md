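# Methods

## The measurement model

`discsig` treats a lumbar intervertebral disc on a sagittal T2-weighted
slice as a bright nucleus zone embedded in a darker annulus. All
quantities are computed on the segmented nucleus mask in a disc-aligned
coordinate frame:

* the **longitudinal axis** u is the major principal axis of the binary
  mask's second central moment matrix, computed in millimetre
  coordinates (pixel-centre convention: pixel (r, c) sits at
  ((c+0.5)·colspacing, (r+0.5)·rowspacing)); the perpendicular axis v is
  its +90° rotation. u is oriented to have a positive image-x component
  (anterior ≈ +x in standard sagittal display), ties broken toward +y,
  and the reported angle lies in (−90°, 90°].
* the **origin** is the posterior-most masked projection onto u, on the
  line through the mask centroid, so longitudinal positions span
  [0, nucleus length]. A *manual* frame built from two endplate-line
  points keeps the first point as origin instead; positions are then
  measured from that point and PSM values from repeated measurements of
  the same disc (or from phantoms sharing one disc geometry) become
  directly comparable even when the nucleus moves.
* with masked pixel coordinates X_i and intensities S_i, the weighted
  centre is X̄ = Σ X_i S_i / Σ S_i; **DX** is |(X̄ − X̄_geom)·u| with
  X̄_geom the unweighted mean of masked pixel centres (the S_i ≡ 1 case
  of the same formula). The signed value is retained in the output.
* the **profile** S(t) sums masked intensities per longitudinal bin;
  **SM** = max S(t), **PSM** = argmax position, ties broken to the
  smallest (posterior-most) position and flagged in the provenance.
  Sums are restricted to masked pixels: including annulus columns would
  contaminate SM.
* **H** is the maximum column-wise perpendicular mask extent
  ((max − min + 1 rows)·spacing). An alternative `h_mode="center"`
  reads the extent at the column nearest the geometric centre, because
  "height" admits both readings; the maximal extent is the default.

## Segmentation

The nucleus is grown from a single user seed over 8-connected pixels
whose intensity reaches `threshold_fraction` (default 0.5) of a robust
seed reference — the median of the seed's 3×3 neighbourhood, which a
single noisy pixel cannot corrupt. The seed's component is closed with a
1-pixel disk, hole-filled, and re-reduced to the seed's component. Every
setting, the reference intensity and a border-leak flag (region touching
the image border, signalling failed containment) are recorded in the mask
provenance. Region growing, closing, hole filling and component
selection are all increasing set operators, so raising the threshold
fraction can never enlarge the final mask — a property the tests hold on
every image. A polygon fallback rasterises a hand-drawn outline by
pixel-centre inclusion for the manual-outline workflow.

## Frame rebinning

Slice and mask are moved into the disc frame by conservative forward
deposition: every masked source pixel adds its full intensity to the
frame bin nearest its centre's (t, w) coordinates, with isotropic bin
width s = min(input spacings). Bins are anchored so that an axis-aligned
frame reproduces the original raster exactly (the longitudinal anchor is
the origin, itself a projected pixel centre; the perpendicular anchor is
the lowest masked projection). Deposition preserves the masked intensity
total exactly at any rotation and anisotropy, so the profile sums — and
hence SM and PSM — computed downstream equal the brute-force reference
values to rounding error. Backward interpolation (bilinear intensity +
nearest-neighbour mask) was evaluated and rejected: its per-column
aliasing jitter is on the order of one pixel-row of intensity, which is
larger than the sub-pixel agreement the profile metrics are held to.
The cost is a blocky aligned raster (bins may receive 0 or 2 pixels);
since every parameter is an aggregate over the mask, this does not
affect the metrology.

## Phantoms and ground truth

A phantom is background + elliptical disc (annulus intensity) + contained
elliptical nucleus (nucleus intensity, optionally with a linear
longitudinal gradient anchored at the nucleus centre, so a translated
nucleus carries its pattern rigidly). Rasterisation uses the
pixel-centre rule; Gaussian noise (sd `noise_sigma`, clipped at zero — a
reasonable high-SNR approximation of magnitude-image noise) is added
last. Defaults: 512×512 matrix at 0.625 mm/px (a 320 mm field of view),
disc 20×5 mm semi-axes, nucleus 10×3.5 mm, intensities 70/12/3
(nucleus/annulus/background). The intensity scale is arbitrary — chosen
so SM lands in the 500–1300 range typical of reported cohorts — and the
disc geometry puts the nucleus height near 7–9 mm.

Ground truth is computed on the rasterised *noiseless* image by a
brute-force oracle written as explicit pixel loops with a closed-form
2×2 eigen-decomposition, sharing no code with the pipeline modules; truth
and pipeline therefore see the same discrete object, and rasterisation
shifts affect both identically. Tests (and `scripts/acceptance.py`)
compare pipeline metrics, given the true mask and frame, against the
oracle on dozens of randomised phantoms: DX/H/PSM agree within one pixel
spacing and SM to rounding error, at orientations up to ±60°.

Tests run most phantoms on a 160×160 canvas at the same 0.625 mm
resolution — the disc occupies identical pixels, only empty background is
trimmed — and cohorts render at 256×256.

### The flat-top plateau

With exactly uniform nucleus intensity the discrete profile has a
plateau around the centre (the rasterised chord height is quantised to
whole pixels), several pixels wide; the tie rule then reports PSM at the
plateau's *posterior edge*, not at the continuous peak. Weak gradients
tilt, but do not dominate, the plateau, so under noise PSM can jitter
across it. This is a genuine property of the estimator on
near-symmetric objects, visible only on phantoms; real degenerated
nuclei have decisively asymmetric profiles. Offset-recovery experiments
therefore compare PSM *differences* between phantoms of identical
nucleus geometry measured in one fixed manual frame, where the plateau
bias cancels exactly.

## Cohort effect model

`EffectModel` draws per-subject nucleus parameters around per-cell means
for a two-pathology (spondylolisthesis, scoliosis) × three-severity
factorial. Default cell means are calibrated so the closed-form metrics
of the means land near published cohort values: scoliotic nuclei longer
(longitudinal semi-axis ~12–15 mm vs ~6–10 mm) and brighter; severity
shortens the nucleus in both pathologies and flattens it in
spondylolisthesis. The intensity gradient is drawn with zero mean
(parametrised by the profile-peak shift τ, sd 1.5 mm; DX ≈ |τ|/4), so
**no factor effect is injected into DX** — matching the expectation that
DX does not discriminate these groups. Between-subject sds (length
1.0 mm, height 0.35 mm, intensity 10, offset 0.5 mm) were chosen once to
give realistic cell SEs at n ≈ 10–15; draws are truncated to keep every
subject's phantom geometrically valid and segmentable.

Because the phantom couples SM to nucleus height × intensity, the
simulated cohort's SM also varies somewhat with severity; the package
asserts the *detected* pattern (pathology on SM, both factors on PSM),
not the non-detections a smaller and noisier clinical cohort shows.

ANOVA type-I-error and power simulations draw cohorts at the **metric
level**: the same subject-parameter draws mapped through noiseless
closed forms (PSM = a + τ, H = 2b, SM = I·chord(τ)/s, DX = |τ|/4),
skipping image rendering. This is what makes 1000-replication operating
characteristic estimates cheap; the image pipeline itself is exercised
end-to-end on a smaller rendered cohort. The closed forms are first-order
(they ignore the plateau effect above), which is immaterial for the
ANOVA's operating characteristics since every replication uses the same
mapping.

## Statistics

* Repeat SDs are sample standard deviations (n−1), pooled over all
  repeats and per observer; SM is expressed as a percent coefficient of
  variation because its units are scanner-arbitrary.
* The two-way ANOVA is a fixed-effects OLS fit with sum-to-zero
  contrasts and Type III sums of squares — the convention classical
  biostatistics packages default to, and the one that keeps main-effect
  tests meaningful in unbalanced designs. The interaction is estimated
  but reported as supplementary; it is dropped (with a warning) when a
  factorial cell is empty, and a zero-residual-variance design yields
  NaN statistics with a warning rather than a spurious rejection.
* Severity is treated as categorical (three levels), not an ordinal
  trend. Discs within a patient are treated as independent records; a
  mixed model for within-patient correlation is out of scope and noted
  as a limitation.
* No multiple-testing correction is applied across the four parameters.

## What the phantoms do and do not show

Phantoms emulate geometry, contrast, a longitudinal intensity gradient
and additive noise. They do not emulate annulus texture, endplate
signal, partial-volume fading at the nucleus boundary, bias fields, or
wedged disc shapes — so passing tests demonstrate the correctness and
stability of the *computations*, not clinical segmentation robustness.
The sagittal plane is also not the maximum-deformation plane for
scoliosis; like the measurement it models, the package makes no attempt
to correct out-of-plane obliquity.
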