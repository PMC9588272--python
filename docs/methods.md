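# Methods

## Measurement model

Systematic MRI geometric distortion displaces imaged structure from its
true position. Writing the true (CT-reference) position as x and the
distorted MR position as x + u(x), the goal is to estimate u at a set of
rigid phantom markers and report ‖u‖ as a function of the 3D distance
r = ‖x − isocenter‖. The estimate is obtained by deformable registration:
the MR is registered to the CT, and the resulting field — defined on the
fixed (CT) grid so that the MR is read at x + u(x) — *is* the measured
distortion. This sign convention is used consistently everywhere: the
per-marker distortion vector is the field sampled at the marker's
fixed-space centroid.

Assumptions inherited from the measurement principle:

* the phantom is rigid and its CT geometry is truth (CT scanner distortion
  is negligible at this scale);
* distortion is minimal at the magnet isocenter, where the rigid
  pre-alignment is anchored;
* the phantom has negligible magnetic susceptibility, so the measured B0
  term reflects the scanner, not the object.

## Coordinate conventions

All physical quantities are world millimetres. The internal world frame is
the NIfTI (RAS) convention; DICOM (LPS) geometry is converted on read.
Voxel (i,j,k) sits at `origin + direction @ (spacing * (i,j,k))`. The
isocenter defaults to the volume's geometric center (phantoms are
laser-centered in practice) and is overridable everywhere. Synthetic
volumes place the volume center at world (0,0,0).

## Synthetic phantom simulator

The simulator emulates the class of large cylindrical grid phantoms used
for distortion QA: a fluid-filled cylinder (default 360 mm diameter ×
360 mm length) with a regular 3D grid of bright markers (default 7×7×7 at
40 mm pitch, 8 mm sphere radius) and an outer housing shell (8 mm) that is
visible on CT only. Default rasterisation is 96³ voxels at 4 mm. These
defaults are one fixed choice of a realistic desk-scale configuration —
commercial phantoms of this class are of comparable outer size but do not
publish a canonical grid pitch — and all of them are configurable.

* **Rasterisation.** Voxels near any analytic surface (|signed distance| ≤
  0.75·‖spacing‖) are 3×3×3 supersampled and averaged, giving
  partial-volume edges and sub-voxel centroid fidelity (rasterised
  centroids match analytic positions to ≪ 0.25 voxel). Marker radius
  should be ≥ 2 voxels: the 1-voxel morphological opening used in marker
  detection erodes smaller markers under noise.
* **Distortion model.** A smooth parametric field: a radial polynomial
  with odd orders, u_r(r) = c1·r + c3·r³ + c5·r⁵, directed radially
  (the gradient-nonlinearity signature: zero at isocenter, growing
  outward), plus a B0-like term b0_amplitude·(r/100 mm)² along the
  frequency-encode axis that flips sign under polarity reversal. With
  `zero_at_isocenter` (default) the field vanishes at the isocenter.
* **Warp application.** The MR is resampled through the warp by inverse
  mapping: for each MR voxel position y the undistorted source x solving
  y = x + u(x) is found by fixed-point iteration (tolerance 0.01 mm,
  ≤ 50 iterations — the warps of interest are small and smooth, so this
  converges in a few steps), and the analytic phantom is evaluated at x.
  Forward splatting would leave holes; inverse mapping is exact here
  because the phantom is analytic.
* **Noise.** MR noise is Rician, approximated as the magnitude of complex
  Gaussian noise; CT gets additive Gaussian noise. Both are seeded; all
  outputs are pure functions of (spec, model, shape, spacing, seed).

What the simulator does **not** emulate: susceptibility artefacts,
chemical shift, coil-sensitivity shading, pulse-sequence contrast, CT
beam-hardening. Passing tests therefore demonstrate the correctness of
the *pipeline* (registration, sampling, statistics, residual logic) under
known geometry, not robustness to every real-world image imperfection.

## Housing masking

The phantom housing is visible on CT but not MR; left in place it drags
the registration at the rim ("false deformable registration"). Two
strategies: an intensity band replaced by background, and
`erode_body_outline`, which erodes the filled body outline and zeroes
foreground outside it. The band must be chosen to include the housing's
partial-volume shell, whose intensities ramp from background to the
housing level — residual shell voxels measurably bias the rim (this is
tested as a direction-of-effect comparison). The erosion strategy removes
the shell by construction and is what the synthetic pipeline uses
(erosion = housing thickness + 2 voxels).

## Deformable registration

Cubic B-spline free-form deformation on a regular control lattice aligned
with the fixed image axes, covering the volume with one extra cell of
margin. Default control-point spacing is 5× the largest voxel spacing
(20 mm at the default grid); spacing must exceed the voxel size. The
similarity term (masked to the phantom body when a mask is given) is SSD
on min–max-normalised intensities (default; full-range normalisation is
deliberate — markers occupy < 1 % of voxels and percentile scaling would
clip away their contrast) or negative NCC; both have analytic gradients
propagated to the control coefficients through the separable B-spline
tensor. NMI (Mattes) is available through the SimpleITK driver, which
implements the same field contract.

Regularisation is a bending-energy penalty: the mean squared second
difference (plus doubled mixed differences) of the control coefficients,
in mm². It is kept in coefficient units rather than divided by the
control spacing so that the default weight (10⁻³) is commensurate with
the normalised similarity term across lattice resolutions; it suppresses
the wild solutions otherwise available in textureless regions. The
optimised bending energy is exposed as `field.meta["bending_energy"]` and
is non-increasing in the weight (the exact-minimiser monotonicity
argument, verified empirically).

Optimisation is L-BFGS-B with analytic gradients over an image pyramid
(default 3 levels, smooth-and-subsample by 2; the control lattice is fixed
in world space so coefficients carry across levels). There is no
stochastic metric sampling: repeated runs are bit-identical. Iterations
default to 100 per level with relative metric tolerance 10⁻⁶.

Capture limit: warps whose magnitude approaches ~¼ of the control spacing
within one cell cannot be represented and are under-recovered — central
accuracy with peripheral underestimation is the expected failure mode,
and is exactly what the residual pass detects.

The rigid pre-alignment utility optimises a bounded Euler transform
(±10°, ±25 mm) with Powell over the central third of the volume, where
distortion is minimal. The bounds matter: a regular marker grid has
period- and rotation-symmetric false optima that an unbounded central
metric cannot distinguish. When optimisation does not meaningfully improve
on the identity metric (< 5 % relative), the identity is returned with a
warning — the images are either already aligned or mis-locked by a full
grid period, and the operator must verify which.

## Distortion analysis

Markers are segmented on the MR by Otsu (default), fixed or percentile
threshold, followed by a 1-voxel binary opening; empty masks and masks
covering > 50 % of the body are rejected as pathological. Components are
labelled with 26-connectivity; intensity-weighted centroids are computed
in world mm; undersized components are discarded and oversized ones
(> 3× median volume) trigger a merged-marker warning.

The field is sampled (trilinear) at fixed-space centroids — the CT is the
geometry reference. Magnitude is the Euclidean norm; radial distance is
3D Euclidean (an in-plane option exists). Statistics use half-open radial
annuli [0,100), [100,200), [200,∞) mm — a marker at exactly 100 mm falls
in the second bin — plus cumulative within-R statistics (default
R = 150 mm). Quantiles use linear interpolation between order statistics
(the numpy default), applied uniformly. Histograms use fixed 0.25 mm
magnitude bins. Constancy checks compare per-bin statistics against a
baseline report by absolute difference with per-statistic tolerances;
reports embed the configuration hash so only like-for-like runs compare.

## Residual validation and the reliable radius

The deformed MR from the first pass is registered to the CT again with
the same contract. Residual displacement marks under-recovery. Markers are
grouped into radial shells (default 10 mm; 25 mm in the validation suites
so every shell of the 7×7×7 grid is populated); scanning outward from the
isocenter, the reliable radius is the outer edge of the last contiguous
shell in which ≥ 95 % of markers have residual ≤ tolerance (default: half
the voxel diagonal, below which residuals are indistinguishable from
interpolation noise). Empty shells give no evidence and do not stop the
scan; the radius is capped at the outermost populated shell. The 95 %
rule, shell width and tolerance are this package's operational definition
of "reliably detected" — the underlying criterion is not standardised —
and all three are recorded in the report.

## Component separation

For two fields acquired with reversed frequency-encode polarity,
g = (u₊ + u₋)/2 and b = (u₊ − u₋)/2 separate the polarity-even
(gradient-nonlinearity) and polarity-odd (B0) parts. Separation happens at
the field level so both field- and marker-level outputs exist.
Reconstruction g ± b reproduces the inputs to floating-point rounding
(1 ulp). The B0 part should live on the frequency-encode axis; its
off-axis RMS is reported as a diagnostic of acquisition consistency.

## Validation-suite conditions

The acceptance script and suite run at a fixed desk-scale configuration:
default phantom, 96³ × 4 mm volumes, cubic warp with 4 mm (recovery) or
6 mm (residual suite) at r = 150 mm, MR noise sigma 20 (SNR 50 at marker
intensity; the residual suite is noise-free because its measured quantity
is a shell boundary that tolerance-level noise would blur), a deliberately
coarse first pass (90 mm control points, 25 iterations) for the residual
suite, and a 48³ small-phantom variant for separation and determinism
runs. Expected behaviour, all computed at run
time: identity registrations report < 0.2 mm; recovery RMS error within
r ≤ 150 mm is below half a voxel; the residual-based reliable radius lands
within one shell width of the radius where true first-pass errors cross
the tolerance; separated components match the simulator within the
registration error budget.

## Known limitations

* Registration accuracy is only demonstrated for smooth synthetic warps on
  noise levels the simulator produces; real scanner data adds artefacts
  the simulator does not model.
* The builtin optimiser assumes the two volumes are rigidly pre-aligned
  (or alignable by the small-correction utility); gross misalignment is
  out of contract.
* No diffeomorphic or inverse-consistency guarantees; fields at the
  capture limit fold before they fail loudly — the residual pass, not the
  first pass, is the guard.
* Reported "distortion" at non-marker voxels is interpolation, not
  measurement; only marker positions carry evidence.
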