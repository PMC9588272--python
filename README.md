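# gridwarp-qa

Vendor-neutral quantification of systematic MRI geometric distortion for
radiotherapy quality assurance.

MR images used for radiotherapy treatment planning are spatially distorted
by B0-field inhomogeneity and gradient-field nonlinearity; the distortion
grows with distance from the scanner isocenter and must be measured at
commissioning and monitored over time. `gridwarp-qa` measures it with any
rigid CT/MR-compatible phantom containing markers visible on both
modalities:

1. the phantom MR is deformably registered to its CT reference with a
   cubic B-spline free-form deformation (control-point lattice, SSD/NCC/NMI
   similarity, bending-energy regularisation, deterministic L-BFGS-B
   optimisation), producing a dense deformation field **u(x)** in mm —
   the measured distortion;
2. markers are segmented on the MR by thresholding, and **u** is sampled
   at each marker centroid, giving per-marker distortion vectors, magnitudes
   ‖u‖ and 3D distances r from isocenter;
3. magnitudes are summarised per radial region (0–100 mm, 100–200 mm,
   > 200 mm annuli plus cumulative "within R" statistics: n, median, 95 %
   quantile, max) with scatter and histogram figures;
4. a **second registration pass** of the already-deformed MR against the CT
   measures what the first pass failed to recover; shell-wise scanning of
   these residuals yields the *reliable radius* inside which the reported
   numbers are trustworthy measurements rather than lower bounds;
5. two acquisitions with reversed frequency-encode polarity can be
   decomposed into gradient-nonlinearity (polarity-even) and B0
   (polarity-odd) components: g = (u₊ + u₋)/2, b = (u₊ − u₋)/2;
6. reports embed a configuration hash and can be compared against a stored
   baseline with per-statistic tolerances (constancy QA).

A synthetic phantom simulator generates matched CT/MR volumes with an
exactly known parametric warp and marker ground truth, so every stage is
validated end-to-end without a scanner.

## Worked example

`python examples/measure_distortion.py` simulates the default phantom
(360 mm body, 7×7×7 markers at 40 mm pitch, 96³ voxels of 4 mm) warped by a
cubic radial distortion reaching 4 mm at r = 150 mm, runs the full pipeline
and prints:

```
Geometric distortion summary (mm, distances from isocenter)

        region     n   median      q95      max     mean
      0-100 mm    81    1.027    1.301    1.309    0.805
    100-200 mm   254    4.246    7.798    7.823    4.259
      > 200 mm     8    8.807    8.834    8.839    8.805
 r <= 150.0 mm   203    2.350    3.724    3.873    1.977

total markers: 343

ground truth for comparison: median 3.15 mm, max 10.64 mm
```

Each annulus row is the region statistic a QA report tracks; the bin
medians grow with radius exactly as the simulated r³ warp does, and the
measured values match the simulator's ground truth within fractions of a
voxel inside the reliable region. The other examples cover simulation
(`simulate_phantom.py`), residual validation and the reliable radius
(`reliable_region.py`), and component separation
(`separate_components.py`).

## Command line

A thin CLI wraps the library for routine use:

```
gridwarp-qa simulate --out pair/                 # synthetic CT/MR + ground truth
gridwarp-qa convert --dicom DIR --out ct.nii.gz  # DICOM series -> NIfTI (+ crop)
gridwarp-qa mask-housing --ct ct.nii.gz --strategy intensity_band --band 400:600 --out ct_m.nii.gz
gridwarp-qa register --fixed ct_m.nii.gz --moving mr.nii.gz --out-field field.nii.gz
gridwarp-qa analyze --field field.nii.gz --mr mr.nii.gz --out report/
gridwarp-qa validate --deformed mr_def.nii.gz --ct ct_m.nii.gz --markers report/markers.csv --out report/
gridwarp-qa separate --fwd f.nii.gz --rev r.nii.gz --axis x --out-grad g.nii.gz --out-b0 b0.nii.gz
gridwarp-qa run --config run.yaml --out run_dir/  # the whole workflow
```

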