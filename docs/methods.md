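# Methods

This note records the models, conventions and numerical choices behind
`lamellakit`, and what its synthetic tests do and do not demonstrate.

## Coordinate and unit conventions

All image and volume coordinates are continuous, 0-based and
pixel-centred: `(x, y)` with x right and y down for images, `(x, y, z)`
with z the slice index for stacks. Physical lengths enter only through an
explicit `PixelGrid` (nm per pixel, nm per slice), so no function silently
assumes a calibration. Angles are degrees at every public interface and
radians internally. Affine transforms act on column vectors
(`p' = L·p + t`) and serialize to JSON as nine row-major floats plus a
3-vector.

## Correlation model

The fluorescence→image correlation is deliberately a 7-d.o.f. similarity
(rotation quaternion, isotropic scale, in-plane translation; projection
drops the third coordinate, which is reported as depth) rather than a full
affine: four or five beads constrain exactly this family, and it is the
transform correlation toolboxes in this field fit. The least-squares
problem is initialized closed-form — the 2×3 linear map from a plain
affine fit is projected by SVD onto the nearest scaled pair of orthonormal
rows, which is exact on noise-free data — and refined with
Levenberg–Marquardt (`xtol = ftol = 1e-15`). When the initial residual is
not already at machine precision, four deterministic extra starts (±45°
about the in-plane axes) guard against a misleading affine solution. The
translation's depth component is fixed at zero by convention, so reported
depths are heights relative to the image plane through the origin.

FIB-view prediction works in SEM-projected space: fiducials are projected
keeping depth, a total-least-squares plane is fitted through them (normal
sign fixed toward +z, ties toward +y, for determinism), the user reference
point is placed on that plane, coordinates are rotated about the
x-parallel axis through it by the inter-beam angle, projected, and
translated onto the user-matched FIB point. The rotation sign is
configurable (`rotation_sign`); the default moves points above the plane
toward −y. We rotate the 3D (projected + depth) coordinates rather than
plane-flattened ones; for fiducials exactly on the plane the two readings
coincide.

## Virtual slices

The lamella mid-plane is the set of fluorescence-frame points whose FIB
projection lands on the horizontal line through the FIB anchor — i.e. the
plane containing the FIB image x-axis and the FIB viewing axis. Membership
in the slab mask is evaluated per voxel: the SEM projection must fall
inside the boundary polygon (even-odd rule, boundary inclusive, with a
1e-9 radius so edge points are never lost to rounding) and the distance to
the mid-plane along its normal, converted to nm through the voxel
calibration, must be at most half the lamella thickness (plus a ~1e-9 nm
tolerance so voxels exactly at half-thickness survive quaternion
round-off). The slab is drawn along the plane normal, the literal reading
of a slab "centred on the contour". The interior point is validated
against the polygon at construction; the slab-and-polygon test itself
fully determines the mask.

Masked projections resample the masked volume by inverse mapping
(trilinear, zero fill; mask multiplied in before interpolation) onto
output-aligned planes and take the maximum along the viewing axis. The
z-range is bounded globally by transforming the volume corners, never per
patch, so the result is bit-identical for any patch size or thread count —
a property the tests assert. Height scanning shifts the FIB anchor in
image-y pixels before mask construction, one projection per height.

## Volume registration

The affine fit minimizes the summed squared correspondence residuals; the
closed-form linear least-squares solution is the core all three strategies
share. RANSAC draws seeded 4-point samples, scores inliers by 3D distance,
refines on the consensus set (up to three re-consensus rounds) and stops
early on full consensus. The multi-start strategy seeds L-BFGS-B runs with
similarity (Umeyama) fits of random correspondence subsets — a
scale-normalized rigid-hypothesis scheme in the spirit of
certifiably-robust registration seeding; basin-hopping perturbs with a
step of 10 % of the point-cloud extent. Because the objective is a convex
quadratic the strategies agree on clean data; they are all exposed (plus a
best-of helper) because their behaviour differs under outliers, and every
random draw derives from the config seed.

Reported `rms` is the **per-coordinate** root-mean-square residual (the
3D-norm RMS is larger by √3); inlier classification always uses full 3D
distances. With 20 points and isotropic noise σ the expected value is
σ·√((3N−12)/(3N)) ≈ 0.89 σ, which the noise-band tests check.

## Stack postprocessing

De-curtaining decomposes each slice with a multilevel 2D DWT (default
`db4`, `levels = floor(log2(height)) − 3`) and damps the low vertical
frequencies of every vertical-detail band: the band's FFT along y is
multiplied by `1 − exp(−ky²/(2·sb²))` with `sb = σ·band_rows/image_rows`,
i.e. a damping width constant in normalized frequency across levels
(default σ = 6). Curtains are constant along y and concentrate at ky ≈ 0
in exactly these bands, so they are removed wholesale while y-varying
structure passes; keeping the width narrow and level-scaled is what
preserves genuine detail in deep levels. A direct spatial blur of the
coefficients cannot do this: at the level whose scale matches the stripe
period the stripe demodulates to a near-DC coefficient pattern that any
finite blur leaves intact (verified numerically during development).
σ = 0 disables the damping, giving the identity up to reconstruction
round-off, and the global mean is re-centred after reconstruction so the
operation is exactly zero-mean at DC.

An unavoidable corollary: structure that is genuinely constant along y is
indistinguishable from curtaining and is removed with it. Restoration
tests therefore draw their clean ground truth from the destripe-preserved
subspace; on real data, long vertical cell edges will be attenuated the
same way, which is the standard trade-off of wavelet destriping.

Charging compensation subtracts a background mask built by Gaussian
blurring (default σ = 35 px) followed by two grayscale erosions (disk
radius 5); the erosions keep the mask under local structure so detail
survives subtraction, and the output is shifted to a non-negative range
for integer writers. A Gaussian blur of width σb removes a fraction
σh²/(σh²+σb²) of a Gaussian hill of width σh, so σb should be chosen
below the artifact scale — the defaults suit the multi-thousand-pixel
frames they were tuned on; the tests use σb = 15–25 px for their
50–60 px hills.

Drift alignment registers each slice to its predecessor with upsampled
phase correlation (default 10×, i.e. 0.1 px quantization) and removes the
cumulative drift with cubic-spline shifts. The offset estimator combines a
plain estimate (exact for periodic content and large shifts), its
wrap-around aliases, and a Hann-windowed estimate (robust to fill
borders); when they disagree beyond 0.05 px each candidate is verified by
un-shifting the moving image and scoring the overlap correlation weighted
by √(overlap fraction), which prevents a wrap alias that explains only a
sliver from beating the true shift. Featureless slices get offset zero
with a warning. The returned offsets are the estimated cumulative drift;
the applied correction is its negative.

The foreshortening stretch resizes the y-axis by `1/sin(angle)` (linear
interpolation, output height rounded); at the 52° inter-beam angle the
factor is 1.2690. The pipeline order is crop → decurtain → decharge →
CLAHE → align → stretch, each stage toggleable and logged.

## Protocols and patterns

Protocols are line-oriented `key: value` text with one `[step]` block per
milling stage (current pA, time s, pattern gap and height µm, overtilt
stored as metadata only); the writer emits a canonical form that
round-trips byte-identically. Pattern sequences are one tab-separated
command per line with `#` comments. Compilation emits two
cleaning-cross-section patterns per step — inner edges at half the step's
gap from the lamella centre, outer edges clipped at the extreme milling
points (which protect grid bars), upper pattern scanning top-to-bottom and
lower bottom-to-top so material is removed toward the lamella face.
Micro-expansion joints are a mirror pair at ±(width/2 + offset); their
dimensions are configurable pragmatic defaults, not instrument-mandated
values. The lift-out trench layout places two parallel trenches
symmetrically around the extraction block and a perpendicular side trench
whose left edge sits `side_offset` beyond the left end of the parallel
trenches (the offset reference is ambiguous in common descriptions; this
choice is asserted by the non-overlap check). Dose arithmetic is
`I·t_dwell·N_line / (e · A_px)` with 1 nm² = 100 Å².

## Simulator

The virtual specimen is a voxel label volume (0 = vacuum) with a
volumetric mill rate per material in µm³/(nA·s) — calibration constants of
the simulation, not sputtering physics. Milling removes voxels
front-to-back within the (misalignment-displaced) footprint, rows ordered
by scan direction, until the charge-time budget divided by the per-voxel
cost is exhausted; mass balance and additivity are asserted by tests.
Rendering is orthographic surface shading (FIB views compressed by
sin(inter-beam angle)) with Poisson noise that is a pure function of the
seed and the view state: identical instrument state reproduces the raster
bit-for-bit, while any change of view draws fresh noise — both properties
the realignment logic depends on.

Drift is quasi-static: the total misalignment (stage recall error + beam
shift + linear drift + per-current beam offset) is evaluated at the start
of each acquisition or milling command and held for its duration. The
automated session realigns on every position recall (stage moves above the
10 µm threshold, beam shifts below) and again before every pattern
command, compensating each current change with a beam-shift-only
correction; the stored reference is refreshed after each successful
correction so every registration spans at most one command's worth of
surface change — registering a pre-milling reference against a heavily
milled view locks onto the trenches. With the default 50 nm voxels this
closed loop holds lamella placement error below two pixels under planted
drifts up to 120 nm/min and finishes the fine stage within one voxel of
the 300 nm protocol target. Rough milling for all positions always
precedes fine milling; the session policy carries a 1-hour fine-milling
budget and a 50 nm/hr condensation rate for contamination bookkeeping.

## Synthetic data: what it shows and what it does not

The generators emulate the features the algorithms are sensitive to —
subpixel bead positions with enforced separation, anisotropic PSF blobs
(σz > σxy as with dry objectives), y-constant sinusoidal curtains, broad
Gaussian charging hills, exact integer (rolled) and fractional
(Fourier-shifted, hence periodic) drifts, and a specimen with near-surface
inclusions that give the realignment texture. They do not emulate
detector-specific noise spectra, redeposition, stripe wander, depth-
dependent PSF aberrations, or non-affine deformation of the support film;
passing tests therefore demonstrate correctness of the geometry, the
estimators and the control loop, not instrument-grade performance on real
data. Problem sizes (e.g. 400²×40-voxel specimens, 256×320 test frames,
100-draw recovery sweeps) were chosen as the smallest at which the
measured properties are stable.

## Known limitations

- The correlation model has no projective or lens-distortion terms
  (out of scope by design).
- Destriping removes genuine y-constant structure (see above).
- The charging mask is global; spatially varying charge (local blooming)
  is only partially compensated.
- `measure_lamella` reads thickness from a single mid-depth column profile
  and so reports in voxel quanta.
- The simulator's driver contract mirrors beam/stage/imaging/milling
  operations only; gas injection, sputtering and manipulator mechanics are
  not modelled.
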