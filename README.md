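# lamellakit

Computational core of automated cryo-FIB/CLEM workflows: the image
analysis, geometry and protocol machinery behind targeted lamella
preparation, decoupled from any proprietary microscope API.

Cryo-electron tomography needs electron-transparent slabs ("lamellae",
~100–500 nm) milled out of frozen cells by a focused ion beam (FIB).
Hitting a fluorescently labelled structure with such a slab requires
registering three modalities — a confocal fluorescence z-stack, the SEM
view and the FIB view — and driving the microscope through staged milling
with realignment against drift. `lamellakit` implements that stack for
people building or studying such automation:

- **Fiducial detection** (`lamellakit.fiducials`) — micron fluorescent
  beads scored in SEM images by the product of a Gaussian matched filter,
  a circle-Hough accumulator and an intensity soft mask; subpixel centres
  by iterated 1D/2D Gaussian fitting; centroids of segmented label volumes.
- **3D→2D correlation** (`lamellakit.correlation`) — a 7-d.o.f. similarity
  transform `q ≈ P(s·R·p + t)` (P drops the depth coordinate) fitted by
  least squares from paired fiducials, with per-point residuals and RMS;
  prediction of FIB-view fiducial positions from the SEM correlation by
  rotating about the shared tilt axis through a reference point by the
  inter-beam angle (52° on the instruments modelled here).
- **Virtual slices** (`lamellakit.virtual_slice`) — a 3D slab mask with the
  position, orientation and thickness of a milled lamella, built from a
  polygon in the SEM view and an anchor in the FIB view, applied to the
  fluorescence volume before an affine-resampled maximum-intensity
  projection (patch-parallel, partition-invariant).
- **Volume registration** (`lamellakit.volume_registration`) — 12-parameter
  affine between fluorescence and FIB-SEM centroid sets via seeded RANSAC,
  multi-start L-BFGS-B, or basin-hopping; volume resampling by inverse
  mapping.
- **Stack postprocessing** (`lamellakit.stack_postprocessing`) — wavelet-
  domain de-curtaining (σ = 6), blur-and-erode charging compensation
  (σ = 35, two erosion steps), CLAHE (slope 3), subpixel phase-correlation
  drift alignment, and the 1/sin 52° foreshortening stretch.
- **Milling protocols** (`lamellakit.milling_protocols`) — text protocols
  compiled into pattern sequences (upper/lower patterns clipped at extreme
  milling points, micro-expansion joints, lift-out trench "C" layouts,
  slice-and-image plans), electron-dose arithmetic
  `dose = I·t_dwell·N_lines / (e·A_px)`, and session bookkeeping
  (success and retention rates, condensation budget).
- **Simulator** (`lamellakit.simulator`) — a voxel specimen and mock driver
  that execute pattern sequences, render SEM/FIB views with drift,
  per-current beam offsets and Poisson noise, and support closed-loop
  realignment tests; plus all synthetic fixture generators (bead fields,
  PSF blobs, curtaining, charging, drifted stacks) with ground truth.

## Worked example

`examples/simulated_session.py` mills one lamella on a drifting virtual
specimen (60 nm/min, per-current beam offsets planted), with closed-loop
phase-correlation realignment:

```
final lamella thickness: 300 nm (fine protocol target: 300 nm, voxel 50 nm)
placement error: 25 nm despite 60 nm/min drift (closed-loop realignment)
session wall-clock (simulated): 65 min, operations logged: 122
```

The fine protocol's last pattern gap is 0.3 µm, so the 300 nm slab means
the session milled to its target within one voxel; the 25 nm placement
error (half a voxel) shows the realignment loop fully absorbed the drift
the stage accumulated over the 65 simulated minutes.

The other scripts in `examples/` each demonstrate one capability — bead
detection and subpixel refinement, correlation fitting plus FIB prediction,
virtual-slice height scanning, robust affine registration, stack
restoration, and protocol compilation with dose arithmetic. A thin CLI
(`lamellakit --help`) wraps the same functions for shell use
(`detect-beads`, `correlate`, `predict-fib`, `virtual-slice`,
`register-volumes`, `postprocess-stack`, `protocol compile|trench`,
`dose`, `resolution`, `simulate-volume`).

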