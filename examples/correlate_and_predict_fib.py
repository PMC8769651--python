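"""Fit a 3D-fluorescence -> SEM correlation and predict FIB bead positions.

Simulates bead coordinates seen in a fluorescence stack and in the SEM
image (related by a known rotation + scale + shift), fits the similarity
transform, then rotates the fiducials by the 52-degree inter-beam angle
about a reference point to predict where they appear in the FIB image.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from lamellakit.correlation import fit_correlation, predict_fib_positions
from lamellakit.frames import BeamGeometry

rng = np.random.default_rng(3)
beads_3d = rng.uniform(-10, 10, (8, 3))
beads_3d[:, 2] = 0.15 * beads_3d[:, 0] + 2.0  # beads roughly on a plane

R_true = Rotation.from_euler("x", 20, degrees=True).as_matrix()
beads_sem = 1.3 * (beads_3d @ R_true.T)[:, :2] + [120.0, 95.0] \
    + rng.normal(0, 0.3, (8, 2))

result = fit_correlation(beads_3d, beads_sem)
print(f"correlation fit: scale {result.transform.scale:.4f}, "
      f"rms residual {result.rms:.3f} px")
# rms near the planted 0.3 px jitter means the 7-dof model explains the data.

fib = predict_fib_positions(beads_3d, sem_ref=(120.0, 95.0),
                            fib_match=(240.0, 310.0),
                            geom=BeamGeometry(inter_beam_angle=52.0),
                            sem_corr=result)
print("predicted FIB positions (px):")
for x, y in fib.points:
    print(f"  ({x:7.2f}, {y:7.2f})")
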