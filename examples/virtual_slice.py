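"""Build a lamella slab mask in a fluorescence volume and render virtual
slices at several sample heights.

The lamella is outlined by a polygon in the SEM view and anchored by a
point in the FIB view; a bright blob is planted on the plane three FIB-y
pixels above the anchor, so the brightest virtual slice identifies the
height at which the fluorescence matches the milled lamella.
"""

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

from lamellakit.correlation import CorrelationResult, CorrelationTransform
from lamellakit.exceptions import EmptyMaskWarning
from lamellakit.frames import PixelGrid
from lamellakit.virtual_slice import LamellaSpec, virtual_slice_series

sem = CorrelationResult(CorrelationTransform.identity(), np.zeros(4), 0.0)
q = Rotation.from_euler("x", 90, degrees=True).as_quat()
fib = CorrelationResult(CorrelationTransform(
    np.r_[q[3], q[:3]], 1.0, np.array([0.0, 20.0, 0.0])), np.zeros(4), 0.0)

volume = np.zeros((24, 24, 24))
volume[13, 12, 12] = 10.0  # blob at height -3 relative to the anchor
spec = LamellaSpec(polygon_sem=((2, 2), (20, 2), (20, 20), (2, 20)),
                   interior_point_sem=(10, 10), fib_anchor=(0, 10),
                   thickness=150.0)
grid = PixelGrid(100.0, 100.0, 100.0)

heights = range(-3, 4)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", EmptyMaskWarning)
    series = virtual_slice_series(volume, sem, fib, heights, spec, grid,
                                  output_shape=(24, 24))
for h, img in zip(heights, series):
    print(f"height {h:+d} px: max intensity {img.max():5.2f}")
best = list(heights)[int(np.argmax([s.max() for s in series]))]
print(f"best-matching height: {best:+d} px "
      "(the plane actually containing the blob)")
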