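"""Lamella masks in the fluorescence frame and masked projections.

After a lamella has been milled, the fluorescence signal it still contains
can be visualised by masking the fluorescence volume with a slab that has
the position, orientation and thickness of the lamella, then projecting the
masked volume onto an image ("virtual slice").  The slab is constructed
from a user-drawn polygon in the SEM image (the lamella boundary), a point
on the lamella in the FIB image (which, through the FIB correlation, fixes
the lamella plane), and a thickness in nm.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import map_coordinates

from .correlation import CorrelationResult, CorrelationTransform
from .exceptions import EmptyMaskWarning, SingularTransform
from .frames import Affine3D, PixelGrid

__all__ = [
    "LamellaSpec",
    "VolumeMask",
    "build_lamella_mask",
    "masked_projection",
    "virtual_slice_series",
]


@dataclass(frozen=True)
class LamellaSpec:
    """User-drawn lamella geometry.

    polygon_sem : (N>=3, 2) vertices of the lamella boundary in SEM pixels.
    interior_point_sem : a point inside the polygon.
    fib_anchor : a point on the lamella in the FIB image; together with the
        FIB correlation it defines the lamella mid-plane.
    thickness : slab thickness in nm.
    """

    polygon_sem: tuple
    interior_point_sem: tuple
    fib_anchor: tuple
    thickness: float

    def __post_init__(self):
        poly = np.asarray(self.polygon_sem, dtype=float)
        if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
            raise ValueError("polygon needs at least 3 (x, y) vertices")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")
        if not _contains(poly, np.asarray([self.interior_point_sem], float))[0]:
            raise ValueError("interior point is not inside the polygon")

    @property
    def polygon(self) -> np.ndarray:
        return np.asarray(self.polygon_sem, dtype=float)


@dataclass
class VolumeMask:
    """Binary slab mask aligned to its fluorescence volume grid (z, y, x)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")

    @property
    def shape(self):
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


def _contains(polygon: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Even-odd point-in-polygon with the boundary counting as inside."""
    path = MplPath(polygon, closed=False)
    eps = 1e-9
    return path.contains_points(xy, radius=eps) | path.contains_points(xy, radius=-eps)


def _view_affine(view) -> Affine3D:
    if isinstance(view, CorrelationResult):
        view = view.transform
    if isinstance(view, CorrelationTransform):
        return Affine3D(view.scale * view.rotation_matrix, view.translation)
    if isinstance(view, Affine3D):
        return view
    raise TypeError("view must be an Affine3D or a CorrelationTransform")


def _lamella_plane(fib_corr, anchor_xy, grid: PixelGrid):
    """Return ``(n, c, inv_norm_nm)`` describing the lamella mid-plane.

    In FIB-transformed coordinates the lamella appears edge-on as the
    horizontal line y = anchor_y: the plane contains the FIB image x-axis
    and the FIB viewing axis.  In fluorescence pixel coordinates p that is
    ``n . p + c = 0`` with n the y-row of the FIB linear map; dividing by
    the norm of n expressed in nm^-1 turns the residual into a signed
    distance in nm.
    """
    aff = _view_affine(fib_corr)
    n = aff.linear[1, :]
    c = aff.translation[1] - float(anchor_xy[1])
    n_nm = n / grid.scales
    norm = np.linalg.norm(n_nm)
    if norm < 1e-12:
        raise SingularTransform("FIB view collapses the y axis")
    return n, c, 1.0 / norm


def build_lamella_mask(spec: LamellaSpec, sem_corr, fib_corr,
                       shape, grid: PixelGrid) -> VolumeMask:
    """Realize a :class:`LamellaSpec` as a binary slab in the FLM volume.

    A voxel belongs to the mask iff (a) its SEM projection falls inside the
    lamella boundary polygon (even-odd rule, boundary inclusive) and (b) its
    distance to the lamella mid-plane, measured in nm along the plane
    normal, is at most half the lamella thickness.  ``shape`` is the
    ``(nz, ny, nx)`` shape of the fluorescence volume.
    """
    nz, ny, nx = shape
    sem_aff = _view_affine(sem_corr)
    n, c, inv_norm = _lamella_plane(fib_corr, spec.fib_anchor, grid)

    zz, yy, xx = np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx),
                             indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()]).astype(float)

    dist_nm = (pts @ n + c) * inv_norm
    # boundary-inclusive with a small tolerance so voxels exactly at
    # half-thickness are not lost to rotation round-off
    in_slab = np.abs(dist_nm) <= spec.thickness / 2.0 + 1e-9 * (1 + spec.thickness)

    inside = np.zeros(pts.shape[0], dtype=bool)
    if in_slab.any():
        proj = sem_aff.apply(pts[in_slab])[:, :2]
        inside[in_slab] = _contains(spec.polygon, proj)

    mask = inside.reshape(nz, ny, nx)
    if not mask.any():
        warnings.warn("lamella slab does not intersect the volume",
                      EmptyMaskWarning, stacklevel=2)
    return VolumeMask(mask)


def masked_projection(volume: np.ndarray, mask: VolumeMask | np.ndarray, view,
                      output_shape, patch_size: int = 64,
                      workers: int = 1) -> np.ndarray:
    """Masked maximum-intensity projection through an affine view.

    The masked volume is resampled by inverse mapping with trilinear
    interpolation onto the stack of output-aligned planes ``z = const``, and
    the maximum is taken along z.  Only the z-range actually covered by the
    transformed volume is evaluated.  The output is computed in independent
    patches (optionally across ``workers`` threads); the result is
    bit-identical for any ``patch_size`` and worker count because every
    output pixel is evaluated over the same global z-range.
    """
    vol = np.asarray(volume, dtype=float)
    mdata = mask.data if isinstance(mask, VolumeMask) else np.asarray(mask, bool)
    if mdata.shape != vol.shape:
        raise ValueError("mask and volume must have the same shape")
    aff = _view_affine(view)
    inv = aff.inverse()  # raises SingularTransform when not invertible

    masked = vol * mdata
    nz, ny, nx = vol.shape
    corners = np.array([[x, y, z] for x in (0, nx - 1)
                        for y in (0, ny - 1) for z in (0, nz - 1)], float)
    zvals = aff.apply(corners)[:, 2]
    z_lo, z_hi = int(np.floor(zvals.min())), int(np.ceil(zvals.max()))
    zs = np.arange(z_lo, z_hi + 1, dtype=float)

    out_h, out_w = output_shape
    out = np.zeros((out_h, out_w), dtype=float)
    tiles = [(r, min(r + patch_size, out_h), c, min(c + patch_size, out_w))
             for r in range(0, out_h, patch_size)
             for c in range(0, out_w, patch_size)]

    def run_tile(tile):
        r0, r1, c0, c1 = tile
        vv, uu = np.mgrid[r0:r1, c0:c1]
        flat = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
        acc = np.full(flat.shape[0], -np.inf)
        for z in zs:
            pts = np.column_stack([flat, np.full(flat.shape[0], z)])
            src = inv.apply(pts)  # (x, y, z) in volume pixels
            coords = np.vstack([src[:, 2], src[:, 1], src[:, 0]])
            vals = map_coordinates(masked, coords, order=1, cval=0.0)
            acc = np.maximum(acc, vals)
        return tile, acc.reshape(r1 - r0, c1 - c0)

    if workers and workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(run_tile, tiles))
    else:
        results = [run_tile(t) for t in tiles]
    for (r0, r1, c0, c1), patch in results:
        out[r0:r1, c0:c1] = patch
    return out


def virtual_slice_series(volume: np.ndarray, sem_corr, fib_corr,
                         heights, spec: LamellaSpec, grid: PixelGrid,
                         output_shape, patch_size: int = 64,
                         workers: int = 1) -> list[np.ndarray]:
    """One masked projection per sample height in the FIB image.

    ``heights`` are offsets in FIB-image y pixels; height h shifts the
    lamella plane anchor by h pixels along FIB y before the slab is built.
    Used to find which fluorescence plane matches the milled lamella best.
    """
    out = []
    for h in heights:
        anchor = (spec.fib_anchor[0], spec.fib_anchor[1] + float(h))
        shifted = replace(spec, fib_anchor=anchor)
        mask = build_lamella_mask(shifted, sem_corr, fib_corr,
                                  volume.shape, grid)
        out.append(masked_projection(volume, mask, fib_corr, output_shape,
                                     patch_size=patch_size, workers=workers))
    return out
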