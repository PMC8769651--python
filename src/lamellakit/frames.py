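"""Coordinate frames, geometric primitives and closed-form optics utilities.

Conventions used throughout the toolkit
---------------------------------------
* Coordinates are continuous, 0-based and pixel-centred: ``(x, y)`` for
  images (x to the right, y down) and ``(x, y, z)`` for stacks, where z is
  the slice index.  Conversion to physical units is only ever done through
  an explicit :class:`PixelGrid`.
* Angles are degrees at every public interface and radians internally.
* Affine transforms act on column vectors: ``p' = linear @ p + translation``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .exceptions import (
    DegenerateGeometry,
    InvalidAngle,
    InvalidOptics,
    SingularTransform,
)

__all__ = [
    "Point2D",
    "Point3D",
    "PixelGrid",
    "Plane",
    "Affine3D",
    "BeamGeometry",
    "apply_affine",
    "invert_affine",
    "compose_affine",
    "fit_plane",
    "foreshortening_factor",
    "confocal_resolution",
]


class Point2D(NamedTuple):
    x: float
    y: float


class Point3D(NamedTuple):
    x: float
    y: float
    z: float


def as_points(points, dim: int) -> np.ndarray:
    """Coerce a point, a sequence of points, or an ``(N, dim)`` array to float array."""
    arr = np.atleast_2d(np.asarray(points, dtype=float))
    if arr.shape[-1] != dim:
        raise ValueError(f"expected {dim}-D points, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("point coordinates must be finite")
    return arr


@dataclass(frozen=True)
class PixelGrid:
    """Physical calibration of an image or stack.

    Parameters
    ----------
    pixel_size_x, pixel_size_y : float
        Length in nm of one pixel along x and y.
    slice_thickness : float, optional
        Spacing in nm between consecutive slices (stacks only).
    origin_offset : tuple of float, optional
        Physical position in nm of pixel ``(0, 0[, 0])``.
    """

    pixel_size_x: float
    pixel_size_y: float
    slice_thickness: float | None = None
    origin_offset: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.pixel_size_x <= 0 or self.pixel_size_y <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.slice_thickness is not None and self.slice_thickness <= 0:
            raise ValueError("slice thickness must be positive")

    @property
    def scales(self) -> np.ndarray:
        """nm-per-pixel along (x, y, z); z defaults to x-scale for 2D grids."""
        sz = self.slice_thickness if self.slice_thickness is not None else self.pixel_size_x
        return np.array([self.pixel_size_x, self.pixel_size_y, sz], dtype=float)

    def to_physical(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        dim = pts.shape[-1]
        return pts * self.scales[:dim] + np.asarray(self.origin_offset[:dim])

    def to_pixels(self, points_nm) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_nm, dtype=float))
        dim = pts.shape[-1]
        return (pts - np.asarray(self.origin_offset[:dim])) / self.scales[:dim]


@dataclass(frozen=True)
class Plane:
    """Plane through ``point`` with unit ``normal``."""

    point: tuple
    normal: tuple

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must have unit length")

    def signed_distance(self, points) -> np.ndarray:
        pts = as_points(points, 3)
        n = np.asarray(self.normal, dtype=float)
        return (pts - np.asarray(self.point, dtype=float)) @ n

    def z_at(self, x: float, y: float) -> float:
        """Height of the plane above image position ``(x, y)`` (normal.z != 0)."""
        nx, ny, nz = self.normal
        if abs(nz) < 1e-12:
            raise DegenerateGeometry("plane is vertical; z is not a function of (x, y)")
        px, py, pz = self.point
        return pz - (nx * (x - px) + ny * (y - py)) / nz


@dataclass
class Affine3D:
    """3D affine map ``p -> linear @ p + translation``."""

    linear: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.linear = np.asarray(self.linear, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "Affine3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix4: np.ndarray) -> "Affine3D":
        m = np.asarray(matrix4, dtype=float)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.linear
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        pts = as_points(points, 3)
        return pts @ self.linear.T + self.translation

    def compose(self, other: "Affine3D") -> "Affine3D":
        """Return the transform that applies ``other`` first, then ``self``."""
        return Affine3D(self.linear @ other.linear,
                        self.linear @ other.translation + self.translation)

    def inverse(self) -> "Affine3D":
        det = np.linalg.det(self.linear)
        if abs(det) < 1e-300 or not np.isfinite(det):
            raise SingularTransform(f"linear part is singular (det={det:g})")
        inv = np.linalg.inv(self.linear)
        return Affine3D(inv, -inv @ self.translation)

    # --- serialization: {"linear": 9 floats row-major, "translation": 3 floats}
    def to_dict(self) -> dict:
        return {"linear": [float(v) for v in self.linear.ravel()],
                "translation": [float(v) for v in self.translation]}

    @classmethod
    def from_dict(cls, d: dict) -> "Affine3D":
        return cls(np.asarray(d["linear"], dtype=float).reshape(3, 3),
                   np.asarray(d["translation"], dtype=float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "Affine3D":
        return cls.from_dict(json.loads(text))


@dataclass(frozen=True)
class BeamGeometry:
    """Relative geometry of the electron and ion columns.

    ``inter_beam_angle`` is the angle between the SEM and FIB axes (52 degrees
    on the dual-beam instruments this toolkit models).  ``stage_tilt`` and
    ``pre_tilt`` are carried as metadata for protocol bookkeeping.
    """

    inter_beam_angle: float = 52.0
    stage_tilt: float = 0.0
    pre_tilt: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.inter_beam_angle <= 90.0:
            raise InvalidAngle("inter-beam angle must be in [0, 90] degrees")


def apply_affine(t: Affine3D, p) -> np.ndarray:
    """Apply ``t`` to one point or an ``(N, 3)`` array of points."""
    single = np.asarray(p).ndim == 1
    out = t.apply(p)
    return out[0] if single else out


def invert_affine(t: Affine3D) -> Affine3D:
    return t.inverse()


def compose_affine(outer: Affine3D, inner: Affine3D) -> Affine3D:
    return outer.compose(inner)


def fit_plane(points) -> Plane:
    """Total-least-squares plane through ``points``.

    The normal is the singular vector of the centred coordinates with the
    smallest singular value, i.e. the plane minimises the sum of squared
    orthogonal point-plane distances.  The sign of the normal is fixed so
    that its z-component is positive (ties broken toward positive y, then x)
    to make the output deterministic.
    """
    pts = as_points(points, 3)
    if pts.shape[0] < 3:
        raise DegenerateGeometry("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    # rank check: collinear points have <= 1 significant singular value
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= max(s[0] * 1e-10, 1e-12):
        raise DegenerateGeometry("points are collinear; plane is not unique")
    normal = vt[2]
    for comp in (2, 1, 0):
        if abs(normal[comp]) > 1e-12:
            if normal[comp] < 0:
                normal = -normal
            break
    return Plane(point=tuple(centroid), normal=tuple(normal / np.linalg.norm(normal)))


def foreshortening_factor(angle_deg: float) -> float:
    """Stretch factor ``1/sin(angle)`` that undoes FIB-view foreshortening.

    The milled face is observed at the inter-beam angle, so its vertical
    extent appears compressed by ``sin(angle)``; images are stretched in y by
    the reciprocal to restore true proportions.
    """
    if not 0.0 < angle_deg <= 90.0:
        raise InvalidAngle("angle must be in (0, 90] degrees")
    return 1.0 / math.sin(math.radians(angle_deg))


def confocal_resolution(numerical_aperture: float, wavelength_nm: float,
                        refractive_index: float = 1.31) -> tuple[float, float]:
    """Confocal resolution bounds (lateral, axial) in nm at 1 Airy-unit pinhole.

    lateral = 0.51 * wavelength / NA
    axial   = 0.88 * wavelength / (n - sqrt(n^2 - NA^2))

    The default refractive index 1.31 is that of vitreous ice, the medium
    of cryo-fixed specimens.
    """
    if wavelength_nm <= 0:
        raise InvalidOptics("wavelength must be positive")
    if not 0 < numerical_aperture < refractive_index:
        raise InvalidOptics("need 0 < NA < refractive index")
    lateral = 0.51 * wavelength_nm / numerical_aperture
    axial = 0.88 * wavelength_nm / (
        refractive_index - math.sqrt(refractive_index ** 2 - numerical_aperture ** 2))
    return lateral, axial
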