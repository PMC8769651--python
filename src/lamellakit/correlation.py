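"""Fluorescence-to-SEM/FIB correlation transforms.

The registration currency of 3D-targeted lamella preparation: a rigid
rotation, isotropic scale and translation that maps 3D fluorescence-stack
coordinates onto a 2D SEM or FIB image (the third coordinate after the
transform is retained as depth above/below the image plane).  The model is
deliberately a 7-d.o.f. similarity rather than a full affine -- fiducial
beads constrain exactly this family, and it is what correlation toolboxes
in this field fit.

Also provided: prediction of fiducial positions in the FIB view from an
existing SEM correlation via the inter-beam geometry (plane fit through the
fiducials, rotation about the reference point by the beam angle,
translation onto a matched FIB point).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .exceptions import DegenerateGeometry, EmptyInput, NotEnoughFiducials
from .fiducials import FiducialSet, Modality
from .frames import BeamGeometry, PixelGrid, Point2D, fit_plane

__all__ = [
    "CorrelationTransform",
    "CorrelationResult",
    "fit_correlation",
    "apply_correlation",
    "predict_fib_positions",
    "rms_residual",
]


@dataclass
class CorrelationTransform:
    """Similarity transform ``p -> scale * R(quaternion) @ p + translation``.

    Projection onto the image is dropping the third component; that
    component (depth) is reported alongside the 2D position.  The quaternion
    is stored as ``(w, x, y, z)`` with unit norm; translation z is fixed to
    0 by convention, so depth is height relative to the image plane through
    the origin.
    """

    quaternion: np.ndarray
    scale: float
    translation: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if n == 0:
            raise ValueError("zero quaternion")
        self.quaternion = q / n
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "CorrelationTransform":
        return cls(np.array([1.0, 0, 0, 0]), 1.0, np.zeros(3))

    @property
    def rotation_matrix(self) -> np.ndarray:
        w, x, y, z = self.quaternion
        return Rotation.from_quat([x, y, z, w]).as_matrix()

    def transform3d(self, points3d) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points3d, dtype=float))
        return self.scale * pts @ self.rotation_matrix.T + self.translation

    def to_dict(self) -> dict:
        return {"quaternion": [float(v) for v in self.quaternion],
                "scale": float(self.scale),
                "translation": [float(v) for v in self.translation]}

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationTransform":
        return cls(np.asarray(d["quaternion"], float), float(d["scale"]),
                   np.asarray(d["translation"], float))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, text: str) -> "CorrelationTransform":
        return cls.from_dict(json.loads(text))


@dataclass
class CorrelationResult:
    transform: CorrelationTransform
    per_point_residuals: np.ndarray
    rms: float

    def __post_init__(self):
        self.per_point_residuals = np.asarray(self.per_point_residuals, dtype=float)
        expected = float(np.sqrt(np.mean(self.per_point_residuals ** 2))) \
            if self.per_point_residuals.size else 0.0
        if abs(self.rms - expected) > 1e-9:
            raise ValueError("rms inconsistent with per-point residuals")


def _as_xy(points, dim):
    if isinstance(points, FiducialSet):
        points = points.points
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != dim:
        raise ValueError(f"expected {dim}-D points, got shape {pts.shape}")
    return pts


def _params_to_transform(params: np.ndarray) -> CorrelationTransform:
    rot = Rotation.from_rotvec(params[:3])
    x, y, z, w = rot.as_quat()
    return CorrelationTransform(np.array([w, x, y, z]), float(np.exp(params[3])),
                                np.array([params[4], params[5], 0.0]))


def fit_correlation(points3d, points2d) -> CorrelationResult:
    """Least-squares similarity fit of 3D fluorescence points to 2D image points.

    Minimises ``sum || project(s R p + t) - q ||^2`` over rotation, isotropic
    scale and in-plane translation.  Initialisation is closed-form: the
    2x3 linear map from a plain affine least-squares fit is projected onto
    the nearest scaled pair of orthonormal rows (SVD), which is exact for
    noise-free data; a quasi-Newton refinement follows.  Deterministic.
    """
    src = _as_xy(points3d, 3)
    dst = _as_xy(points2d, 2)
    if src.shape[0] != dst.shape[0]:
        raise ValueError("point lists must be paired")
    n = src.shape[0]
    if n < 4:
        raise NotEnoughFiducials(f"need >= 4 paired fiducials, got {n}")
    if np.linalg.matrix_rank(dst - dst.mean(axis=0), tol=1e-9) < 1:
        raise DegenerateGeometry("2D points are all coincident")

    # --- closed-form initialisation: affine fit, then nearest similarity
    A = np.hstack([src, np.ones((n, 1))])
    sol, _, rank, _ = np.linalg.lstsq(A, dst, rcond=None)
    M = sol[:3].T          # 2x3 linear part
    t2 = sol[3]
    u, s, vt = np.linalg.svd(M, full_matrices=False)
    scale0 = max(float(s.mean()), 1e-9)
    rows = u @ vt          # nearest orthonormal-row 2x3 matrix
    r3 = np.cross(rows[0], rows[1])
    R0 = np.vstack([rows, r3])
    x0 = np.concatenate([Rotation.from_matrix(R0).as_rotvec(),
                         [np.log(scale0)], t2])

    def residuals(params):
        tr = _params_to_transform(params)
        return (tr.transform3d(src)[:, :2] - dst).ravel()

    best = None
    starts = [x0]
    if np.sqrt(np.mean(residuals(x0) ** 2)) > 1e-9:
        # a few deterministic extra starts guard against a poor affine init
        for axis in ((1, 0, 0), (0, 1, 0)):
            for sign in (1, -1):
                extra = Rotation.from_rotvec(sign * np.deg2rad(45) * np.array(axis))
                rv = (extra * Rotation.from_matrix(R0)).as_rotvec()
                starts.append(np.concatenate([rv, [np.log(scale0)], t2]))
    for start in starts:
        sol = least_squares(residuals, start, method="lm",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-20:
            break

    transform = _params_to_transform(best.x)
    res = np.linalg.norm(transform.transform3d(src)[:, :2] - dst, axis=1)
    return CorrelationResult(transform, res, float(np.sqrt(np.mean(res ** 2))))


def apply_correlation(t: CorrelationTransform, p):
    """Map 3D point(s) to (2D image position, depth above/below the plane)."""
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    out = t.transform3d(pts)
    if np.asarray(p).ndim == 1:
        return out[0, :2], float(out[0, 2])
    return out[:, :2], out[:, 2]


def predict_fib_positions(fiducials3d, sem_ref, fib_match,
                          geom: BeamGeometry, sem_corr: CorrelationResult,
                          rotation_sign: int = 1) -> FiducialSet:
    """Predict fiducial positions in the FIB image from the SEM correlation.

    At coincidence height the SEM and FIB views are related by a rotation
    about the shared tilt axis (the image x-axis) plus beam shifts.  The
    procedure: (1) project the 3D fiducials into SEM-image space keeping
    depth; (2) fit the best plane through them; (3) place the user reference
    point ``sem_ref`` on that plane; (4) rotate about the x-parallel axis
    through it by the inter-beam angle; (5) drop depth and translate so the
    reference lands on its user-matched FIB point ``fib_match``.

    ``rotation_sign`` flips the rotation direction; +1 moves points above
    the plane toward negative y (away from the viewer).
    """
    src = _as_xy(fiducials3d, 3)
    sem_ref = np.asarray(sem_ref, dtype=float).reshape(2)
    fib_match = np.asarray(fib_match, dtype=float).reshape(2)

    proj, depth = apply_correlation(sem_corr.transform, src)
    pts = np.column_stack([proj, depth])
    plane = fit_plane(pts)
    ref = np.array([sem_ref[0], sem_ref[1], plane.z_at(*sem_ref)])

    theta = rotation_sign * np.deg2rad(geom.inter_beam_angle)
    c, s = np.cos(theta), np.sin(theta)
    rot_x = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)
    rotated = (pts - ref) @ rot_x.T + ref
    predicted = rotated[:, :2] + (fib_match - sem_ref)
    return FiducialSet(points=predicted, modality=Modality.FIB)


def rms_residual(pairs, grid: PixelGrid | None = None):
    """Root-mean-square distance between paired 2D points, in pixels.

    ``pairs`` is a sequence of ``((x, y), (x, y))`` tuples or an
    ``(N, 2, 2)`` array.  With a :class:`PixelGrid` the value is also
    returned in nm (pixel sizes applied per axis before taking norms).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise EmptyInput("no point pairs")
    arr = arr.reshape(-1, 2, 2)
    diff = arr[:, 0] - arr[:, 1]
    rms_px = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    if grid is None:
        return rms_px
    diff_nm = diff * np.array([grid.pixel_size_x, grid.pixel_size_y])
    rms_nm = float(np.sqrt(np.mean(np.sum(diff_nm ** 2, axis=1))))
    return rms_px, rms_nm
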