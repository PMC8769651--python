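"""3D affine registration between fluorescence and FIB-SEM volumes.

Matched fiducial centroids (beads, stained lipid droplets) in the two
volumes are related by a full 12-parameter affine transform -- anisotropic
scale absorbs the axial compression of air-objective cryo-fluorescence
stacks, shear absorbs slicing drift.  Because correspondences can contain
gross outliers (mis-segmented droplets, cluster mismatches), the fit is
offered with three strategies: seeded RANSAC, local minimisation from
multiple correspondence-derived starting points, and basin-hopping, all
around the same linear least-squares core and all reproducible from a
single seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform
from scipy.optimize import basinhopping, minimize
from scipy.spatial.distance import cdist

from .exceptions import DegenerateGeometry, EmptyMatchingWarning
from .fiducials import FiducialSet
from .frames import Affine3D

__all__ = [
    "RegistrationConfig",
    "match_fiducials",
    "fit_affine",
    "best_affine_fit",
    "transform_volume",
]


@dataclass
class RegistrationConfig:
    """Strategy and reproducibility knobs for the affine fit.

    inlier_threshold is in the units of the destination points (nm when
    centroids are given in nm, which is the recommended convention).
    """

    strategy: str = "ransac"  # ransac | multistart_local | basinhopping
    ransac_iters: int = 1000
    inlier_threshold: float = 150.0
    n_starts: int = 8
    hops: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("ransac", "multistart_local", "basinhopping"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if min(self.ransac_iters, self.n_starts, self.hops) < 1:
            raise ValueError("iteration counts must be >= 1")
        if self.inlier_threshold <= 0:
            raise ValueError("inlier threshold must be positive")


def match_fiducials(src: FiducialSet, dst: FiducialSet,
                    initial_guess: Affine3D | None = None,
                    max_dist: float = np.inf) -> list[tuple[int, int]]:
    """Mutual-nearest-neighbour correspondences between two point sets.

    ``src`` points are optionally pre-transformed by ``initial_guess``
    before distances are evaluated; pairs farther apart than ``max_dist``
    are discarded.  Returns index pairs sorted by source index.
    """
    a = np.atleast_2d(np.asarray(src.points if isinstance(src, FiducialSet) else src, float))
    b = np.atleast_2d(np.asarray(dst.points if isinstance(dst, FiducialSet) else dst, float))
    if a.size == 0 or b.size == 0:
        raise ValueError("point sets must be non-empty")
    if initial_guess is not None:
        a = initial_guess.apply(a)
    d = cdist(a, b)
    nn_ab = d.argmin(axis=1)
    nn_ba = d.argmin(axis=0)
    pairs = [(i, int(j)) for i, j in enumerate(nn_ab)
             if nn_ba[j] == i and d[i, j] <= max_dist]
    if not pairs:
        warnings.warn("no mutual-nearest-neighbour pairs within max_dist",
                      EmptyMatchingWarning, stacklevel=2)
    return pairs


def _lstsq_affine(src: np.ndarray, dst: np.ndarray) -> Affine3D:
    """Closed-form least-squares affine (the core all strategies share)."""
    n = src.shape[0]
    A = np.hstack([src, np.ones((n, 1))])
    sol, _, rank, _ = np.linalg.lstsq(A, dst, rcond=None)
    if rank < 4:
        raise DegenerateGeometry("source points are coplanar or fewer than 4")
    return Affine3D(sol[:3].T, sol[3])


def _check_pairs(src, dst):
    src = np.atleast_2d(np.asarray(src, float))
    dst = np.atleast_2d(np.asarray(dst, float))
    if src.shape != dst.shape or src.shape[1] != 3:
        raise ValueError("need paired (N, 3) arrays")
    if src.shape[0] < 4:
        raise DegenerateGeometry("affine fit needs >= 4 point pairs")
    centred = src - src.mean(axis=0)
    s = np.linalg.svd(centred, compute_uv=False)
    if s[2] <= max(s[0] * 1e-9, 1e-12):
        raise DegenerateGeometry("source points are coplanar")
    return src, dst


def _rms(aff: Affine3D, src, dst, mask=None) -> float:
    """Per-coordinate root-mean-square residual (nm when inputs are in nm)."""
    res = aff.apply(src) - dst
    if mask is not None:
        res = res[mask]
    return float(np.sqrt(np.mean(res ** 2))) if res.size else np.inf


def _similarity_umeyama(src: np.ndarray, dst: np.ndarray) -> Affine3D:
    """Scale-normalised rigid (similarity) fit; used to seed local searches."""
    mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
    sc, dc = src - mu_s, dst - mu_d
    cov = dc.T @ sc / src.shape[0]
    u, s, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(u @ vt))
    S = np.diag([1.0, 1.0, d])
    R = u @ S @ vt
    var = (sc ** 2).sum() / src.shape[0]
    scale = (s * np.diag(S)).sum() / var if var > 0 else 1.0
    return Affine3D(scale * R, mu_d - scale * R @ mu_s)


def _pack(aff: Affine3D) -> np.ndarray:
    return np.concatenate([aff.linear.ravel(), aff.translation])


def _unpack(x: np.ndarray) -> Affine3D:
    return Affine3D(x[:9].reshape(3, 3), x[9:])


def fit_affine(src3d, dst3d, cfg: RegistrationConfig):
    """Fit the affine minimising the sum of squared correspondence residuals.

    Returns ``(Affine3D, rms, inlier_mask)``.  ``rms`` is the per-coordinate
    root-mean-square residual in the destination units.  For RANSAC the
    transform and rms are computed over the consensus set and the mask flags
    the inliers; the other strategies use every pair (mask all True).  All
    randomness is drawn from ``cfg.seed``.
    """
    src, dst = _check_pairs(src3d, dst3d)
    n = src.shape[0]
    rng = np.random.default_rng(cfg.seed)

    def objective(x):
        aff = _unpack(x)
        return float(np.sum((aff.apply(src) - dst) ** 2))

    if cfg.strategy == "ransac":
        best_mask, best_count, best_rms = None, -1, np.inf
        for _ in range(cfg.ransac_iters):
            idx = rng.choice(n, size=4, replace=False)
            sub = src[idx] - src[idx].mean(axis=0)
            if np.linalg.svd(sub, compute_uv=False)[2] < 1e-9:
                continue
            try:
                hyp = _lstsq_affine(src[idx], dst[idx])
            except DegenerateGeometry:
                continue
            res = np.linalg.norm(hyp.apply(src) - dst, axis=1)
            mask = res <= cfg.inlier_threshold
            count = int(mask.sum())
            if count > best_count or (count == best_count
                                      and _rms(hyp, src, dst, mask) < best_rms):
                best_mask, best_count = mask, count
                best_rms = _rms(hyp, src, dst, mask)
                if best_count == n:
                    break  # full consensus; more sampling cannot improve
        if best_mask is None or best_count < 4:
            raise DegenerateGeometry("RANSAC found no valid 4-point sample")
        # iterative consensus refinement on the inlier set
        mask = best_mask
        for _ in range(3):
            aff = _lstsq_affine(src[mask], dst[mask])
            res = np.linalg.norm(aff.apply(src) - dst, axis=1)
            new_mask = res <= cfg.inlier_threshold
            if new_mask.sum() < 4 or np.array_equal(new_mask, mask):
                break
            mask = new_mask
        aff = _lstsq_affine(src[mask], dst[mask])
        return aff, _rms(aff, src, dst, mask), mask

    mask = np.ones(n, dtype=bool)
    if cfg.strategy == "multistart_local":
        starts = [_pack(_lstsq_affine(src, dst))]
        for _ in range(cfg.n_starts - 1):
            idx = rng.choice(n, size=min(6, n), replace=False)
            try:
                starts.append(_pack(_similarity_umeyama(src[idx], dst[idx])))
            except np.linalg.LinAlgError:
                continue
        best = None
        for x0 in starts:
            sol = minimize(objective, x0, method="L-BFGS-B",
                           options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12})
            if best is None or sol.fun < best.fun:
                best = sol
        aff = _unpack(best.x)
    else:  # basinhopping
        extent = float(np.ptp(src, axis=0).max())
        x0 = _pack(_similarity_umeyama(src, dst))
        sol = basinhopping(
            objective, x0, niter=cfg.hops, stepsize=0.1 * max(extent, 1.0),
            minimizer_kwargs={"method": "L-BFGS-B",
                              "options": {"maxiter": 500, "ftol": 1e-15}},
            seed=int(cfg.seed))
        aff = _unpack(sol.x)
    # polish with the closed-form solution (the objective is quadratic)
    polished = _lstsq_affine(src, dst)
    if objective(_pack(polished)) <= objective(_pack(aff)) + 1e-12:
        aff = polished
    return aff, _rms(aff, src, dst), mask


def best_affine_fit(src3d, dst3d, cfg: RegistrationConfig):
    """Run all three strategies and return the minimum-rms result.

    Returns ``(strategy_name, Affine3D, rms, inlier_mask)``.
    """
    results = {}
    for strategy in ("ransac", "multistart_local", "basinhopping"):
        c = RegistrationConfig(strategy=strategy, ransac_iters=cfg.ransac_iters,
                               inlier_threshold=cfg.inlier_threshold,
                               n_starts=cfg.n_starts, hops=cfg.hops, seed=cfg.seed)
        results[strategy] = fit_affine(src3d, dst3d, c)
    name = min(results, key=lambda k: results[k][1])
    return (name,) + results[name]


def transform_volume(volume: np.ndarray, a: Affine3D, out_shape=None,
                     fill: float = 0.0) -> np.ndarray:
    """Resample ``volume`` through affine ``a`` by inverse mapping.

    ``a`` maps source ``(x, y, z)`` pixel coordinates to destination
    coordinates; the output voxel at destination p receives the trilinear
    interpolation of the source at ``a^-1(p)``, with ``fill`` outside.
    """
    vol = np.asarray(volume, dtype=float)
    inv = a.inverse()
    # convert the (x, y, z) convention to array (z, y, x) index order
    P = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    m = P @ inv.linear @ P
    off = P @ inv.translation
    return affine_transform(vol, m, offset=off, order=1, cval=fill,
                            output_shape=out_shape or vol.shape)
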