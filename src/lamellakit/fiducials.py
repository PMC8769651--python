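"""Fiducial detection and subpixel localization.

Micron-sized fluorescent beads are visible in fluorescence, SEM and FIB
imaging and serve as the landmarks from which cross-modality transforms are
fitted.  This module scores SEM images for bead-like features with three
independent measures (Gaussian matched filter, circle Hough transform,
intensity soft mask), multiplies them into a final score, picks peaks, and
refines centres to subpixel precision by iterated Gaussian fitting.
Centroids of segmented label volumes (lipid droplets, beads in FIB-SEM
stacks) are extracted by connected-component labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import canny, match_template, peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk
from skimage.transform import hough_circle

from .exceptions import FitFailed, ImageTooSmall

__all__ = [
    "Modality",
    "BeadDetectionParams",
    "FiducialSet",
    "bead_score_maps",
    "detect_beads",
    "fit_center_gaussian",
    "extract_centroids",
]


class Modality(str, Enum):
    FLM = "FLM"
    SEM = "SEM"
    FIB = "FIB"
    FIBSEM_VOL = "FIBSEM_VOL"


@dataclass
class BeadDetectionParams:
    """Tunables of the three-score bead detector.

    radius is the expected bead radius in pixels; the Hough accumulator is
    evaluated over radii ``radius * radius_multiplier * [0.8, 1.2]`` in five
    steps and max-pooled.  min_separation defaults to the bead radius.
    """

    radius: float
    radius_multiplier: float = 1.0
    threshold_method: str = "otsu"  # one of: otsu, mean, fixed
    threshold_value: float = 0.5    # used when threshold_method == "fixed"
    n_peaks: int = 10
    min_separation: float | None = None

    def __post_init__(self):
        if self.radius < 1:
            raise ValueError("bead radius must be >= 1 pixel")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.threshold_method not in ("otsu", "mean", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.min_separation is None:
            self.min_separation = self.radius


@dataclass
class FiducialSet:
    """A list of fiducial coordinates tagged with their imaging modality.

    ``points`` is an ``(N, 2)`` or ``(N, 3)`` float array in pixel units.
    """

    points: np.ndarray
    modality: Modality = Modality.SEM
    labels: list | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.size == 0:
            self.points = self.points.reshape(0, 2)
        if self.points.ndim != 2 or self.points.shape[1] not in (2, 3):
            raise ValueError("points must be an (N, 2) or (N, 3) array")
        self.modality = Modality(self.modality)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def _minmax(a: np.ndarray) -> np.ndarray:
    lo, hi = float(a.min()), float(a.max())
    if hi - lo < 1e-300:
        return np.zeros_like(a)
    return (a - lo) / (hi - lo)


def _gaussian_kernel(sigma: float) -> np.ndarray:
    half = max(2, int(round(3 * sigma)))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    return np.exp(-(xx ** 2 + yy ** 2) / (2.0 * sigma ** 2))


def bead_score_maps(image: np.ndarray, params: BeadDetectionParams):
    """Three per-pixel bead scores, each the same shape as ``image``.

    Returns ``(gauss_score, hough_score, soft_mask)``:

    * gauss_score -- normalized cross-correlation of the image with a
      Gaussian kernel of sigma = bead radius,
    * hough_score -- circle-centre accumulator from Canny edges, max-pooled
      over five radii around ``radius * radius_multiplier``,
    * soft_mask   -- thresholded image, dilated by a disk of the bead radius
      and blurred with sigma = radius, rescaled to [0, 1].
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("bead detection operates on 2D images")
    r = params.radius
    if min(img.shape) < 3 * r:
        raise ImageTooSmall(
            f"image {img.shape} smaller than 3x bead radius ({3 * r:.0f} px)")

    gauss_score = match_template(img, _gaussian_kernel(r), pad_input=True)

    edges = canny(_minmax(img), sigma=1.0)
    r0 = r * params.radius_multiplier
    radii = np.unique(np.maximum(1, np.round(np.linspace(0.8 * r0, 1.2 * r0, 5)))).astype(int)
    hough = hough_circle(edges, radii)
    hough_score = hough.max(axis=0)

    norm = _minmax(img)
    if params.threshold_method == "otsu":
        thr = threshold_otsu(norm) if norm.max() > norm.min() else np.inf
    elif params.threshold_method == "mean":
        thr = float(norm.mean())
    else:
        thr = params.threshold_value
    fg = norm > thr
    dilated = dilation(fg, disk(max(1, int(round(r)))))
    soft_mask = ndimage.gaussian_filter(dilated.astype(float), sigma=r)
    if soft_mask.max() > 0:
        soft_mask = soft_mask / soft_mask.max()
    return gauss_score, hough_score, soft_mask


def detect_beads(image: np.ndarray, params: BeadDetectionParams):
    """Detect bead centres as peaks of the product of the three score maps.

    Each score map is min-max normalized to [0, 1] before multiplication.
    Peaks are local maxima with non-maximum suppression at
    ``params.min_separation``; a border of one bead radius is excluded.  The
    top ``n_peaks`` are returned ordered by (score desc, y asc, x asc).

    Returns ``(FiducialSet, peak_map)`` where ``peak_map`` is a boolean
    raster marking the returned integer positions.
    """
    gauss, hough, mask = bead_score_maps(image, params)
    score = _minmax(gauss) * _minmax(hough) * _minmax(mask)

    border = int(round(params.radius))
    coords = peak_local_max(
        score,
        min_distance=max(1, int(round(params.min_separation))),
        threshold_abs=1e-12,
        exclude_border=border,
    )
    peak_map = np.zeros(score.shape, dtype=bool)
    if coords.size:
        vals = score[coords[:, 0], coords[:, 1]]
        # deterministic order: score desc, then y asc, then x asc
        order = np.lexsort((coords[:, 1], coords[:, 0], -vals))
        coords = coords[order][: params.n_peaks]
        peak_map[coords[:, 0], coords[:, 1]] = True
        points = coords[:, ::-1].astype(float)  # (row, col) -> (x, y)
    else:
        points = np.zeros((0, 2))
    return FiducialSet(points=points, modality=Modality.SEM), peak_map


def _fit_gaussian_1d(profile: np.ndarray, coords: np.ndarray, center0: float,
                     sigma0: float) -> float:
    """Return the centre of a 1D Gaussian + constant offset fit."""
    amp0 = float(profile.max() - profile.min())
    off0 = float(profile.min())
    if amp0 <= 0:
        raise FitFailed("flat profile")

    def model(x, amp, mu, sigma, off):
        return amp * np.exp(-(x - mu) ** 2 / (2.0 * sigma ** 2)) + off

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, coords, profile, p0=(amp0, center0, sigma0, off0), maxfev=5000)
    except RuntimeError as exc:
        raise FitFailed(str(exc)) from exc
    amp, mu, sigma, off = popt
    if amp <= 0 or not coords.min() - 1 <= mu <= coords.max() + 1:
        raise FitFailed("1D fit amplitude <= background or centre left the window")
    return float(mu)


def _fit_gaussian_2d(patch: np.ndarray, x0: float, y0: float, oy: int, ox: int,
                     sigma0: float) -> tuple[float, float]:
    yy, xx = np.mgrid[0:patch.shape[0], 0:patch.shape[1]]
    yy = yy + oy
    xx = xx + ox
    amp0 = float(patch.max() - patch.min())
    off0 = float(patch.min())
    if amp0 <= 0:
        raise FitFailed("flat patch")

    def model(coords, amp, mux, muy, sx, sy, off):
        x, y = coords
        return (amp * np.exp(-((x - mux) ** 2 / (2 * sx ** 2)
                               + (y - muy) ** 2 / (2 * sy ** 2))) + off).ravel()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(
                model, (xx, yy), patch.ravel(),
                p0=(amp0, x0, y0, sigma0, sigma0, off0), maxfev=4000)
    except RuntimeError as exc:
        raise FitFailed(str(exc)) from exc
    amp, mux, muy, sx, sy, off = popt
    if amp <= 0:
        raise FitFailed("2D fit amplitude <= background")
    return float(mux), float(muy)


def fit_center_gaussian(data: np.ndarray, seed, window: int = 11) -> np.ndarray:
    """Subpixel centre of a blob by iterated 1D and 2D Gaussian fitting.

    Starting from ``seed`` (``(x, y)`` for 2D input, ``(x, y, z)`` for 3D),
    each iteration fits 1D Gaussians with a constant background along every
    axis through the current centre, then a 2D Gaussian in the in-plane
    window.  Iteration stops when the centre moves less than 0.01 px, or
    after 20 iterations.  For 3D input the z-centre comes from the 1D fit
    along z.  Raises :class:`FitFailed` for flat or non-convergent data.
    """
    arr = np.asarray(data, dtype=float)
    if window < 5 or window % 2 == 0:
        raise ValueError("window must be odd and >= 5")
    half = window // 2
    seed = np.asarray(seed, dtype=float)
    is3d = arr.ndim == 3
    if (is3d and seed.shape != (3,)) or (not is3d and seed.shape != (2,)):
        raise ValueError("seed dimensionality does not match data")
    if float(arr.max() - arr.min()) <= 0:
        raise FitFailed("image is flat")

    center = seed.copy()
    sigma0 = max(1.0, half / 2.0)

    def clampi(v, lo, hi):
        return int(min(max(round(v), lo), hi))

    for _ in range(20):
        prev = center.copy()
        cx, cy = center[0], center[1]
        cz = center[2] if is3d else None
        plane = arr[clampi(cz, 0, arr.shape[0] - 1)] if is3d else arr
        iy = clampi(cy, 0, plane.shape[0] - 1)
        ix = clampi(cx, 0, plane.shape[1] - 1)

        x_lo, x_hi = max(0, ix - half), min(plane.shape[1], ix + half + 1)
        y_lo, y_hi = max(0, iy - half), min(plane.shape[0], iy + half + 1)
        cx = _fit_gaussian_1d(plane[iy, x_lo:x_hi], np.arange(x_lo, x_hi), cx, sigma0)
        cy = _fit_gaussian_1d(plane[y_lo:y_hi, ix], np.arange(y_lo, y_hi), cy, sigma0)

        if is3d:
            iz = clampi(cz, 0, arr.shape[0] - 1)
            z_lo, z_hi = max(0, iz - half), min(arr.shape[0], iz + half + 1)
            zprof = arr[z_lo:z_hi, clampi(cy, 0, arr.shape[1] - 1),
                        clampi(cx, 0, arr.shape[2] - 1)]
            cz = _fit_gaussian_1d(zprof, np.arange(z_lo, z_hi), cz, sigma0)
            plane = arr[clampi(cz, 0, arr.shape[0] - 1)]

        iy = clampi(cy, 0, plane.shape[0] - 1)
        ix = clampi(cx, 0, plane.shape[1] - 1)
        y_lo, y_hi = max(0, iy - half), min(plane.shape[0], iy + half + 1)
        x_lo, x_hi = max(0, ix - half), min(plane.shape[1], ix + half + 1)
        cx, cy = _fit_gaussian_2d(plane[y_lo:y_hi, x_lo:x_hi], cx, cy, y_lo, x_lo, sigma0)

        center = np.array([cx, cy, cz]) if is3d else np.array([cx, cy])
        if np.linalg.norm(center - prev) < 0.01:
            return center
    return center


def extract_centroids(label_volume: np.ndarray) -> FiducialSet:
    """Unweighted centroids of 26-connected components of a 3D label volume.

    Voxels with value 0 are background.  Distinct input labels are kept as
    distinct components even when they touch; a single non-background label
    is split into its connected components.  Centroids are returned as
    ``(x, y, z)`` points (z = slice index) ordered by input label then by
    scan order of each component's first voxel, with the component label
    recorded in ``labels``.
    """
    vol = np.asarray(label_volume)
    if vol.ndim != 3:
        raise ValueError("expected a 3D label volume")
    if np.any(vol < 0):
        raise ValueError("labels must be >= 0")
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    points, labels = [], []
    for lab in np.unique(vol):
        if lab == 0:
            continue
        comps, n = ndimage.label(vol == lab, structure=structure)
        for comp in range(1, n + 1):
            zz, yy, xx = np.nonzero(comps == comp)
            points.append([xx.mean(), yy.mean(), zz.mean()])
            labels.append(int(lab))
    pts = np.asarray(points, dtype=float) if points else np.zeros((0, 3))
    return FiducialSet(points=pts, modality=Modality.FIBSEM_VOL, labels=labels)
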