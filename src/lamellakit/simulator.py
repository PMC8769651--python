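"""Simulated dual-beam microscope and synthetic fixture generators.

The simulator stands in for the proprietary instrument driver: a voxelized
virtual specimen is milled by executing pattern sequences and imaged by
orthographic SEM/FIB renders, with stage-recall errors, linear drift and
per-current beam offsets injected so that realignment logic can be
exercised end to end.  Rendering is surface shading with Poisson noise, not
a physical SEM model -- sufficient for registration and closed-loop tests.

Drift is quasi-static: the misalignment is evaluated at the start of each
acquisition or milling command and held constant for its duration, so a
realignment immediately before a mill places the pattern to within the
phase-correlation accuracy.

The module also hosts every synthetic fixture generator used by the test
surface of the toolkit (bead fields, fluorescence blob volumes, curtaining,
charging hills, drifted stacks), each returning machine-readable ground
truth next to the data.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Protocol as TypingProtocol

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from ._phasecorr import subpixel_offset

from .exceptions import (
    ParamError,
    TruncatedStackWarning,
    ZeroConfidence,
)
from .frames import BeamGeometry, PixelGrid
from .milling_protocols import (
    LamellaTarget,
    PatternSequence,
    Protocol,
    SampleStats,
    ScanDirection,
    SessionPolicy,
    SessionStats,
    compile_lamella_patterns,
    volume_imaging_plan,
)
from .stack_postprocessing import SliceStack

__all__ = [
    "VirtualSpecimen",
    "InstrumentState",
    "DriverContract",
    "SimulatedDriver",
    "Correction",
    "realign",
    "realign_on_current_change",
    "SessionPosition",
    "PositionOutcome",
    "run_lamella_session",
    "run_volume_session",
    "synth_bead_image",
    "synth_flm_volume",
    "synth_curtain",
    "synth_charge",
    "synth_drift_stack",
]


# ---------------------------------------------------------------------------
# virtual specimen

@dataclass
class VirtualSpecimen:
    """Voxel label volume standing in for the frozen specimen.

    ``labels`` is ``(nz, ny, nx)`` with 0 = vacuum and positive integers for
    materials; z increases with depth below the surface.  ``mill_rates``
    give the volumetric ablation rate per material in um^3 per (nA s) --
    calibration constants of the virtual specimen, not physics claims.
    """

    labels: np.ndarray
    voxel_size_nm: float
    mill_rates: dict = field(default_factory=lambda: {1: 0.5})
    intensities: dict = field(default_factory=lambda: {1: 100.0})

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D volume")
        if self.voxel_size_nm <= 0:
            raise ValueError("voxel size must be positive")
        for lab in np.unique(self.labels):
            if lab and self.mill_rates.get(int(lab), 0) <= 0:
                raise ValueError(f"material {lab} needs a positive mill rate")

    @classmethod
    def uniform_block(cls, shape, voxel_size_nm: float, label: int = 1,
                      mill_rate: float = 0.5,
                      intensity: float = 100.0) -> "VirtualSpecimen":
        return cls(np.full(shape, label, dtype=np.uint8), voxel_size_nm,
                   {label: mill_rate}, {label: intensity})

    @property
    def voxel_volume_um3(self) -> float:
        return (self.voxel_size_nm / 1000.0) ** 3

    def material_voxels(self) -> int:
        return int(np.count_nonzero(self.labels))

    def surface_intensity(self) -> np.ndarray:
        """Top-down render: intensity of the first material voxel per column."""
        nz = self.labels.shape[0]
        occupied = self.labels > 0
        first = np.argmax(occupied, axis=0)
        empty = ~occupied.any(axis=0)
        surf = np.take_along_axis(self.labels, first[None], axis=0)[0]
        lut = np.zeros(int(self.labels.max()) + 1)
        for lab, val in self.intensities.items():
            if lab <= self.labels.max():
                lut[lab] = val
        img = lut[surf]
        img[empty] = 0.0
        return img


@dataclass
class InstrumentState:
    """Stage, beam and error-model state of the (simulated) instrument."""

    stage_um: np.ndarray = field(default_factory=lambda: np.zeros(2))
    tilt_deg: float = 0.0
    beam_shift_um: np.ndarray = field(default_factory=lambda: np.zeros(2))
    beam_shift_limit_um: float = 25.0
    current_pA: float = 30.0
    drift_nm_per_min: np.ndarray = field(default_factory=lambda: np.zeros(2))
    drift_suppression: bool = False
    clock_min: float = 0.0
    seed: int = 0
    stage_recall_error_um: float = 0.3
    current_offsets_um: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stage_um = np.asarray(self.stage_um, dtype=float).reshape(2)
        self.beam_shift_um = np.asarray(self.beam_shift_um, dtype=float).reshape(2)
        self.drift_nm_per_min = np.asarray(self.drift_nm_per_min,
                                           dtype=float).reshape(2)

    def drift_um(self) -> np.ndarray:
        if self.drift_suppression:
            return np.zeros(2)
        return self.drift_nm_per_min * self.clock_min / 1000.0


class DriverContract(TypingProtocol):
    """The operations any driver -- simulated or real -- must provide."""

    def acquire_image(self, beam: str = "SEM", settings: dict | None = None) -> np.ndarray: ...
    def mill(self, seq: PatternSequence) -> None: ...
    def move_stage(self, position_um) -> None: ...
    def apply_beam_shift(self, delta_um) -> None: ...
    def set_current(self, current_pA: float) -> None: ...


class SimulatedDriver:
    """Mock microscope driver operating on a :class:`VirtualSpecimen`.

    Image pixels coincide with specimen voxels (pixel size =
    ``specimen.voxel_size_nm``); images are renders of the specimen surface
    displaced by the current total misalignment (stage recall error + beam
    shift + accumulated drift + per-current beam offset).  Milling places
    pattern footprints with the same misalignment, so closed-loop
    realignment can be tested faithfully.  Every beam/stage operation is
    appended to ``log``.
    """

    def __init__(self, specimen: VirtualSpecimen, state: InstrumentState,
                 beam_geometry: BeamGeometry | None = None,
                 noise_scale: float = 0.05):
        self.specimen = specimen
        self.state = state
        self.beam = beam_geometry or BeamGeometry()
        self.noise_scale = noise_scale
        self.stage_error_um = np.zeros(2)
        self.log: list[dict] = []
        self._rng_recall = np.random.default_rng(state.seed + 101)

    # -- geometry helpers
    @property
    def pixel_size_nm(self) -> float:
        return self.specimen.voxel_size_nm

    def misalignment_um(self) -> np.ndarray:
        off = self.stage_error_um + self.state.beam_shift_um + self.state.drift_um()
        cur = self.state.current_offsets_um.get(self.state.current_pA)
        if cur is not None:
            off = off + np.asarray(cur, dtype=float)
        return off

    def _um_to_px(self, v_um) -> np.ndarray:
        return np.asarray(v_um, dtype=float) * 1000.0 / self.pixel_size_nm

    # -- DriverContract operations
    def acquire_image(self, beam: str = "SEM", settings: dict | None = None) -> np.ndarray:
        settings = settings or {}
        base = self.specimen.surface_intensity()
        if beam == "FIB":
            sin_a = np.sin(np.deg2rad(self.beam.inter_beam_angle))
            new_h = max(1, int(round(base.shape[0] * sin_a)))
            squeezed = resize(base, (new_h, base.shape[1]), order=1,
                              mode="constant", cval=0.0, anti_aliasing=False)
            img = np.zeros_like(base)
            img[:new_h] = squeezed
            base = img
        m_px = self._um_to_px(self.misalignment_um())
        if np.any(m_px != 0):
            base = ndimage.shift(base, (-m_px[1], -m_px[0]), order=1, cval=0.0)
        if self.noise_scale > 0 and base.max() > 0:
            # noise is a pure function of the seed and the view state, so an
            # unchanged instrument state reproduces the raster bit-for-bit
            # while any view change draws fresh, independent noise
            key = zlib.crc32(repr((beam, round(self.state.current_pA, 6),
                                   tuple(np.round(m_px, 6)))).encode())
            rng = np.random.default_rng([self.state.seed, key])
            lam = np.clip(base, 0, None) / self.noise_scale
            base = rng.poisson(lam).astype(float) * self.noise_scale
        self.log.append({"op": "acquire", "beam": beam,
                         "clock_min": self.state.clock_min})
        return base

    def move_stage(self, position_um) -> None:
        """Recall a stored stage position; injects a seeded recall error."""
        self.state.stage_um = np.asarray(position_um, dtype=float).reshape(2)
        err = self._rng_recall.normal(0.0, self.state.stage_recall_error_um, 2)
        self.stage_error_um = err
        self.log.append({"op": "move_stage", "position_um": list(self.state.stage_um),
                         "clock_min": self.state.clock_min})

    def correct_stage(self, offset_um) -> None:
        self.stage_error_um = self.stage_error_um - np.asarray(offset_um, float)
        self.log.append({"op": "stage_correction", "offset_um": list(offset_um)})

    def apply_beam_shift(self, delta_um) -> None:
        new = self.state.beam_shift_um + np.asarray(delta_um, dtype=float)
        if np.linalg.norm(new) > self.state.beam_shift_limit_um:
            raise ValueError("beam shift out of range; use a stage move")
        self.state.beam_shift_um = new
        self.log.append({"op": "beam_shift", "delta_um": list(np.asarray(delta_um))})

    def set_current(self, current_pA: float) -> None:
        self.state.current_pA = float(current_pA)
        self.log.append({"op": "set_current", "current_pA": float(current_pA)})

    def mill(self, seq: PatternSequence, reference_point_um=(0.0, 0.0)) -> None:
        """Execute a pattern sequence on the specimen.

        Footprints are positioned at ``reference_point_um + command.center``
        displaced by the current misalignment; voxels are removed
        front-to-back (increasing depth), rows ordered by scan direction,
        until the command's charge-time budget ``current * time`` divided by
        the per-material mill rate is exhausted (or the stated depth is
        reached).  Patterns falling entirely outside the specimen are
        skipped with a warning.
        """
        vs_um = self.specimen.voxel_size_nm / 1000.0
        labels = self.specimen.labels
        nz, ny, nx = labels.shape
        for cmd in seq.commands:
            offset = self.misalignment_um()
            cx = reference_point_um[0] + cmd.center[0] + offset[0]
            cy = reference_point_um[1] + cmd.center[1] + offset[1]
            x0 = int(np.round((cx - cmd.width / 2) / vs_um))
            x1 = int(np.round((cx + cmd.width / 2) / vs_um))
            y0 = int(np.round((cy - cmd.height / 2) / vs_um))
            y1 = int(np.round((cy + cmd.height / 2) / vs_um))
            x0c, x1c = max(0, x0), min(nx, x1)
            y0c, y1c = max(0, y0), min(ny, y1)
            if x0c >= x1c or y0c >= y1c:
                warnings.warn("pattern footprint outside the specimen; skipped",
                              UserWarning, stacklevel=2)
                continue
            if cmd.depth_is_time:
                budget_nAs = cmd.current * 1e-3 * cmd.depth_or_time  # pA->nA
                self._mill_budget(x0c, x1c, y0c, y1c, budget_nAs,
                                  cmd.scan_direction)
                self.state.clock_min += cmd.depth_or_time / 60.0
            else:
                z1 = min(nz, int(np.round(cmd.depth_or_time / vs_um)))
                labels[:z1, y0c:y1c, x0c:x1c] = 0
            self.log.append({"op": "mill", "shape": cmd.shape.value,
                             "center_um": [cx, cy],
                             "clock_min": self.state.clock_min})

    def _mill_budget(self, x0, x1, y0, y1, budget_nAs, scan_direction):
        labels = self.specimen.labels
        vvol = self.specimen.voxel_volume_um3
        cost_lut = np.zeros(int(labels.max()) + 1)
        for lab, rate in self.specimen.mill_rates.items():
            if lab <= labels.max():
                cost_lut[lab] = vvol / rate
        rows = list(range(y0, y1)) if scan_direction == ScanDirection.TOP_TO_BOTTOM \
            else list(range(y1 - 1, y0 - 1, -1))
        spent = 0.0
        for z in range(labels.shape[0]):
            for y in rows:
                line = labels[z, y, x0:x1]
                idx = np.nonzero(line)[0]
                if idx.size == 0:
                    continue
                cum = spent + np.cumsum(cost_lut[line[idx]])
                removable = idx[cum <= budget_nAs]
                line[removable] = 0
                spent = cum[removable.size - 1] if removable.size else spent
                if removable.size < idx.size:
                    return


# ---------------------------------------------------------------------------
# realignment

@dataclass(frozen=True)
class Correction:
    mode: str               # "stage" | "beam_shift"
    offset_um: tuple

    @property
    def magnitude_um(self) -> float:
        return float(np.linalg.norm(self.offset_um))


def realign(reference: np.ndarray, live: np.ndarray, grid: PixelGrid,
            stage_threshold_um: float = 10.0) -> Correction:
    """Measure the live-vs-reference offset and pick the correction mode.

    Subpixel phase correlation (10x upsampling) estimates the displacement
    of the live view relative to the stored reference; stage movements are
    used for offsets larger than the threshold (default 10 um) and beam
    shifts for subtle corrections.  Raises :class:`ZeroConfidence` for
    featureless images.
    """
    ref = np.asarray(reference, dtype=float)
    mov = np.asarray(live, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("reference and live images must have the same shape")
    if ref.std() == 0 or mov.std() == 0:
        raise ZeroConfidence("zero-signal image(s); cannot realign")
    # rendering displaces image content by minus the view offset, so the
    # measured content displacement is the negative of the offset change
    disp = subpixel_offset(ref, mov, upsample=10)
    offset_px = -np.array([disp[1], disp[0]])
    offset_um = offset_px * np.array([grid.pixel_size_x, grid.pixel_size_y]) / 1000.0
    mode = "stage" if np.linalg.norm(offset_um) > stage_threshold_um else "beam_shift"
    return Correction(mode=mode, offset_um=tuple(offset_um))


def apply_correction(driver: SimulatedDriver, corr: Correction) -> None:
    if corr.mode == "stage":
        driver.correct_stage(corr.offset_um)
    else:
        driver.apply_beam_shift(-np.asarray(corr.offset_um))


def realign_on_current_change(driver: SimulatedDriver, old_current: float,
                              new_current: float, grid: PixelGrid) -> Correction:
    """Beam-shift-only realignment across a FIB current change.

    A reference is taken at the previous current and a live image at the new
    current; the measured offset (dominated by the per-current beam
    misalignment) is always corrected with beam shifts, never the stage.
    """
    driver.set_current(old_current)
    ref = driver.acquire_image("FIB")
    driver.set_current(new_current)
    live = driver.acquire_image("FIB")
    corr = realign(ref, live, grid, stage_threshold_um=np.inf)
    return Correction(mode="beam_shift", offset_um=corr.offset_um)


# ---------------------------------------------------------------------------
# automated sessions

@dataclass
class SessionPosition:
    """A stored position of interest plus its lamella definition.

    ``location_um`` is the specimen-frame (x, y) of the lamella centre; the
    target geometry is expressed relative to that point.
    """

    name: str
    location_um: tuple
    target: LamellaTarget


@dataclass
class PositionOutcome:
    name: str
    rough_done: bool = False
    fine_done: bool = False
    failed: bool = False
    thickness_nm: float | None = None
    placement_error_nm: float | None = None


def _grid(driver: SimulatedDriver) -> PixelGrid:
    return PixelGrid(driver.pixel_size_nm, driver.pixel_size_nm)


def measure_lamella(specimen: VirtualSpecimen, location_um, depth_frac=0.5):
    """Thickness (nm) and centre offset (nm) of the slab left at a position.

    Scans the y-profile of remaining material at the lamella centre column
    and mid-depth, and returns the length of the contiguous run containing
    (or nearest) the intended centre, plus the offset of its midpoint.
    """
    vs = specimen.voxel_size_nm
    ix = int(round(location_um[0] * 1000.0 / vs))
    iy = int(round(location_um[1] * 1000.0 / vs))
    iz = int(specimen.labels.shape[0] * depth_frac)
    col = specimen.labels[iz, :, ix] > 0
    if not col.any():
        return None, None
    # contiguous runs of material
    padded = np.diff(np.concatenate([[0], col.astype(int), [0]]))
    starts, ends = np.nonzero(padded == 1)[0], np.nonzero(padded == -1)[0]
    centers = (starts + ends - 1) / 2.0
    best = int(np.argmin(np.abs(centers - iy)))
    thickness_nm = (ends[best] - starts[best]) * vs
    offset_nm = (centers[best] - iy) * vs
    return thickness_nm, offset_nm


def run_lamella_session(positions: list[SessionPosition], rough: Protocol,
                        fine: Protocol, driver: SimulatedDriver,
                        policy: SessionPolicy | None = None,
                        realign_enabled: bool = True,
                        imaging_current_pA: float = 10.0):
    """Automated two-phase milling: rough for all positions, then fine.

    On every position recall the stored reference image is re-registered
    against a fresh low-current view and the offset corrected (stage moves
    above the 10 um threshold, beam shifts below); before each milling step
    the current change is compensated with a beam-shift-only realignment.
    A realignment failure marks the position failed and the session
    continues.  Returns ``(SessionStats, outcomes, specimen)``.
    """
    policy = policy or SessionPolicy()
    grid = _grid(driver)
    outcomes = {p.name: PositionOutcome(p.name) for p in positions}
    references: dict[str, np.ndarray] = {}

    # session setup: store reference images per position
    for pos in positions:
        driver.move_stage(pos.location_um)
        driver.stage_error_um = np.zeros(2)  # setup views are taken aligned
        baseline = driver.misalignment_um().copy()
        references[pos.name] = (driver.acquire_image("FIB"), baseline)

    phases = [("rough", rough), ("fine", fine)] if policy.rough_before_fine \
        else [("fine", fine), ("rough", rough)]
    fine_elapsed_s = 0.0
    for phase_name, protocol in phases:
        for pos in positions:
            out = outcomes[pos.name]
            if out.failed:
                continue
            driver.move_stage(pos.location_um)

            def recall_realign():
                driver.set_current(imaging_current_pA)
                ref_img, _ = references[pos.name]
                live = driver.acquire_image("FIB")
                corr = realign(ref_img, live, grid)
                apply_correction(driver, corr)
                if corr.mode == "stage":  # refine with a beam shift pass
                    live = driver.acquire_image("FIB")
                    apply_correction(driver, realign(ref_img, live, grid))
                # refresh the reference from the corrected state so the next
                # registration spans only one milling step of surface change
                references[pos.name] = (driver.acquire_image("FIB"),
                                        driver.misalignment_um().copy())

            try:
                if realign_enabled:
                    recall_realign()
                for step in protocol.steps:
                    single = Protocol(protocol.name, (step,), protocol.stage)
                    seq = compile_lamella_patterns(single, pos.target)
                    for cmd in seq.commands:
                        if realign_enabled:
                            # re-register against the stored reference before
                            # every pattern: drift accrued while the previous
                            # one milled would otherwise go uncorrected
                            recall_realign()
                            corr = realign_on_current_change(
                                driver, imaging_current_pA, step.current, grid)
                            apply_correction(driver, corr)
                        driver.set_current(step.current)
                        driver.mill(PatternSequence(seq.reference_image, (cmd,)),
                                    reference_point_um=pos.location_um)
                    if phase_name == "fine":
                        fine_elapsed_s += step.time
            except ZeroConfidence:
                out.failed = True
                continue
            if phase_name == "rough":
                out.rough_done = True
            else:
                out.fine_done = True

    for pos in positions:
        out = outcomes[pos.name]
        t, e = measure_lamella(driver.specimen, pos.location_um)
        out.thickness_nm, out.placement_error_nm = t, e
        if t is None:
            out.failed = True
    n_fine = sum(1 for o in outcomes.values() if o.fine_done and not o.failed)
    stats = SessionStats([SampleStats("simulated", len(positions), n_fine, n_fine)])
    stats.contamination_nm = policy.contamination_nm(fine_elapsed_s)
    return stats, outcomes, driver.specimen


def run_volume_session(window, slice_thickness_nm: float, n_slices: int,
                       driver: SimulatedDriver) -> SliceStack:
    """Alternating slice-and-image acquisition of a FIB-SEM volume.

    Each cycle removes one slice of material from the current front (the
    exposed face, advancing with depth) and records an SEM render of the
    newly exposed cross-section.  If the front leaves the specimen the
    stack is truncated with a warning.  Slice thickness and beam geometry
    travel with the returned stack's metadata.
    """
    plan = volume_imaging_plan(window, slice_thickness_nm, n_slices)
    spec = driver.specimen
    vs = spec.voxel_size_nm
    front_nm = 0.0
    rng = np.random.default_rng(driver.state.seed + 7)
    slices = []
    lut = np.zeros(int(spec.labels.max()) + 1)
    for lab, val in spec.intensities.items():
        if lab <= spec.labels.max():
            lut[lab] = val
    for action in plan:
        if action.kind == "mill":
            front_nm += action.front_advance_nm
            front_vox = int(np.floor(front_nm / vs))
            if front_vox >= spec.labels.shape[0]:
                warnings.warn("milling front left the specimen; stack truncated",
                              TruncatedStackWarning, stacklevel=2)
                break
            spec.labels[:front_vox] = 0
            driver.state.clock_min += action.command.depth_or_time / 60.0
        else:
            front_vox = int(np.floor(front_nm / vs))
            face = lut[spec.labels[front_vox]]
            if driver.noise_scale > 0 and face.max() > 0:
                face = rng.poisson(np.clip(face, 0, None)
                                   / driver.noise_scale) * driver.noise_scale
            slices.append(face.astype(float))
    driver.front_nm = front_nm
    if not slices:
        slices = np.zeros((0, spec.labels.shape[1], spec.labels.shape[2]))
    grid = PixelGrid(vs, vs, slice_thickness=slice_thickness_nm)
    return SliceStack(np.asarray(slices), grid, driver.beam)


# ---------------------------------------------------------------------------
# synthetic fixture generators (seeds are mandatory)

def _require_seed(seed):
    if seed is None:
        raise ParamError("generators require an explicit seed")


def synth_bead_image(n: int, radius: float, snr: float, seed: int,
                     shape=(128, 128), min_separation: float | None = None):
    """Field of bright disks with known subpixel centres plus Gaussian noise.

    Centres are drawn uniformly with a minimum pairwise separation of
    ``4 * radius`` (rejection sampling) and at least ``2 * radius`` clear of
    the border.  Disk edges are softened over one pixel.  Noise sigma is
    ``1 / snr`` relative to the unit disk amplitude.  Returns
    ``(image, centers)`` with centers as ``(n, 2)`` (x, y).
    """
    _require_seed(seed)
    if n < 0 or radius < 1 or snr <= 0:
        raise ParamError("need n >= 0, radius >= 1, snr > 0")
    rng = np.random.default_rng(seed)
    sep = 4 * radius if min_separation is None else min_separation
    h, w = shape
    margin = 2 * radius
    centers = []
    for _ in range(10000):
        if len(centers) == n:
            break
        cand = rng.uniform([margin, margin], [w - margin, h - margin])
        if all(np.hypot(*(cand - c)) >= sep for c in centers):
            centers.append(cand)
    if len(centers) < n:
        raise ParamError("could not place beads at the requested separation")
    centers = np.asarray(centers).reshape(-1, 2)
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros(shape, dtype=float)
    for cx, cy in centers:
        dist = np.hypot(xx - cx, yy - cy)
        img = np.maximum(img, np.clip(radius + 0.5 - dist, 0.0, 1.0))
    img += rng.normal(0.0, 1.0 / snr, shape)
    return img, centers


def synth_flm_volume(blobs, psf_xyz, seed: int, shape=(32, 96, 96),
                     amplitude: float = 1.0, noise: float = 0.0):
    """Fluorescence z-stack of Gaussian blobs with an anisotropic PSF.

    ``blobs`` is either a count (centres drawn uniformly inside the volume
    with a one-PSF margin) or an ``(n, 3)`` array of (x, y, z) centres.
    ``psf_xyz`` are Gaussian sigmas (in voxels) along x, y and z -- sigma_z
    exceeding sigma_xy emulates the elongated axial response of dry
    objectives.  Returns ``(volume, centers)``.
    """
    _require_seed(seed)
    sx, sy, sz = psf_xyz
    if min(sx, sy, sz) <= 0:
        raise ParamError("PSF sigmas must be positive")
    rng = np.random.default_rng(seed)
    nz, ny, nx = shape
    if np.isscalar(blobs):
        m = np.array([3 * sx, 3 * sy, 3 * sz])
        lo = m
        hi = np.array([nx, ny, nz]) - 1 - m
        if np.any(hi <= lo):
            raise ParamError("volume too small for the PSF margin")
        centers = rng.uniform(lo, hi, size=(int(blobs), 3))
    else:
        centers = np.asarray(blobs, dtype=float).reshape(-1, 3)
    zz, yy, xx = np.mgrid[0:nz, 0:ny, 0:nx].astype(float)
    vol = np.zeros(shape, dtype=float)
    for cx, cy, cz in centers:
        vol += amplitude * np.exp(-((xx - cx) ** 2 / (2 * sx ** 2)
                                    + (yy - cy) ** 2 / (2 * sy ** 2)
                                    + (zz - cz) ** 2 / (2 * sz ** 2)))
    if noise > 0:
        vol += rng.normal(0.0, noise, shape)
    return vol, centers


def synth_curtain(image: np.ndarray, period: float, amplitude: float,
                  seed: int):
    """Add vertical curtaining stripes (constant along y) to an image.

    The stripe profile is a sinusoid of the given period with a seeded
    random phase, scaled by ``amplitude`` times the image dynamic range.
    Returns ``(striped_image, stripe_field)``.
    """
    _require_seed(seed)
    if period <= 0 or amplitude < 0:
        raise ParamError("period must be positive and amplitude >= 0")
    img = np.asarray(image, dtype=float)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    x = np.arange(img.shape[1], dtype=float)
    profile = np.sin(2 * np.pi * x / period + phase)
    scale = amplitude * (np.ptp(img) if np.ptp(img) > 0 else 1.0)
    stripes = np.broadcast_to(scale * profile, img.shape).copy()
    return img + stripes, stripes


def synth_charge(image: np.ndarray, sigma: float, amplitude: float,
                 center=None):
    """Add a broad additive Gaussian hill emulating a charging gradient."""
    if sigma <= 0:
        raise ParamError("sigma must be positive")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    cy, cx = (h / 2.0, w / 2.0) if center is None else (center[1], center[0])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    hill = amplitude * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma ** 2))
    return img + hill, hill


def synth_drift_stack(base: np.ndarray, drift_per_slice, n: int, seed: int):
    """Stack of ``n`` copies of ``base`` with a cumulative per-slice drift.

    Integer drifts are applied by exact rolling and fractional drifts as
    Fourier phase shifts, so both are exact (with periodic boundaries) and
    recoverable to the aligner's precision.  Returns ``(stack, offsets)``
    with ``offsets[i]`` the applied (dx, dy) of slice i.
    """
    _require_seed(seed)
    if n < 1:
        raise ParamError("need n >= 1 slices")
    base = np.asarray(base, dtype=float)
    d = np.asarray(drift_per_slice, dtype=float).reshape(2)
    offsets = np.outer(np.arange(n), d)
    slices = []
    for off in offsets:
        if np.allclose(off, np.round(off)):
            s = np.roll(base, (int(round(off[1])), int(round(off[0]))),
                        axis=(0, 1))
        else:
            s = np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(base),
                                                   (off[1], off[0]))).real
        slices.append(s)
    return np.asarray(slices), offsets
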