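"""Milling protocols, pattern sequences, and session/dose accounting.

A *protocol* is a small line-oriented text file describing the staged
removal of material (currents, times, pattern gaps per step).  The toolkit
compiles protocols against a user-defined lamella target into *pattern
sequence files*: ordered lists of milling commands (shape, position, size,
current, time) relative to a reference point, which a driver -- real or
simulated -- executes verbatim.  Also here: micro-expansion joints,
lift-out trench layouts, slice-and-image plans, electron-dose arithmetic,
and success/retention bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import NamedTuple

from .exceptions import EmptyInput, InvalidGeometry, InvalidTarget, ParseError
from .frames import Point2D

__all__ = [
    "MillingStep",
    "Protocol",
    "PatternShape",
    "ScanDirection",
    "PatternCommand",
    "PatternSequence",
    "LamellaTarget",
    "SampleStats",
    "SessionStats",
    "SessionPolicy",
    "parse_protocol",
    "write_protocol",
    "parse_pattern_sequence",
    "write_pattern_sequence",
    "compile_lamella_patterns",
    "expansion_joint_patterns",
    "compile_trench_patterns",
    "volume_imaging_plan",
    "electron_dose",
    "success_rate",
    "retention_rate",
]

ELEMENTARY_CHARGE_C = 1.602176634e-19


@dataclass(frozen=True)
class MillingStep:
    """One stage of material removal.

    current in pA, time in s, pattern_distance (gap between the upper and
    lower pattern inner edges) and pattern_height in um.  overtilt is
    stored as metadata only; it is never applied computationally.
    """

    current: float
    time: float
    pattern_distance: float = 0.0
    pattern_height: float = 5.0
    overtilt: float = 0.0

    def __post_init__(self):
        if self.current <= 0 or self.time <= 0:
            raise ValueError("current and time must be positive")
        if self.pattern_distance < 0 or self.pattern_height <= 0:
            raise ValueError("pattern distance must be >= 0 and height > 0")


@dataclass(frozen=True)
class Protocol:
    name: str
    steps: tuple
    stage: str = "rough"  # rough | fine

    def __post_init__(self):
        if not self.steps:
            raise ValueError("protocol needs at least one step")
        if self.stage not in ("rough", "fine"):
            raise ValueError("stage must be 'rough' or 'fine'")
        object.__setattr__(self, "steps", tuple(self.steps))


class PatternShape(str, Enum):
    RECTANGLE = "rectangle"
    CLEANING_CROSS_SECTION = "cleaning_cross_section"
    REGULAR_CROSS_SECTION = "regular_cross_section"


class ScanDirection(str, Enum):
    TOP_TO_BOTTOM = "top_to_bottom"
    BOTTOM_TO_TOP = "bottom_to_top"


@dataclass(frozen=True)
class PatternCommand:
    """A single milling operation.

    center is the pattern centre in um, relative to the sequence's
    reference point; y is positive downward as in the FIB image.
    depth_or_time is a milling time in s (the default driver currency) or a
    depth in um, disambiguated by ``depth_is_time``.
    """

    shape: PatternShape
    center: tuple
    width: float
    height: float
    depth_or_time: float
    current: float
    scan_direction: ScanDirection = ScanDirection.TOP_TO_BOTTOM
    depth_is_time: bool = True

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("pattern width and height must be positive")

    @property
    def footprint(self):
        """(x0, x1, y0, y1) bounding box in um relative to the reference."""
        cx, cy = self.center
        return (cx - self.width / 2, cx + self.width / 2,
                cy - self.height / 2, cy + self.height / 2)


@dataclass(frozen=True)
class PatternSequence:
    reference_image: str
    commands: tuple

    def __post_init__(self):
        object.__setattr__(self, "commands", tuple(self.commands))

    def __len__(self) -> int:
        return len(self.commands)

    def total_time(self) -> float:
        return sum(c.depth_or_time for c in self.commands if c.depth_is_time)


@dataclass(frozen=True)
class LamellaTarget:
    """Lamella geometry on the reference FIB image, all lengths in um.

    ``extremes`` are the (upper, lower) y-limits beyond which no pattern may
    mill -- they protect grid bars; y is positive downward, so
    upper < position.y < lower.
    """

    position: tuple
    width: float
    extremes: tuple
    expansion_joints: bool = False
    joint_width: float = 0.5
    joint_offset: float = 2.0
    joint_height: float | None = None

    def __post_init__(self):
        up, low = self.extremes
        if not up < self.position[1] < low:
            raise InvalidTarget("extremes must bracket the lamella position")
        if self.width <= 0:
            raise InvalidTarget("lamella width must be positive")


class SampleStats(NamedTuple):
    name: str
    target_sites: int
    fine_milled: int
    transferred: int | None = None
    thickness_range_nm: tuple | None = None


@dataclass
class SessionStats:
    samples: list

    def __post_init__(self):
        for s in self.samples:
            if s.fine_milled > s.target_sites:
                raise ValueError(f"{s.name}: fine_milled exceeds target sites")

    @property
    def total_sites(self) -> int:
        return sum(s.target_sites for s in self.samples)

    @property
    def total_lamellae(self) -> int:
        return sum(s.fine_milled for s in self.samples)


@dataclass(frozen=True)
class SessionPolicy:
    """Session-level scheduling and contamination bookkeeping.

    Rough milling runs for all positions before any fine milling starts, so
    finished lamellae spend as little time as possible exposed to residual
    water vapour.  The fine-milling time budget bounds that exposure; the
    condensation rate converts elapsed fine time into ice growth.
    """

    rough_before_fine: bool = True
    fine_time_budget_s: float = 3600.0
    condensation_rate_nm_per_hr: float = 50.0

    def contamination_nm(self, elapsed_fine_s: float) -> float:
        return self.condensation_rate_nm_per_hr * elapsed_fine_s / 3600.0


# ---------------------------------------------------------------------------
# protocol text format: "key: value" lines, one [step] header per step

_STEP_KEYS = ("current", "time", "pattern_distance", "pattern_height", "overtilt")
_REQUIRED_KEYS = ("current", "time")


def _fmt(v: float) -> str:
    return f"{v:g}"


def parse_protocol(text: str) -> Protocol:
    """Parse a protocol file; raises :class:`ParseError` with a line number."""
    name, stage = None, "rough"
    steps: list[MillingStep] = []
    current_block: dict | None = None
    block_line = 0

    def close_block():
        nonlocal current_block
        if current_block is None:
            return
        for key in _REQUIRED_KEYS:
            if key not in current_block:
                raise ParseError(f"step is missing required field '{key}'", block_line)
        try:
            steps.append(MillingStep(**current_block))
        except (TypeError, ValueError) as exc:
            raise ParseError(str(exc), block_line) from exc
        current_block = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line == "[step]":
            close_block()
            current_block, block_line = {}, lineno
            continue
        if ":" not in line:
            raise ParseError(f"expected 'key: value', got {raw.strip()!r}", lineno)
        key, value = (part.strip() for part in line.split(":", 1))
        if current_block is None:
            if key == "name":
                name = value
            elif key == "stage":
                stage = value
            else:
                raise ParseError(f"unknown header field '{key}'", lineno)
        else:
            if key not in _STEP_KEYS:
                raise ParseError(f"unknown step field '{key}'", lineno)
            try:
                current_block[key] = float(value)
            except ValueError:
                raise ParseError(f"field '{key}' is not a number: {value!r}", lineno)
    close_block()
    if name is None:
        raise ParseError("protocol has no 'name' field")
    if not steps:
        raise ParseError("protocol has no [step] blocks")
    try:
        return Protocol(name=name, steps=tuple(steps), stage=stage)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def write_protocol(protocol: Protocol) -> str:
    """Serialize a protocol to its canonical text form (round-trip safe)."""
    lines = [f"name: {protocol.name}", f"stage: {protocol.stage}", ""]
    for step in protocol.steps:
        lines.append("[step]")
        for key in _STEP_KEYS:
            lines.append(f"{key}: {_fmt(getattr(step, key))}")
        lines.append("")
    return "\n".join(lines).rstrip("\n") + "\n"


def write_pattern_sequence(seq: PatternSequence) -> str:
    """Serialize to one tab-separated command per line, '#' comments allowed."""
    lines = [f"# reference_image: {seq.reference_image}",
             "# shape\tcx\tcy\twidth\theight\tdepth_or_time\tcurrent\tscan\tunit"]
    for c in seq.commands:
        lines.append("\t".join([
            c.shape.value, _fmt(c.center[0]), _fmt(c.center[1]), _fmt(c.width),
            _fmt(c.height), _fmt(c.depth_or_time), _fmt(c.current),
            c.scan_direction.value, "s" if c.depth_is_time else "um"]))
    return "\n".join(lines) + "\n"


def parse_pattern_sequence(text: str) -> PatternSequence:
    reference = ""
    commands = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("# reference_image:"):
            reference = line.split(":", 1)[1].strip()
            continue
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ParseError(f"expected 9 tab-separated fields, got {len(parts)}",
                             lineno)
        try:
            commands.append(PatternCommand(
                shape=PatternShape(parts[0]),
                center=(float(parts[1]), float(parts[2])),
                width=float(parts[3]), height=float(parts[4]),
                depth_or_time=float(parts[5]), current=float(parts[6]),
                scan_direction=ScanDirection(parts[7]),
                depth_is_time=parts[8] == "s"))
        except ValueError as exc:
            raise ParseError(str(exc), lineno) from exc
    return PatternSequence(reference_image=reference, commands=tuple(commands))


# ---------------------------------------------------------------------------
# pattern compilation

def compile_lamella_patterns(protocol: Protocol, target: LamellaTarget,
                             reference_image: str = "") -> PatternSequence:
    """Compile a lamella protocol into its pattern sequence.

    Per step, two patterns are emitted (upper first), their inner edges at
    half the step's pattern distance from the lamella centre and their outer
    edges clipped at the extreme milling points.  Centres are relative to
    the lamella position.  Upper patterns scan top-to-bottom and lower ones
    bottom-to-top so material is always removed toward the lamella face.
    """
    up, low = target.extremes
    yc = target.position[1]
    commands = []
    for step in protocol.steps:
        half_gap = step.pattern_distance / 2.0
        upper_h = min(step.pattern_height, (yc - half_gap) - up)
        lower_h = min(step.pattern_height, low - (yc + half_gap))
        if upper_h <= 0 or lower_h <= 0:
            raise InvalidTarget(
                "pattern gap does not fit between the extreme milling points")
        commands.append(PatternCommand(
            shape=PatternShape.CLEANING_CROSS_SECTION,
            center=(0.0, -(half_gap + upper_h / 2.0)),
            width=target.width, height=upper_h,
            depth_or_time=step.time, current=step.current,
            scan_direction=ScanDirection.TOP_TO_BOTTOM))
        commands.append(PatternCommand(
            shape=PatternShape.CLEANING_CROSS_SECTION,
            center=(0.0, half_gap + lower_h / 2.0),
            width=target.width, height=lower_h,
            depth_or_time=step.time, current=step.current,
            scan_direction=ScanDirection.BOTTOM_TO_TOP))
    return PatternSequence(reference_image=reference_image,
                           commands=tuple(commands))


def expansion_joint_patterns(target: LamellaTarget, time_s: float = 30.0,
                             current_pA: float = 1000.0,
                             reference_image: str = "") -> PatternSequence:
    """Stress-relief cuts flanking the lamella, milled before rough milling.

    Two narrow rectangles mirror-symmetric about the lamella centre at
    ``x = +-(width/2 + joint_offset)``.  Returns an empty sequence when the
    target does not request joints.  Joint dimensions are configurable on
    the target (the defaults are pragmatic values, not instrument-mandated).
    """
    if not target.expansion_joints:
        return PatternSequence(reference_image=reference_image, commands=())
    up, low = target.extremes
    height = target.joint_height if target.joint_height is not None else (low - up)
    xoff = target.width / 2.0 + target.joint_offset
    commands = tuple(
        PatternCommand(shape=PatternShape.RECTANGLE, center=(sign * xoff, 0.0),
                       width=target.joint_width, height=height,
                       depth_or_time=time_s, current=current_pA)
        for sign in (-1.0, 1.0))
    return PatternSequence(reference_image=reference_image, commands=commands)


def _overlaps(a, b) -> bool:
    ax0, ax1, ay0, ay1 = a
    bx0, bx1, by0, by1 = b
    return ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1


def compile_trench_patterns(chunk_width: float = 20.0, chunk_depth_y: float = 20.0,
                            trench_w: float = 40.0, trench_h: float = 15.0,
                            side_offset: float = 15.0, side_trench_w: float = 10.0,
                            side_trench_h: float = 40.0, side: str = "left",
                            time_s: float = 600.0, current_pA: float = 1000.0,
                            reference_image: str = "") -> PatternSequence:
    """Horseshoe ("C-shape") trench layout for lift-out site preparation.

    Two parallel trenches are arranged symmetrically around the central
    extraction block (separated by ``chunk_depth_y``), and a third trench is
    milled perpendicular to them, offset laterally from the end of the
    parallel trenches, leaving the block attached on one side only.  All
    patterns are regular cross-sections centred on the reference point.
    """
    dims = (chunk_width, chunk_depth_y, trench_w, trench_h,
            side_offset, side_trench_w, side_trench_h)
    if any(d <= 0 for d in dims):
        raise InvalidGeometry("all trench dimensions must be positive")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    mirror = -1.0 if side == "right" else 1.0

    cy = chunk_depth_y / 2.0 + trench_h / 2.0
    # side trench: its left edge sits side_offset beyond the left end of the
    # parallel trenches (offset direction mirrored for side='right')
    side_cx = mirror * (-(trench_w / 2.0 + side_offset) + side_trench_w / 2.0)
    commands = (
        PatternCommand(PatternShape.REGULAR_CROSS_SECTION, (0.0, -cy),
                       trench_w, trench_h, time_s, current_pA,
                       ScanDirection.TOP_TO_BOTTOM),
        PatternCommand(PatternShape.REGULAR_CROSS_SECTION, (0.0, cy),
                       trench_w, trench_h, time_s, current_pA,
                       ScanDirection.BOTTOM_TO_TOP),
        PatternCommand(PatternShape.REGULAR_CROSS_SECTION, (side_cx, 0.0),
                       side_trench_w, side_trench_h, time_s, current_pA,
                       ScanDirection.TOP_TO_BOTTOM),
    )
    block = (-chunk_width / 2.0, chunk_width / 2.0,
             -chunk_depth_y / 2.0, chunk_depth_y / 2.0)
    for c in commands:
        if _overlaps(c.footprint, block):
            raise InvalidGeometry("trench pattern overlaps the extraction block")
    return PatternSequence(reference_image=reference_image, commands=commands)


class PlanAction(NamedTuple):
    kind: str                       # "mill" | "acquire"
    front_advance_nm: float         # 0 for acquisitions
    command: PatternCommand | None = None


def volume_imaging_plan(window, slice_thickness_nm: float, n_slices: int,
                        current_pA: float = 500.0,
                        mill_time_s: float = 15.0) -> list[PlanAction]:
    """Interleaved slice-and-image plan for FIB-SEM volume acquisition.

    ``window`` is ``(width_um, height_um)`` of the imaging window.  Returns
    ``2 * n_slices`` actions alternating mill/acquire; each mill advances
    the exposed front by one slice thickness.
    """
    if n_slices < 0:
        raise ValueError("n_slices must be >= 0")
    if n_slices and slice_thickness_nm <= 0:
        raise ValueError("slice thickness must be positive")
    w, h = window
    plan = []
    for _ in range(n_slices):
        cmd = PatternCommand(PatternShape.REGULAR_CROSS_SECTION, (0.0, 0.0),
                             w, h, mill_time_s, current_pA)
        plan.append(PlanAction("mill", slice_thickness_nm, cmd))
        plan.append(PlanAction("acquire", 0.0))
    return plan


def electron_dose(current_pA: float, dwell_us: float, line_integration: int,
                  pixel_size_nm: float) -> float:
    """Electron dose per image in e/A^2.

    dose = current * dwell * line_integration / (e * pixel_area), i.e. the
    number of electrons deposited per pixel divided by the pixel footprint
    (1 nm^2 = 100 A^2).
    """
    if min(current_pA, dwell_us, line_integration, pixel_size_nm) < 0:
        raise ValueError("dose inputs must be non-negative")
    electrons = current_pA * 1e-12 * dwell_us * 1e-6 * line_integration \
        / ELEMENTARY_CHARGE_C
    area_A2 = (pixel_size_nm * 10.0) ** 2
    return electrons / area_A2


def success_rate(stats: SessionStats) -> float:
    """Overall milling success: fine-milled lamellae per target site, in %."""
    total = stats.total_sites
    if total == 0:
        raise ZeroDivisionError("no target sites")
    return round(100.0 * stats.total_lamellae / total, 1)


def retention_rate(retained: int, total: int) -> float:
    """Percentage of lamellae that retained the targeted structure."""
    if total == 0:
        raise ZeroDivisionError("no lamellae")
    if retained > total or retained < 0:
        raise ValueError("retained must be between 0 and total")
    return round(100.0 * retained / total, 1)
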