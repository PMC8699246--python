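"""Dot-and-crosshairs guidance logic.

Maps the current detections and lumen fits to a display state: a dot
whose offset is a gain-scheduled function of the lateral distance
between the projected needle path and the target-vessel centroid, a
red/yellow/green color code, hazard cues (bifurcation in view, an
untargeted vessel interposed on the needle path), and a readiness flag.
The needle may only be released when the lateral offset falls inside
the dynamic insertion window — 10% of the target vessel diameter, so
1 mm for a 1 cm vessel — and the path to the target is clear.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detection import CUE_MOVE_CRANIAL, Detection, detect_bifurcation_cue
from .segmentation import VesselFit

__all__ = [
    "GuidanceConfig",
    "GuidanceState",
    "GuidanceSession",
    "SafetyResult",
    "insertion_window",
    "safety_check",
    "update_guidance",
    "HAZARD_NONE",
    "HAZARD_CRANIAL",
    "HAZARD_CAUDAL",
    "RED",
    "YELLOW",
    "GREEN",
]

HAZARD_NONE = "none"
HAZARD_CRANIAL = "reposition-cranial"
HAZARD_CAUDAL = "reposition-caudal"
RED, YELLOW, GREEN = "red", "yellow", "green"
_COLOR_RANK = {RED: 0, YELLOW: 1, GREEN: 2}


@dataclass(frozen=True)
class GuidanceConfig:
    window_fraction: float = 0.10
    yellow_radius_mm: float = 5.0
    gain_coarse: float = 1.0   # display mm per device mm, far from target
    gain_fine: float = 3.0     # display mm per device mm, near target
    target_class: str = "vein"
    hysteresis_frames: int = 3
    stale_target_downgrades: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.window_fraction < 1.0:
            raise ValueError("window_fraction must be in (0, 1)")
        if self.gain_coarse <= 0 or self.gain_fine <= 0:
            raise ValueError("gains must be positive")


@dataclass(frozen=True)
class GuidanceState:
    dot_offset_display: float
    color: str
    hazard: str
    safety_ok: bool
    ready: bool
    window_mm: float
    lateral_offset_mm: float | None = None

    def __post_init__(self) -> None:
        if self.ready and not (self.color == GREEN and self.safety_ok
                               and self.hazard == HAZARD_NONE):
            raise ValueError("ready requires green, safe, and no hazard")


@dataclass(frozen=True)
class SafetyResult:
    safe: bool
    blocking_class: str | None = None


def insertion_window(diameter_mm: float, window_fraction: float = 0.10) -> float:
    """Half-width of the dynamic insertion window: 10% of vessel diameter."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    return window_fraction * diameter_mm


def _segment_ellipse_intersection(p0: np.ndarray, p1: np.ndarray,
                                  fit: VesselFit) -> bool:
    """Does segment p0->p1 touch the ellipse (boundary or interior)?

    Analytic: map the ellipse to the unit circle and solve the quadratic
    |q0 + t (q1 - q0)|^2 = 1 for t in [0, 1]; also catch the
    fully-interior case.
    """
    cx, cy = fit.center_mm
    a, b = fit.semi_axes_mm
    theta = math.radians(fit.rotation_deg)
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    def to_unit(p):
        dx, dy = p[0] - cx, p[1] - cy
        u = (cos_t * dx + sin_t * dy) / a
        v = (-sin_t * dx + cos_t * dy) / b
        return np.array([u, v])

    q0, q1 = to_unit(p0), to_unit(p1)
    if q0 @ q0 <= 1.0 or q1 @ q1 <= 1.0:
        return True
    d = q1 - q0
    aa = d @ d
    if aa == 0.0:
        return False
    bb = 2.0 * (q0 @ d)
    cc = q0 @ q0 - 1.0
    disc = bb * bb - 4.0 * aa * cc
    if disc < 0:
        return False
    sq = math.sqrt(disc)
    for t in ((-bb - sq) / (2 * aa), (-bb + sq) / (2 * aa)):
        if 0.0 <= t <= 1.0:
            return True
    return False


def safety_check(needle_path: tuple[tuple[float, float], tuple[float, float]],
                 target_fit: VesselFit,
                 other_fits: list[VesselFit]) -> SafetyResult:
    """Unsafe iff an untargeted vessel sits on the path to the target.

    ``needle_path`` is a transverse-plane segment from the skin (depth 0)
    to the target centroid; intersection with each non-target ellipse is
    computed analytically.
    """
    (x0, y0), (x1, y1) = needle_path
    if abs(y0) > 1e-9:
        raise ValueError("needle path must start at the skin (depth 0)")
    tx, ty = target_fit.center_mm
    if abs(x1 - tx) > 1e-6 or abs(y1 - ty) > 1e-6:
        raise ValueError("needle path must end at the target centroid")
    p0 = np.array([x0, y0], dtype=float)
    p1 = np.array([x1, y1], dtype=float)
    for fit in other_fits:
        if fit.cls == target_fit.cls:
            continue
        if _segment_ellipse_intersection(p0, p1, fit):
            return SafetyResult(safe=False, blocking_class=fit.cls)
    return SafetyResult(safe=True)


def update_guidance(detections: list[Detection],
                    fits: list[VesselFit],
                    config: GuidanceConfig | None = None,
                    geometry=None,
                    cc_hazard: str = HAZARD_NONE) -> GuidanceState:
    """Pure per-frame guidance update.

    The projected needle path lies in the elevational plane through the
    probe centre, so its lateral coordinate at any depth is 0 in the
    device frame and the tracking error is simply the target centroid's
    lateral offset.  Color code: red when the target is absent or far,
    yellow inside the approach radius, green only when the offset is
    inside the dynamic window, the path is safe, no hazard is active and
    the target fit is current (stale fits keep the state at yellow).
    ``cc_hazard`` lets a caller inject a cranio-caudal positioning hazard
    (e.g. outside the access-length window).
    """
    config = config or GuidanceConfig()
    target = next((f for f in fits if f.cls == config.target_class), None)
    cue = detect_bifurcation_cue(detections)

    if target is None:
        hazard = HAZARD_CRANIAL if cue == CUE_MOVE_CRANIAL else cc_hazard
        return GuidanceState(dot_offset_display=0.0, color=RED, hazard=hazard,
                             safety_ok=False, ready=False, window_mm=0.0,
                             lateral_offset_mm=None)

    x = target.center_mm[0]
    window = insertion_window(target.effective_diameter_mm,
                              config.window_fraction)
    others = [f for f in fits if f is not target]
    safety = safety_check(((0.0, 0.0), target.center_mm), target, others)

    hazard = HAZARD_NONE
    if cue == CUE_MOVE_CRANIAL:
        hazard = HAZARD_CRANIAL
    elif not safety.safe:
        hazard = HAZARD_CRANIAL  # common femoral segment lies cranially
    elif cc_hazard != HAZARD_NONE:
        hazard = cc_hazard

    gain = config.gain_fine if abs(x) <= config.yellow_radius_mm \
        else config.gain_coarse
    dot = gain * x

    if abs(x) > config.yellow_radius_mm:
        color = RED
    elif (abs(x) <= window and safety.safe and hazard == HAZARD_NONE
          and target.age == 0):
        color = GREEN
    else:
        color = YELLOW

    return GuidanceState(dot_offset_display=dot, color=color, hazard=hazard,
                         safety_ok=safety.safe, ready=(color == GREEN),
                         window_mm=window, lateral_offset_mm=x)


class GuidanceSession:
    """Stateful wrapper adding color hysteresis across frames.

    A color upgrade (red -> yellow -> green) must persist for
    ``hysteresis_frames`` consecutive raw frames before it is displayed;
    downgrades apply immediately.  This suppresses flicker near the
    window boundary without ever displaying green in an unsafe frame.
    """

    def __init__(self, config: GuidanceConfig | None = None):
        self.config = config or GuidanceConfig()
        self._displayed = RED
        self._pending: str | None = None
        self._pending_count = 0

    def update(self, detections: list[Detection], fits: list[VesselFit],
               cc_hazard: str = HAZARD_NONE) -> GuidanceState:
        raw = update_guidance(detections, fits, self.config,
                              cc_hazard=cc_hazard)
        if _COLOR_RANK[raw.color] <= _COLOR_RANK[self._displayed]:
            self._displayed = raw.color
            self._pending, self._pending_count = None, 0
        else:
            if raw.color == self._pending:
                self._pending_count += 1
            else:
                self._pending, self._pending_count = raw.color, 1
            if self._pending_count >= self.config.hysteresis_frames:
                self._displayed = raw.color
                self._pending, self._pending_count = None, 0
        color = self._displayed
        ready = (color == GREEN and raw.safety_ok
                 and raw.hazard == HAZARD_NONE)
        return GuidanceState(dot_offset_display=raw.dot_offset_display,
                             color=color, hazard=raw.hazard,
                             safety_ok=raw.safety_ok, ready=ready,
                             window_mm=raw.window_mm,
                             lateral_offset_mm=raw.lateral_offset_mm)
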