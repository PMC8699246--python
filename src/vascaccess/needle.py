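"""Needle trajectory planning and closed-loop insertion simulation.

Planning converts a fitted target lumen into an insertion angle and a
sequence of along-path waypoints with commanded speeds:

====  =================================  ============
 WP    location                           speed (mm/s)
====  =================================  ============
 A     1 mm short of the posterior wall   45
 B     vessel centroid                    20
 C     posterior wall                     10
 D     anterior wall                      10
 E     vessel centroid                    10
====  =================================  ============

The fast initial leg overshoots the centroid to defeat wall tenting;
the slow C/D/E legs are the dither retry that gives an optical
flashback sensor time to confirm intravascular placement.  The
simulator executes a plan against ground-truth anatomy with kickback
at skin puncture, rigid-offset anterior-wall tenting, per-sample
flashback checks (motion stops immediately on blood), and
retract-and-retry attempts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .phantom import AnatomyInstance
from .segmentation import VesselFit

__all__ = [
    "NeedleGeometry",
    "Waypoint",
    "NeedlePlan",
    "TissueParams",
    "InsertionResult",
    "PlanningError",
    "plan_trajectory",
    "plan_duration",
    "flashback_sample",
    "simulate_insertion",
    "confirm_by_image",
    "WAYPOINT_SPEEDS",
]

WAYPOINT_SPEEDS = {"A": 45.0, "B": 20.0, "C": 10.0, "D": 10.0, "E": 10.0}


class PlanningError(ValueError):
    """Raised when a target geometry cannot be reached by the needle."""


@dataclass(frozen=True)
class NeedleGeometry:
    """Fixed device geometry: entry point offset and needle length."""

    entry_offset_mm: float = 15.0   # skin distance, imaging plane to entry
    needle_length_mm: float = 90.0  # 9 cm 18G angiographic needle
    gauge: str = "18G"

    def __post_init__(self) -> None:
        if self.entry_offset_mm <= 0:
            raise ValueError("entry_offset_mm must be positive")
        if self.needle_length_mm <= 0:
            raise ValueError("needle_length_mm must be positive")


@dataclass(frozen=True)
class Waypoint:
    label: str
    position_mm: float   # along-path distance from the skin entry point
    speed_mm_s: float

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValueError("waypoint speed must be positive")


@dataclass(frozen=True)
class NeedlePlan:
    angle_deg: float
    anterior_wall_mm: float
    centroid_mm: float
    posterior_wall_mm: float
    waypoints: tuple[Waypoint, ...]

    def __post_init__(self) -> None:
        pos = {wp.label: wp.position_mm for wp in self.waypoints}
        if not (pos["D"] < pos["B"] == pos["E"] < pos["A"] < pos["C"]):
            raise PlanningError("waypoints must satisfy D < B = E < A < C")


def plan_trajectory(target_fit: VesselFit,
                    geometry: NeedleGeometry | None = None) -> NeedlePlan:
    """Plan insertion angle and waypoints for a fitted target lumen.

    The needle travels in the elevational plane; its angle from the skin
    surface is ``arctan(centroid depth / entry offset)``.  Along the
    straight path the lumen is treated as a circle of the vessel's
    effective radius, so the anterior wall, centroid, and posterior wall
    sit at L - r, L, and L + r where L is the Euclidean entry-to-centroid
    distance.
    """
    geometry = geometry or NeedleGeometry()
    depth = target_fit.center_mm[1]
    radius = target_fit.effective_diameter_mm / 2.0
    if depth <= 0 or radius <= 0:
        raise PlanningError("target depth and diameter must be positive")
    if 2.0 * radius <= 2.0:
        raise PlanningError(
            "vessel too small for a 1 mm posterior-wall overshoot margin")
    angle = math.degrees(math.atan2(depth, geometry.entry_offset_mm))
    centroid = math.hypot(depth, geometry.entry_offset_mm)
    anterior = centroid - radius
    posterior = centroid + radius
    if posterior > geometry.needle_length_mm:
        raise PlanningError(
            f"required path {posterior:.1f} mm exceeds the "
            f"{geometry.needle_length_mm:.0f} mm needle")
    waypoints = tuple(
        Waypoint(label, position, WAYPOINT_SPEEDS[label])
        for label, position in (("A", posterior - 1.0), ("B", centroid),
                                ("C", posterior), ("D", anterior),
                                ("E", centroid)))
    return NeedlePlan(angle_deg=angle, anterior_wall_mm=anterior,
                      centroid_mm=centroid, posterior_wall_mm=posterior,
                      waypoints=waypoints)


def plan_duration(plan: NeedlePlan) -> float:
    """Total travel time: sum of |leg length| / leg speed from the entry."""
    t = 0.0
    position = 0.0
    for wp in plan.waypoints:
        t += abs(wp.position_mm - position) / wp.speed_mm_s
        position = wp.position_mm
    return t


@dataclass(frozen=True)
class TissueParams:
    """Needle-tissue interaction parameters for one simulated subject."""

    tenting_capacity_mm: float = 4.5
    kickback_sd_mm: float = 0.5
    kickback_sd_deg: float = 0.5
    flashback_sample_rate_hz: float = 100.0
    max_dither_cycles: int = 1
    max_attempts_per_trial: int = 3
    # per-attempt lognormal jitter on the effective tenting capacity;
    # 0 recovers a fully deterministic wall
    capacity_jitter_sd: float = 0.25
    flashback_delay_samples: int = 0

    def __post_init__(self) -> None:
        for name in ("tenting_capacity_mm", "kickback_sd_mm",
                     "kickback_sd_deg", "flashback_sample_rate_hz",
                     "capacity_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.max_attempts_per_trial < 1 or self.max_dither_cycles < 0:
            raise ValueError("attempt/dither counts must be positive")


@dataclass(frozen=True)
class InsertionResult:
    attempts: int
    success: bool
    flashback_time_s: float | None
    stop_position_mm: float
    tip_in_lumen_at_stop: bool
    posterior_wall_punctured: bool
    events: tuple[tuple[float, str], ...] = ()

    def __post_init__(self) -> None:
        if self.success and (not self.tip_in_lumen_at_stop
                             or self.flashback_time_s is None):
            raise ValueError("success requires an intra-luminal stop with "
                             "a recorded flashback time")


def flashback_sample(tip_position_mm: float, anterior_wall_mm: float,
                     posterior_wall_mm: float, punctured: bool) -> bool:
    """Blood iff the wall is punctured and the tip is intra-luminal."""
    return punctured and anterior_wall_mm < tip_position_mm < posterior_wall_mm


def _true_walls(plan: NeedlePlan, anatomy: AnatomyInstance,
                lateral_error_mm: float) -> tuple[float, float] | None:
    """Ground-truth wall crossings along the planned path, or None on miss.

    The path is laterally offset from the true vein centre by
    ``lateral_error_mm``; the lumen cross-section in the needle plane is
    a circle of the vein's effective radius centred at the planned
    centroid distance.
    """
    r = anatomy.vein.effective_diameter_mm / 2.0
    if abs(lateral_error_mm) >= r:
        return None
    half_chord = math.sqrt(r * r - lateral_error_mm * lateral_error_mm)
    return (plan.centroid_mm - half_chord, plan.centroid_mm + half_chord)


def simulate_insertion(plan: NeedlePlan, anatomy: AnatomyInstance,
                       tissue: TissueParams, lateral_error_mm: float = 0.0,
                       seed: int = 0) -> InsertionResult:
    """Execute a plan against ground-truth anatomy at the sample rate.

    Per attempt: a kickback perturbation (lateral + angular Gaussian,
    applied once at skin puncture) shifts the path off the true vein
    centre; the anterior wall then deflects with the advancing tip
    (rigid-offset tenting) and punctures the instant the deflection
    exceeds the effective tenting capacity, recovering whenever the tip
    reverses.  The flashback sensor is evaluated every sample and halts
    motion immediately on blood.  A full waypoint pass without flashback
    fails the attempt; the needle retracts and retries up to
    ``max_attempts_per_trial``.
    """
    if seed is None or int(seed) != seed:
        raise ValueError("seed must be an integer")
    rng = np.random.default_rng(int(seed))
    dt = 1.0 / tissue.flashback_sample_rate_hz
    depth = plan.centroid_mm * math.sin(math.radians(plan.angle_deg))

    events: list[tuple[float, str]] = []
    time = 0.0
    posterior_punctured = False
    stop_position = 0.0
    tip_in_lumen = False

    for attempt in range(1, tissue.max_attempts_per_trial + 1):
        kick_lat = rng.normal(0.0, tissue.kickback_sd_mm) \
            if tissue.kickback_sd_mm > 0 else 0.0
        kick_deg = rng.normal(0.0, tissue.kickback_sd_deg) \
            if tissue.kickback_sd_deg > 0 else 0.0
        total_lateral = (lateral_error_mm + kick_lat
                         + math.tan(math.radians(kick_deg)) * depth)
        capacity = tissue.tenting_capacity_mm
        if tissue.capacity_jitter_sd > 0:
            capacity *= math.exp(rng.normal(0.0, tissue.capacity_jitter_sd))
        walls = _true_walls(plan, anatomy, total_lateral)
        events.append((time, f"attempt {attempt} start "
                             f"(lateral {total_lateral:+.2f} mm)"))

        s = 0.0
        punctured = False
        blood_samples = 0
        flashback_time = None

        legs = list(plan.waypoints)
        dither = [wp for wp in plan.waypoints if wp.label in ("C", "D", "E")]
        for _ in range(max(0, tissue.max_dither_cycles - 1)):
            legs.extend(dither)  # extra C-D-E dither passes, if configured
        for wp in legs:
            direction = 1.0 if wp.position_mm >= s else -1.0
            while (s - wp.position_mm) * direction < -1e-12:
                step = min(wp.speed_mm_s * dt,
                           abs(wp.position_mm - s))
                s += direction * step
                time += dt
                if walls is not None:
                    anterior, posterior = walls
                    if not punctured and s > anterior:
                        deflection = s - anterior
                        if deflection > capacity:
                            punctured = True
                            events.append((time, f"puncture at {s:.2f} mm"))
                    if punctured and s >= posterior:
                        posterior_punctured = True
                        events.append((time, "posterior wall breached"))
                    if flashback_sample(s, anterior, posterior, punctured):
                        blood_samples += 1
                        if blood_samples > tissue.flashback_delay_samples:
                            flashback_time = time
                            break
                    else:
                        blood_samples = 0
            if flashback_time is not None:
                break

        if flashback_time is not None:
            events.append((time, f"flashback at {s:.2f} mm"))
            return InsertionResult(
                attempts=attempt, success=True,
                flashback_time_s=flashback_time, stop_position_mm=s,
                tip_in_lumen_at_stop=True,
                posterior_wall_punctured=posterior_punctured,
                events=tuple(events))

        # retract and reset for a fresh attempt
        time += s / WAYPOINT_SPEEDS["A"]
        events.append((time, f"attempt {attempt} failed, retracted"))
        stop_position = 0.0

    return InsertionResult(attempts=tissue.max_attempts_per_trial,
                           success=False, flashback_time_s=None,
                           stop_position_mm=stop_position,
                           tip_in_lumen_at_stop=tip_in_lumen,
                           posterior_wall_punctured=posterior_punctured,
                           events=tuple(events))


def confirm_by_image(pre_frame, post_frame, predicted_tip_mm: tuple[float, float],
                     roi_radius_mm: float, threshold: float = 8.0) -> bool:
    """Image-change confirmation of needle insertion (secondary sensor).

    Compares mean absolute intensity change inside a circular ROI around
    the predicted tip position; returns True when it exceeds the
    threshold.  This check never overrides flashback — it is an adjunct
    the caller may consult when no flashback was sensed.
    """
    if pre_frame.pixels.shape != post_frame.pixels.shape:
        raise ValueError("frames must have identical shapes")
    if pre_frame.pixel_spacing_mm != post_frame.pixel_spacing_mm:
        raise ValueError("frames must have identical pixel spacing")
    sp = pre_frame.pixel_spacing_mm
    rows = np.arange(pre_frame.n_rows)
    cols = np.arange(pre_frame.n_cols)
    depth, lat = np.meshgrid((rows + 0.5) * sp,
                             (cols + 0.5 - pre_frame.n_cols / 2.0) * sp,
                             indexing="ij")
    tip_lat, tip_depth = predicted_tip_mm
    roi = (lat - tip_lat) ** 2 + (depth - tip_depth) ** 2 <= roi_radius_mm ** 2
    if not roi.any():
        return False
    diff = np.abs(post_frame.pixels.astype(np.float64)
                  - pre_frame.pixels.astype(np.float64))
    return float(diff[roi].mean()) > threshold
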