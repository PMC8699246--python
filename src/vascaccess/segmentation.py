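"""Vessel boundary and centroid segmentation.

The chain mirrors how a classical contour-fitting pipeline localises a
hypoechoic lumen in a transverse B-mode view: threshold the (inverted)
region of interest with Otsu's method to get an initial binary image,
clean it with morphological opening/closing and a minimum-area filter,
cast spokes from a seed inside the lumen to collect boundary points, and
fit an ellipse to those points.  The ellipse centre is the reported
vessel centroid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.measure import EllipseModel
from skimage.morphology import closing, disk, opening, remove_small_objects

from .phantom import BModeFrame

__all__ = [
    "SegmentationError",
    "SegmentationConfig",
    "VesselFit",
    "otsu_threshold",
    "clean_mask",
    "spoke_fit",
    "fit_ellipse",
    "segment_vessel",
]


class SegmentationError(RuntimeError):
    """Single failure signal for the segmentation pipeline."""


@dataclass(frozen=True)
class SegmentationConfig:
    n_spokes: int = 32
    spoke_quorum: float = 0.60      # min fraction of spokes that must hit
    roi_margin_fraction: float = 0.20
    morph_radius_px: int = 2
    min_area_px: int = 30
    spoke_step_px: float = 0.3
    max_radius_factor: float = 1.5  # x bbox half-diagonal
    # a genuine lumen is much darker than its surround; an Otsu split of
    # bare tissue texture is not
    max_lumen_contrast_ratio: float = 0.70


@dataclass(frozen=True)
class VesselFit:
    """Fitted lumen ellipse in frame coordinates (mm).

    ``center_mm`` is (lateral, depth); ``semi_axes_mm`` is (a, b) with
    a >= b > 0; ``rotation_deg`` is the angle of the a-axis from the
    lateral axis.
    """

    center_mm: tuple[float, float]
    semi_axes_mm: tuple[float, float]
    rotation_deg: float
    boundary_points_mm: np.ndarray
    cls: str = "vein"
    age: int = 0

    def __post_init__(self) -> None:
        a, b = self.semi_axes_mm
        if not (a >= b > 0):
            raise ValueError("semi axes must satisfy a >= b > 0")

    @property
    def effective_diameter_mm(self) -> float:
        a, b = self.semi_axes_mm
        return 2.0 * math.sqrt(a * b)


def otsu_threshold(pixels: np.ndarray) -> int:
    """Otsu threshold over the 8-bit histogram.

    Returns the intensity t in [0, 255] that maximises the between-class
    variance of the two populations {v <= t} and {v > t}; ties break
    toward the lower threshold.  Raises ``ValueError`` on a constant
    image, which has no separable classes.
    """
    values = np.asarray(pixels).ravel()
    if values.size == 0:
        raise ValueError("empty input")
    values = np.clip(np.round(values), 0, 255).astype(np.int64)
    if values.min() == values.max():
        raise ValueError("constant image has no separable classes")
    hist = np.bincount(values, minlength=256).astype(np.float64)
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)
    m0 = np.cumsum(hist * levels)
    total = w0[-1]
    mu_total = m0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        between = w0 * w1 * (mean0 - mean1) ** 2
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))  # argmax takes the first (lowest) maximum


def clean_mask(mask: np.ndarray, morph_radius_px: int = 2,
               min_area_px: int = 30) -> np.ndarray:
    """Morphological opening then closing, then small-component removal."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    footprint = disk(morph_radius_px)
    out = opening(mask, footprint)
    out = closing(out, footprint)
    if min_area_px > 0:
        # drop components strictly smaller than min_area_px
        out = remove_small_objects(out, max_size=min_area_px - 1)
    return out


def spoke_fit(mask: np.ndarray, seed_point_mm: tuple[float, float],
              pixel_spacing_mm: float, n_spokes: int = 32,
              max_radius_mm: float | None = None,
              quorum: float = 0.60, step_px: float = 0.3) -> np.ndarray:
    """Cast radial spokes from a seed and collect lumen boundary points.

    The seed and returned points are in local image mm with x = (col+0.5)
    * spacing and y = (row+0.5) * spacing.  Each spoke walks outward in
    sub-pixel steps; the boundary point is the midpoint between the last
    in-mask and first out-of-mask sample.  Spokes that never leave the
    mask within ``max_radius_mm`` are dropped; fewer than ``quorum`` of
    hits is an error (unreliable fit), as is a seed outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    sx, sy = seed_point_mm
    seed_c = sx / pixel_spacing_mm - 0.5
    seed_r = sy / pixel_spacing_mm - 0.5
    r0 = int(round(seed_r))
    c0 = int(round(seed_c))
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]) \
            or not mask[r0, c0]:
        raise SegmentationError("spoke seed lies outside the mask")
    if max_radius_mm is None:
        max_radius_mm = 0.5 * math.hypot(*mask.shape) * pixel_spacing_mm
    max_steps = int(max_radius_mm / (step_px * pixel_spacing_mm)) + 1

    points = []
    for k in range(n_spokes):
        ang = 2.0 * math.pi * k / n_spokes
        dx, dy = math.cos(ang), math.sin(ang)
        prev_inside = 0.0
        found = False
        for step in range(1, max_steps + 1):
            dist_px = step * step_px
            c = seed_c + dx * dist_px
            r = seed_r + dy * dist_px
            ri, ci = int(round(r)), int(round(c))
            inside = (0 <= ri < mask.shape[0] and 0 <= ci < mask.shape[1]
                      and mask[ri, ci])
            if not inside:
                hit = (prev_inside + dist_px) / 2.0 * pixel_spacing_mm
                points.append((sx + dx * hit, sy + dy * hit))
                found = True
                break
            prev_inside = dist_px
        if not found:
            continue  # spoke never left the mask within max radius
    if len(points) < quorum * n_spokes:
        raise SegmentationError(
            f"only {len(points)}/{n_spokes} spokes hit a boundary")
    return np.asarray(points, dtype=float)


def _circle_fallback(points: np.ndarray) -> tuple[tuple[float, float],
                                                  tuple[float, float], float]:
    center = points.mean(axis=0)
    radius = float(np.sqrt(((points - center) ** 2).sum(axis=1).mean()))
    return (float(center[0]), float(center[1])), (radius, radius), 0.0


def fit_ellipse(points: np.ndarray, cls: str = "vein") -> VesselFit:
    """Least-squares ellipse through boundary points.

    Uses a direct least-squares conic fit; when the conic degenerates,
    falls back to the boundary centroid with an RMS-radius circle.
    Requires at least 5 non-collinear points.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 5:
        raise SegmentationError("ellipse fit needs at least 5 (x, y) points")
    centered = points - points.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise SegmentationError("boundary points are collinear")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = EllipseModel.from_estimate(points)
    if model:
        cx, cy = (float(v) for v in model.center)
        a, b = (float(v) for v in model.axis_lengths)
        theta = float(model.theta)
        if a < b:
            a, b = b, a
            theta += math.pi / 2.0
        if not (np.isfinite([cx, cy, a, b, theta]).all() and b > 0):
            center, axes, rot = _circle_fallback(points)
        else:
            center, axes, rot = (cx, cy), (a, b), math.degrees(theta) % 180.0
    else:
        center, axes, rot = _circle_fallback(points)
    if axes[1] <= 0:
        raise SegmentationError("degenerate boundary configuration")
    return VesselFit(center_mm=center, semi_axes_mm=axes, rotation_deg=rot,
                     boundary_points_mm=points, cls=cls)


def segment_vessel(frame: BModeFrame, detection,
                   config: SegmentationConfig | None = None) -> VesselFit:
    """Full lumen segmentation for one detection on one frame.

    Pipeline: crop the detection bbox plus margin, invert so the dark
    lumen becomes bright, Otsu-threshold, clean the mask, spoke-fit from
    the bbox centre, fit the ellipse, and convert the result into frame
    coordinates (lateral relative to the probe centre, depth from skin).
    Any sub-step failure raises :class:`SegmentationError`.
    """
    config = config or SegmentationConfig()
    r0, c0, r1, c1 = detection.bbox
    if not (0 <= r0 < r1 <= frame.n_rows and 0 <= c0 < c1 <= frame.n_cols):
        raise SegmentationError("detection bbox outside the frame")
    if detection.cls not in ("artery", "vein"):
        raise SegmentationError(f"cannot segment class {detection.cls!r}")

    mr = int(round(config.roi_margin_fraction * (r1 - r0)))
    mc = int(round(config.roi_margin_fraction * (c1 - c0)))
    R0, C0 = max(0, r0 - mr), max(0, c0 - mc)
    R1, C1 = min(frame.n_rows, r1 + mr), min(frame.n_cols, c1 + mc)
    roi = frame.pixels[R0:R1, C0:C1].astype(np.float64)

    inverted = 255.0 - roi
    try:
        thr = otsu_threshold(inverted)
    except ValueError as exc:
        raise SegmentationError(str(exc)) from exc
    mask = inverted > thr
    mask = clean_mask(mask, config.morph_radius_px, config.min_area_px)
    if not mask.any():
        raise SegmentationError("empty mask after cleaning")
    if mask.all():
        raise SegmentationError("mask covers the whole ROI")
    if roi[mask].mean() > config.max_lumen_contrast_ratio * roi[~mask].mean():
        raise SegmentationError("ROI lacks a hypoechoic lumen")

    sp = frame.pixel_spacing_mm
    seed_mm = (((r0 + r1) / 2.0 - R0) * sp, ((c0 + c1) / 2.0 - C0) * sp)
    half_diag = 0.5 * math.hypot(r1 - r0, c1 - c0) * sp
    points_local = spoke_fit(
        mask, (seed_mm[1], seed_mm[0]), sp, n_spokes=config.n_spokes,
        max_radius_mm=config.max_radius_factor * half_diag,
        quorum=config.spoke_quorum, step_px=config.spoke_step_px)

    # local ROI mm -> frame mm
    lat = points_local[:, 0] + (C0 - frame.n_cols / 2.0) * sp
    depth = points_local[:, 1] + R0 * sp
    fit = fit_ellipse(np.column_stack([lat, depth]), cls=detection.cls)
    return fit
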