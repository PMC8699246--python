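"""Per-frame vessel detection and multi-frame persistence logic.

The default backend is a classical morphology-based detector: dark-blob
candidates from adaptive Otsu thresholding of the smoothed frame,
area-gated connected components, and artery/vein classification from
wall-ring brightness and circularity (the artery wall is thicker and
more hyperechoic; the artery lumen is more circular).  A merged blob
with two distinct lobes is classified as a bifurcation.  The backend is
pluggable: any callable ``frame -> list[Detection]`` (for instance a
convolutional detector) may replace it.

Multi-frame smoothing carries the most recent detection of a class
forward when the current frame misses it, up to a maximum age.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import gaussian
from skimage.measure import label, regionprops

from .phantom import ARTERY, BIFURCATION, VEIN, AnatomyPriors, BModeFrame
from .segmentation import otsu_threshold

__all__ = [
    "Detection",
    "DetectionHistory",
    "DetectorConfig",
    "detect_frame",
    "smooth_detections",
    "detect_bifurcation_cue",
    "CUE_NONE",
    "CUE_MOVE_CRANIAL",
]

CUE_NONE = "none"
CUE_MOVE_CRANIAL = "move-cranial"


@dataclass(frozen=True)
class Detection:
    """One detected vessel: class, half-open pixel bbox, score, age."""

    cls: str
    bbox: tuple[int, int, int, int]
    score: float
    frame_index: int = 0
    age: int = 0

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bbox
        if not (r0 < r1 and c0 < c1):
            raise ValueError("bbox must be non-empty half-open")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")
        if self.age < 0:
            raise ValueError("age must be non-negative")

    @property
    def center_rc(self) -> tuple[float, float]:
        r0, c0, r1, c1 = self.bbox
        return ((r0 + r1) / 2.0, (c0 + c1) / 2.0)


class DetectionHistory:
    """Ring buffer of per-frame detection lists, capacity ``max_age``."""

    def __init__(self, max_age: int = 5):
        if max_age < 1:
            raise ValueError("max_age must be at least 1")
        self.max_age = max_age
        self._frames: deque[tuple[int, list[Detection]]] = deque(maxlen=max_age)

    def push(self, frame_index: int, detections: list[Detection]) -> None:
        if self._frames and frame_index <= self._frames[-1][0]:
            raise ValueError("history frames must be pushed in order")
        self._frames.append((frame_index, list(detections)))

    def __len__(self) -> int:
        return len(self._frames)

    def frames(self) -> list[tuple[int, list[Detection]]]:
        return list(self._frames)


@dataclass(frozen=True)
class DetectorConfig:
    smooth_sigma_px: float = 2.0
    # candidate lumen area gate, as fractions of the prior-mean class areas
    area_gate_low: float = 0.25
    area_gate_high: float = 4.0
    ring_width_mm: float = 1.2
    # interior/surround intensity ratio above which a dark blob is rejected
    max_contrast_ratio: float = 0.40
    # speckle blobs are ragged; even a flattened lumen stays above this
    min_circularity: float = 0.55
    # artery/vein split on the wall-ring brightness (upper-quartile ring
    # intensity; the thick hyperechoic artery wall saturates it) and the
    # logistic scale turning the margin into a score
    ring_split_intensity: float = 215.0
    margin_scale: float = 15.0
    circularity_weight: float = 30.0
    # two distance-transform lobes => merged lumens => bifurcation
    lobe_peak_fraction: float = 0.62
    lobe_neck_fraction: float = 0.88
    max_background_fraction: float = 0.30


def _class_area_gate(priors: AnatomyPriors, pixel_spacing_mm: float,
                     config: DetectorConfig) -> tuple[float, float]:
    hypo_vein_d = priors.vein_diameter_mean_mm * priors.hypotension_diameter_factor
    hypo_vein_ecc = priors.vein_aspect_mean * priors.hypotension_flattening_factor
    areas = []
    for d, ecc in ((priors.artery_diameter_mean_mm, priors.artery_aspect_mean),
                   (priors.vein_diameter_mean_mm, priors.vein_aspect_mean),
                   (hypo_vein_d, hypo_vein_ecc)):
        areas.append(math.pi * (d / 2.0) * (d * ecc / 2.0)
                     / pixel_spacing_mm ** 2)
    return (config.area_gate_low * min(areas), config.area_gate_high * max(areas))


def _count_lobes(region_mask: np.ndarray, config: DetectorConfig) -> int:
    """Distinct lobes of a blob via distance-transform peaks with a neck test."""
    dt = ndimage.distance_transform_edt(region_mask)
    dmax = dt.max()
    if dmax <= 0:
        return 0
    peaks = peak_local_max(dt, min_distance=max(3, int(0.9 * dmax)),
                           threshold_abs=config.lobe_peak_fraction * dmax,
                           exclude_border=False)
    if len(peaks) < 2:
        return 1
    # require a genuine neck between the two strongest peaks: a flat ridge
    # inside an elongated single lumen has no dip
    p0, p1 = peaks[0], peaks[1]
    n = max(8, int(np.hypot(*(p1 - p0))))
    rr = np.linspace(p0[0], p1[0], n).round().astype(int)
    cc = np.linspace(p0[1], p1[1], n).round().astype(int)
    profile = dt[rr, cc]
    smaller_peak = min(dt[tuple(p0)], dt[tuple(p1)])
    if profile.min() < config.lobe_neck_fraction * smaller_peak:
        return 2
    return 1


def detect_frame(frame: BModeFrame,
                 config: DetectorConfig | None = None,
                 priors: AnatomyPriors | None = None) -> list[Detection]:
    """Classical dark-blob detector; returns possibly empty detections."""
    config = config or DetectorConfig()
    priors = priors or AnatomyPriors()
    img = frame.pixels.astype(np.float64)
    sm = gaussian(img, sigma=config.smooth_sigma_px, preserve_range=True)

    try:
        thr = otsu_threshold(sm)
    except ValueError:
        return []
    dark = sm <= thr
    # if Otsu split the background in half, re-threshold within the dark side
    for _ in range(2):
        if dark.mean() <= config.max_background_fraction:
            break
        try:
            thr = otsu_threshold(sm[dark])
        except ValueError:
            break
        dark = sm <= thr

    labels = label(dark)
    area_lo, area_hi = _class_area_gate(priors, frame.pixel_spacing_mm, config)
    ring_px = max(1, int(round(config.ring_width_mm / frame.pixel_spacing_mm)))
    detections: list[Detection] = []
    for region in regionprops(labels):
        if not (area_lo <= region.area <= area_hi):
            continue
        r0, c0, r1, c1 = region.bbox
        region_mask = np.zeros(img.shape, dtype=bool)
        region_mask[r0:r1, c0:c1] = labels[r0:r1, c0:c1] == region.label

        interior = img[region_mask].mean()
        ring_mask = ndimage.binary_dilation(region_mask, iterations=ring_px) \
            & ~region_mask
        if not ring_mask.any():
            continue
        ring_vals = img[ring_mask]
        ring_mean = ring_vals.mean()
        if ring_mean <= 0 or interior / ring_mean > config.max_contrast_ratio:
            continue  # not a hypoechoic lumen against a brighter surround
        ring_q75 = float(np.quantile(ring_vals, 0.75))

        perimeter = region.perimeter or 1.0
        circularity = min(1.0, 4.0 * math.pi * region.area / perimeter ** 2)
        if circularity < config.min_circularity:
            continue

        sub_mask = region_mask[r0:r1, c0:c1]
        if _count_lobes(sub_mask, config) >= 2:
            cls = BIFURCATION
            margin = 1.0
        else:
            # artery: brighter wall ring, more circular lumen
            margin = (ring_q75 - config.ring_split_intensity
                      + config.circularity_weight * (circularity - 0.90)) \
                / config.margin_scale
            cls = ARTERY if margin >= 0 else VEIN
        score = float(np.clip(1.0 / (1.0 + math.exp(-abs(margin))), 0.0, 1.0))
        detections.append(Detection(cls=cls, bbox=(r0, c0, r1, c1),
                                    score=score,
                                    frame_index=frame.frame_index, age=0))
    # keep the best-scoring detection per class
    best: dict[str, Detection] = {}
    for det in detections:
        if det.cls not in best or det.score > best[det.cls].score:
            best[det.cls] = det
    return sorted(best.values(), key=lambda d: d.cls)


def smooth_detections(history: DetectionHistory,
                      current: list[Detection],
                      max_age: int | None = None) -> list[Detection]:
    """Carry the most recent detection of each missing class forward.

    Classes present in ``current`` pass through with age 0.  A class
    absent from the current frame is filled from the most recent history
    frame that contains it, with ``age`` set to the number of frames
    since that direct observation; classes last seen ``max_age`` or more
    frames ago are dropped.
    """
    max_age = history.max_age if max_age is None else max_age
    current_frame = current[0].frame_index if current else (
        history.frames()[-1][0] + 1 if len(history) else 0)
    out = [replace(det, age=0) for det in current]
    present = {det.cls for det in current}
    for frame_index, dets in reversed(history.frames()):
        if frame_index >= current_frame:
            continue
        age = current_frame - frame_index
        if age >= max_age:
            break
        for det in dets:
            if det.cls in present:
                continue
            present.add(det.cls)
            out.append(replace(det, age=age))
    return sorted(out, key=lambda d: d.cls)


def detect_bifurcation_cue(detections: list[Detection]) -> str:
    """Cue the user to move cranially whenever a bifurcation is detected."""
    if any(det.cls == BIFURCATION for det in detections):
        return CUE_MOVE_CRANIAL
    return CUE_NONE
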