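"""Shared fixtures: rendered frame sets are expensive, so build once."""

from __future__ import annotations

import numpy as np
import pytest

import vascaccess as va
from vascaccess.detection import Detection, detect_frame


@pytest.fixture(scope="session")
def priors():
    return va.AnatomyPriors()


@pytest.fixture(scope="session")
def circle_fit():
    """A circular vein fit at 20 mm depth (25 mm along the default path)."""
    return va.VesselFit(center_mm=(0.0, 20.0), semi_axes_mm=(5.0, 5.0),
                        rotation_deg=0.0,
                        boundary_points_mm=np.empty((0, 2)), cls="vein")


def _render_case(priors, seed, state, frame_index=0):
    inst = va.sample_anatomy(priors, state, seed=seed)
    frame, gt = va.render_frame(
        inst, (inst.vein.lateral_center_mm, 0.0), seed=seed + 50_000,
        frame_index=frame_index)
    return inst, frame, gt


@pytest.fixture(scope="session")
def centroid_eval_set(priors):
    """200 frames spanning both physiologic states with GT-assisted boxes.

    Returns a list of (state, frame, gt, fits) where fits were produced by
    the full Otsu/morphology/spoke/ellipse chain seeded from the
    ground-truth bounding boxes.
    """
    from vascaccess.segmentation import SegmentationError, segment_vessel

    cases = []
    for i in range(200):
        state = va.NORMOTENSIVE if i % 2 == 0 else va.HYPOTENSIVE
        inst, frame, gt = _render_case(priors, 10_000 + i, state, frame_index=i)
        fits = []
        for g in gt:
            if g.cls not in (va.ARTERY, va.VEIN):
                continue
            det = Detection(cls=g.cls, bbox=g.bbox, score=1.0,
                            frame_index=g.frame_index)
            try:
                fits.append((g, segment_vessel(frame, det)))
            except SegmentationError:
                continue
        cases.append((state, frame, gt, fits))
    return cases


@pytest.fixture(scope="session")
def detection_eval_set(priors):
    """150 matched frames with raw detector output for PR evaluation."""
    cases = []
    for i in range(150):
        state = va.NORMOTENSIVE if i % 2 == 0 else va.HYPOTENSIVE
        inst, frame, gt = _render_case(priors, 20_000 + i, state, frame_index=i)
        dets = detect_frame(frame)
        cases.append((frame, gt, dets))
    return cases
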