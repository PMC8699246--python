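"""Evaluation harness: detection PR/AUC, centroid accuracy, campaigns.

Detection quality is scored with greedy IoU matching and
average-precision (step-interpolated) PR curves per class.  Centroid
accuracy compares fitted lumen centres to rendered ground truth per
axis and per class.  ``run_campaign`` closes the loop: sample an
anatomy, render, detect, segment, guide the simulated operator to a
ready state, plan, and simulate the insertion with retries, then
aggregate success statistics with exact (Clopper-Pearson) binomial
confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from . import guidance as gd
from . import needle as nd
from .detection import (Detection, DetectionHistory, DetectorConfig,
                        detect_frame, smooth_detections)
from .phantom import (ARTERY, HYPOTENSIVE, NORMOTENSIVE, VEIN, AnatomyPriors,
                      GroundTruthRecord, ImagingConfig, render_frame,
                      sample_anatomy)
from .segmentation import (SegmentationConfig, SegmentationError, VesselFit,
                           segment_vessel)

__all__ = [
    "MatchResult",
    "PRCurve",
    "CampaignConfig",
    "CampaignSummary",
    "iou",
    "match_detections",
    "pr_curve",
    "centroid_error",
    "binomial_ci",
    "run_campaign",
]


def iou(box_a, box_b) -> float:
    """Intersection over union of two half-open pixel boxes (r0,c0,r1,c1)."""
    ar0, ac0, ar1, ac1 = box_a
    br0, bc0, br1, bc1 = box_b
    if ar0 >= ar1 or ac0 >= ac1 or br0 >= br1 or bc0 >= bc1:
        raise ValueError("boxes must be non-empty half-open")
    ir = max(0, min(ar1, br1) - max(ar0, br0))
    ic = max(0, min(ac1, bc1) - max(ac0, bc0))
    inter = ir * ic
    union = (ar1 - ar0) * (ac1 - ac0) + (br1 - br0) * (bc1 - bc0) - inter
    return inter / union if union > 0 else 0.0


@dataclass(frozen=True)
class MatchResult:
    """Per-class TP/FP/FN counts at one IoU (and score) threshold."""

    counts: dict  # cls -> (tp, fp, fn)

    def totals(self) -> tuple[int, int, int]:
        tp = sum(v[0] for v in self.counts.values())
        fp = sum(v[1] for v in self.counts.values())
        fn = sum(v[2] for v in self.counts.values())
        return tp, fp, fn


def match_detections(predicted: list, truth: list,
                     iou_threshold: float = 0.5) -> MatchResult:
    """Greedy per-class matching by descending score.

    Predictions and truths are grouped by (frame, class); each prediction
    may claim at most one unmatched truth with IoU at or above the
    threshold.  Truths may be :class:`GroundTruthRecord` or any object
    with ``frame_index``/``cls``/``bbox``.
    """
    classes = sorted({d.cls for d in predicted} | {t.cls for t in truth})
    counts = {}
    for cls in classes:
        preds = sorted((p for p in predicted if p.cls == cls),
                       key=lambda p: -p.score)
        truths = [t for t in truth if t.cls == cls]
        matched = [False] * len(truths)
        tp = fp = 0
        for p in preds:
            best_j, best_iou = -1, iou_threshold
            for j, t in enumerate(truths):
                if matched[j] or t.frame_index != p.frame_index:
                    continue
                val = iou(p.bbox, t.bbox)
                if val >= best_iou:
                    best_iou, best_j = val, j
            if best_j >= 0:
                matched[best_j] = True
                tp += 1
            else:
                fp += 1
        counts[cls] = (tp, fp, len(truths) - tp)
    return MatchResult(counts=counts)


@dataclass(frozen=True)
class PRCurve:
    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float  # average precision (step interpolation)


def pr_curve(predictions: list, truths: list,
             iou_threshold: float = 0.5) -> PRCurve:
    """Precision-recall curve and average precision over score thresholds.

    Predictions are ranked by descending score and greedily matched; the
    AUC is the step-wise average-precision sum, so a perfect detector
    scores 1.0 and an all-wrong detector 0.0.
    """
    if not truths:
        raise ValueError("pr_curve requires at least one ground-truth box")
    n_truth = len(truths)
    ranked = sorted(predictions, key=lambda p: -p.score)
    matched = [False] * n_truth
    is_tp = []
    for p in ranked:
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(truths):
            if matched[j] or t.cls != p.cls or t.frame_index != p.frame_index:
                continue
            val = iou(p.bbox, t.bbox)
            if val >= best_iou:
                best_iou, best_j = val, j
        if best_j >= 0:
            matched[best_j] = True
            is_tp.append(1)
        else:
            is_tp.append(0)
    is_tp = np.asarray(is_tp, dtype=float)
    scores = np.asarray([p.score for p in ranked], dtype=float)
    if len(ranked) == 0:
        return PRCurve(np.array([]), np.array([]), np.array([]), 0.0)
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(1.0 - is_tp)
    precision = tp_cum / (tp_cum + fp_cum)
    recall = tp_cum / n_truth
    # one PR point per unique score (threshold sweep)
    keep = np.r_[scores[1:] != scores[:-1], True]
    ap = 0.0
    prev_recall = 0.0
    for i in np.flatnonzero(keep):
        ap += (recall[i] - prev_recall) * precision[i]
        prev_recall = recall[i]
    return PRCurve(thresholds=scores[keep], precision=precision[keep],
                   recall=recall[keep], auc=float(ap))


def centroid_error(fits: list[VesselFit], truths: list[GroundTruthRecord],
                   fit_frames: list[int] | None = None):
    """Signed per-axis centroid errors (fit - truth) with summary stats.

    Fits are matched to truths by (frame, class); ``fit_frames`` supplies
    the frame index for each fit (fits carry no frame field).  Returns
    ``(errors, summary, n_unmatched)`` where ``errors`` has one row per
    matched fit and ``summary`` holds the median and IQR of signed and
    absolute errors per class and axis.
    """
    if fit_frames is None:
        fit_frames = [0] * len(fits)
    truth_by_key = {(t.frame_index, t.cls): t for t in truths}
    rows = []
    n_unmatched = 0
    for fit, frame_index in zip(fits, fit_frames):
        t = truth_by_key.get((frame_index, fit.cls))
        if t is None:
            n_unmatched += 1
            continue
        rows.append({
            "frame": frame_index, "class": fit.cls,
            "lateral_error_mm": fit.center_mm[0] - t.centroid_mm[0],
            "depth_error_mm": fit.center_mm[1] - t.centroid_mm[1],
        })
    errors = pd.DataFrame(rows, columns=["frame", "class",
                                         "lateral_error_mm", "depth_error_mm"])
    summaries = []
    for cls, grp in errors.groupby("class"):
        for axis in ("lateral_error_mm", "depth_error_mm"):
            e = grp[axis]
            summaries.append({
                "class": cls, "axis": axis.replace("_error_mm", ""),
                "median_mm": e.median(), "iqr_mm": e.quantile(0.75) - e.quantile(0.25),
                "median_abs_mm": e.abs().median(),
                "iqr_abs_mm": e.abs().quantile(0.75) - e.abs().quantile(0.25),
                "n": len(e),
            })
    summary = pd.DataFrame(summaries)
    return errors, summary, n_unmatched


def binomial_ci(successes: int, n: int,
                alpha: float = 0.05) -> tuple[float, float]:
    """Exact Clopper-Pearson binomial confidence interval."""
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(successes, n, alpha=alpha, method="beta")
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# closed-loop campaign
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CampaignConfig:
    priors: AnatomyPriors = field(default_factory=AnatomyPriors)
    condition: str = NORMOTENSIVE
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    guidance: gd.GuidanceConfig = field(default_factory=gd.GuidanceConfig)
    geometry: nd.NeedleGeometry = field(default_factory=nd.NeedleGeometry)
    kickback_sd_mm: float = 0.5
    kickback_sd_deg: float = 0.5
    max_attempts_per_trial: int = 3
    capacity_jitter_sd: float = 0.25
    max_guidance_frames: int = 40
    operator_noise_sd_mm: float = 0.3
    use_ground_truth_boxes: bool = False


@dataclass(frozen=True)
class CampaignSummary:
    """Aggregate insertion statistics over one campaign.

    ``n_trials`` counts trials that reached needle insertion;
    ``non_acquisitions`` counts trials where guidance never reached a
    ready state (reported, never crashed).  ``success_rate`` is
    successful insertions per attempt, in the style of per-attempt
    success tables, with an exact binomial CI.
    """

    condition: str
    n_trials: int
    non_acquisitions: int
    n_attempts: int
    successes: int
    first_attempt_successes: int
    mean_attempts: float
    success_rate: float
    success_rate_ci95: tuple[float, float]
    ci_method: str = "clopper-pearson"

    def __post_init__(self) -> None:
        if self.successes > self.n_trials:
            raise ValueError("successes cannot exceed trials")
        if self.n_trials > 0 and self.mean_attempts < 1.0:
            raise ValueError("mean attempts per insertion trial must be >= 1")

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "n_trials": self.n_trials,
            "non_acquisitions": self.non_acquisitions,
            "n_attempts": self.n_attempts,
            "successes": self.successes,
            "first_attempt_successes": self.first_attempt_successes,
            "mean_attempts": self.mean_attempts,
            "success_rate": self.success_rate,
            "success_rate_ci95": list(self.success_rate_ci95),
            "ci_method": self.ci_method,
        }


def _acquire(anatomy, config: CampaignConfig, rng) -> tuple:
    """Simulated operator: move the probe until guidance reads ready.

    Returns ``(ready, probe_lateral, target_fit)``.
    """
    probe_lateral = anatomy.vein.lateral_center_mm + rng.uniform(-8.0, 8.0)
    probe_cc = 0.0
    history = DetectionHistory(max_age=5)
    session = gd.GuidanceSession(config.guidance)
    target_fit = None
    for i in range(config.max_guidance_frames):
        frame_seed = int(rng.integers(0, 2**31 - 1))
        frame, gt = render_frame(anatomy, (probe_lateral, probe_cc),
                                 config.imaging, seed=frame_seed,
                                 frame_index=i)
        if config.use_ground_truth_boxes:
            detections = [Detection(cls=g.cls, bbox=g.bbox, score=1.0,
                                    frame_index=i) for g in gt]
        else:
            detections = detect_frame(frame, config.detector, config.priors)
        smoothed = smooth_detections(history, detections)
        history.push(i, detections)
        fits = []
        for det in smoothed:
            if det.cls not in (ARTERY, VEIN):
                continue
            try:
                fit = segment_vessel(frame, det, config.segmentation)
            except SegmentationError:
                continue
            fits.append(replace(fit, age=det.age))
        state = session.update(smoothed, fits)
        target = next((f for f in fits
                       if f.cls == config.guidance.target_class), None)
        if state.ready and target is not None:
            return True, probe_lateral, target
        if state.hazard == gd.HAZARD_CRANIAL:
            probe_cc += 5.0
        if state.lateral_offset_mm is not None:
            probe_lateral += state.lateral_offset_mm \
                + rng.normal(0.0, config.operator_noise_sd_mm)
        else:
            probe_lateral += rng.uniform(-4.0, 4.0)  # search scan
        lim_lat = config.imaging.skin_lateral_extent_mm - 1.0
        lim_cc = config.imaging.skin_cc_extent_mm - 1.0
        probe_lateral = float(np.clip(probe_lateral, -lim_lat, lim_lat))
        probe_cc = float(np.clip(probe_cc, -lim_cc, lim_cc))
    return False, probe_lateral, target_fit


def run_campaign(config: CampaignConfig, seeds) -> CampaignSummary:
    """Run end-to-end insertion trials and aggregate their outcomes."""
    if config.condition not in (NORMOTENSIVE, HYPOTENSIVE):
        raise ValueError(f"unknown condition {config.condition!r}")
    seeds = list(seeds)
    n_attempts = successes = first_successes = non_acq = trials = 0
    for seed in seeds:
        anatomy = sample_anatomy(config.priors, config.condition, seed=seed)
        rng = np.random.default_rng((int(seed) * 2654435761 + 17) % (2**31))
        ready, probe_lateral, target = _acquire(anatomy, config, rng)
        if not ready or target is None:
            non_acq += 1
            continue
        try:
            plan = nd.plan_trajectory(target, config.geometry)
        except nd.PlanningError:
            non_acq += 1
            continue
        trials += 1
        lateral_error = anatomy.vein.lateral_center_mm - probe_lateral
        tissue = nd.TissueParams(
            tenting_capacity_mm=anatomy.tenting_capacity_mm,
            kickback_sd_mm=config.kickback_sd_mm,
            kickback_sd_deg=config.kickback_sd_deg,
            max_attempts_per_trial=config.max_attempts_per_trial,
            capacity_jitter_sd=config.capacity_jitter_sd)
        result = nd.simulate_insertion(plan, anatomy, tissue,
                                       lateral_error_mm=lateral_error,
                                       seed=int(seed))
        n_attempts += result.attempts
        if result.success:
            successes += 1
            if result.attempts == 1:
                first_successes += 1
    rate = successes / n_attempts if n_attempts else 0.0
    return CampaignSummary(
        condition=config.condition, n_trials=trials,
        non_acquisitions=non_acq, n_attempts=n_attempts,
        successes=successes, first_attempt_successes=first_successes,
        mean_attempts=(n_attempts / trials) if trials else 0.0,
        success_rate=rate,
        success_rate_ci95=binomial_ci(successes, n_attempts))
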