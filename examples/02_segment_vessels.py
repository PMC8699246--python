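"""Detect and segment vessels on a rendered frame.

Runs the classical detector (dark-blob candidates, wall-ring/circularity
classification), then the contour chain — Otsu threshold, morphological
cleaning, spoke casting, least-squares ellipse — and compares the fitted
centroids against the renderer's ground truth.
"""

import vascaccess as va
from vascaccess.detection import detect_frame
from vascaccess.segmentation import segment_vessel

anatomy = va.sample_anatomy(va.AnatomyPriors(), seed=11)
frame, truth = va.render_frame(anatomy,
                               (anatomy.vein.lateral_center_mm, 0.0), seed=11)

detections = detect_frame(frame)
truth_by_cls = {t.cls: t for t in truth}
for det in detections:
    print(f"detected {det.cls:6s} score {det.score:.2f} bbox {det.bbox}")
    if det.cls not in ("artery", "vein"):
        continue
    fit = segment_vessel(frame, det)
    t = truth_by_cls[det.cls]
    err_lat = fit.center_mm[0] - t.centroid_mm[0]
    err_depth = fit.center_mm[1] - t.centroid_mm[1]
    print(f"  fitted centre ({fit.center_mm[0]:+.2f}, "
          f"{fit.center_mm[1]:.2f}) mm, effective diameter "
          f"{fit.effective_diameter_mm:.1f} mm")
    print(f"  centroid error (lateral, depth) = "
          f"({err_lat:+.3f}, {err_depth:+.3f}) mm")
# Errors of a few hundredths of a millimetre at 0.1 mm/px show the
# spoke/ellipse chain localising well below the pixel grid.
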