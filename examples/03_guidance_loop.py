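"""Follow the dot-and-crosshairs guidance as a simulated operator.

The operator starts a few millimetres off target and moves the probe by
the displayed dot offset each frame.  The dot is red when far, yellow
inside the approach radius (with a finer display gain), and green only
once the lateral error is inside the dynamic insertion window (10% of
vessel diameter) with a clear path and no bifurcation in view.
"""

from dataclasses import replace

import vascaccess as va
from vascaccess.detection import DetectionHistory, detect_frame, smooth_detections
from vascaccess.guidance import GuidanceSession
from vascaccess.segmentation import SegmentationError, segment_vessel

anatomy = va.sample_anatomy(va.AnatomyPriors(), seed=23)
probe_lateral = anatomy.vein.lateral_center_mm + 6.0  # start 6 mm off
session = GuidanceSession()
history = DetectionHistory()

for i in range(25):
    frame, _ = va.render_frame(anatomy, (probe_lateral, 0.0), seed=100 + i,
                               frame_index=i)
    dets = detect_frame(frame)
    smoothed = smooth_detections(history, dets)
    history.push(i, dets)
    fits = []
    for det in smoothed:
        if det.cls not in ("artery", "vein"):
            continue
        try:
            fits.append(replace(segment_vessel(frame, det), age=det.age))
        except SegmentationError:
            pass
    state = session.update(smoothed, fits)
    x = state.lateral_offset_mm
    print(f"frame {i:2d}: offset {x if x is None else round(x, 2)!s:>6} mm  "
          f"dot {state.dot_offset_display:+6.2f}  {state.color:6s} "
          f"hazard={state.hazard}  ready={state.ready}")
    if state.ready:
        print("\ngreen for three consecutive frames: needle release enabled")
        break
    if x is not None:
        probe_lateral += x  # move the device toward the target
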