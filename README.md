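# vascaccess

A desk-scale simulator and analysis toolkit for **ultrasound-guided
femoral vascular access**. It reproduces, entirely in software, the
closed loop that a handheld robotic venipuncture device executes at the
bedside: interpret a transverse B-mode image, localise the common
femoral vein and artery, guide the operator laterally into a safe
insertion corridor, plan a needle trajectory, and drive the needle
through tenting tissue until blood flashback confirms intravascular
placement.

It is written for researchers prototyping image-guided intervention
logic who need a fully observable, reproducible stand-in for animal or
phantom experiments: every synthetic frame carries exact ground truth,
and every stage (detection, segmentation, guidance, insertion) is an
importable, seedable function.

## What it implements

**Synthetic phantom** (`vascaccess.phantom`). Subject anatomies are drawn
from truncated-normal priors matching adult femoral statistics — vein
depth 2.2 ± 0.6 cm and diameter 0.9 ± 0.3 cm, artery depth 1.8 ± 0.6 cm
and diameter 0.8 ± 0.2 cm — with a 65% prevalence of partial
anteroposterior artery-over-vein overlap. Frames are rendered at
0.1 mm/px over a 4 cm depth of view: hypoechoic elliptical lumens,
hyperechoic wall rings (thicker and brighter for the artery),
multiplicative speckle, and a bifurcation appearance (two merging
lumens) near the bifurcation coordinate. Hypotension shrinks and
flattens the vein and doubles its tenting capacity.

**Segmentation** (`vascaccess.segmentation`). The contour chain
`otsu_threshold → clean_mask → spoke_fit → fit_ellipse`: Otsu's
between-class-variance threshold on the inverted region of interest,
morphological opening/closing with a minimum-area filter, radial spokes
from the box centre collecting boundary points, and a direct
least-squares ellipse whose centre is the reported centroid.

**Detection** (`vascaccess.detection`). A pluggable per-frame backend
(default: classical dark-blob candidates classified by wall-ring
brightness and circularity; two-lobed blobs become bifurcations) plus
multi-frame carry-forward smoothing of missed classes.

**Guidance** (`vascaccess.guidance`). The dot-and-crosshairs state
machine: gain-scheduled dot, red/yellow/green colour code, cranial
repositioning cues on bifurcations or an interposed artery (analytic
segment–ellipse safety check), and the **dynamic insertion window** —
needle release only within 10% of the vessel diameter of the centroid,
i.e. 1 mm for a 1 cm vessel.

**Needle robotics** (`vascaccess.needle`). Trajectory planning with
angle `arctan(depth / entry offset)` and the waypoint schedule
A: 1 mm short of the posterior wall at 45 mm/s, B: centroid at 20 mm/s,
then the C → D → E dither at 10 mm/s; a 100 Hz kinematic insertion
simulator with skin-strike kickback, rigid-offset wall tenting,
stop-on-flashback, image-change confirmation, and retract-and-retry.

**Evaluation** (`vascaccess.evaluate`). Greedy IoU matching, PR curves
with average precision, per-axis centroid-error tables, and end-to-end
insertion campaigns with exact Clopper–Pearson confidence intervals.

## Worked example

```python
import vascaccess as va
from vascaccess.detection import detect_frame
from vascaccess.segmentation import segment_vessel
from vascaccess.needle import plan_trajectory, plan_duration

anatomy = va.sample_anatomy(va.AnatomyPriors(), seed=11)
frame, truth = va.render_frame(anatomy,
                               (anatomy.vein.lateral_center_mm, 0.0), seed=11)
vein_det = next(d for d in detect_frame(frame) if d.cls == "vein")
fit = segment_vessel(frame, vein_det)
print(fit.center_mm, fit.effective_diameter_mm)
plan = plan_trajectory(fit)
print([(w.label, w.position_mm) for w in plan.waypoints], plan_duration(plan))
```

Running this prints (seed 11):

```
(0.0195387..., 34.8415...) 10.8245...
[('A', 42.34...), ('B', 37.93...), ('C', 43.34...), ('D', 32.52...), ('E', 37.93...)] 3.33...
```

The fitted vein centroid sits 0.02 mm lateral of the probe axis at
34.8 mm along the needle path with a 10.8 mm effective diameter; the
planned waypoints overshoot the centroid (B) to 1 mm short of the
posterior wall (A), dither C → D → E, and the whole sequence takes
3.3 s — a little over the ~3 s typical of a 2 cm-deep vein, because
this subject's vein is unusually deep (30 mm to the anterior wall). The narrative
scripts in `examples/` walk through phantom generation, segmentation
accuracy, the guidance loop, and matched normotensive/hypotensive
campaigns; a thin CLI (`vascaccess phantom|detect|segment|guide|insert|
eval-pr|eval-centroid|campaign`) exposes the same stages for shell use.

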