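# Methods

This note documents the models behind `vascaccess`: what each stage
assumes, which parameters matter and why their defaults were chosen,
what the synthetic phantom does and does not emulate, and the numerical
choices that shape the results.

## Anatomy model

A subject is two elliptical lumen cross-sections (artery, vein) in the
lateral–depth plane, each with a skin-to-anterior-wall depth, lateral
diameter, wall thickness, and aspect ratio (depth axis / lateral axis;
1 = circular). Draws use normals truncated at ±3 sd — population
statistics for adult femoral vessels:

| parameter | vein | artery |
|---|---|---|
| depth (mm) | 22 ± 6 | 18 ± 6 |
| diameter (mm) | 9 ± 3 | 8 ± 2 |
| wall thickness (mm) | 0.6 ± 0.1 | 1.2 ± 0.15 |
| aspect ratio | 0.85 ± 0.08 | 0.95 ± 0.03 |

Anteroposterior artery-over-vein overlap is drawn as a Bernoulli event
with prevalence 0.65; given the draw, the lateral separation of the
centres is placed strictly inside (35–90% of the summed lateral
semi-diameters) or strictly outside (110–140%) the overlap region, so
the geometric overlap fraction estimates the prevalence without
boundary ambiguity. The artery sits toward image-left of the vein for a
right leg; a mirror flag flips it.

Two constraints are enforced after the marginal draws:

- **Field of view.** The imaged depth is 40 mm. A vessel whose
  *vertical* extent (depth + diameter × aspect) would leave the image is
  first flattened (aspect reduced, floor 0.5) and only then shrunk.
  This keeps the depth and diameter marginals essentially exact (the
  adjustment touches roughly 1% of draws) — a joint rejection rule was
  rejected because it visibly biased the vein depth distribution.
- **Non-interpenetration.** Vessels may overlap in anteroposterior
  projection but are physical tubes: when the outer walls would
  intersect in-plane, the artery is pulled anteriorly (it crosses over
  the vein) until a 0.5 mm clearance holds, with the vein pushed deeper
  only in rare shallow-vein cases.

Hypotension multiplies the vein diameter by 0.6, its aspect by 0.8
(flattening), the artery diameter by 0.9, and the tenting capacity by
2.0. Direction is physiologic (compensatory venous collapse, more
compliant walls); the magnitudes are configurable because quantitative
mappings from arterial pressure to femoral geometry are not
established. Tenting capacity — the anterior-wall deflection a needle
can impose before puncture — is drawn from a truncated normal
4.5 ± 1.5 mm (floor 0.5 mm), calibrated so that first-attempt insertion
success under default normotensive conditions lands near 0.9.

## Rendering

Frames are 400 × 384 px at 0.1 mm/px isotropic (40 mm depth of view);
the fine grid leaves sub-pixel headroom for centroid evaluation at the
0.3 mm level. Rendering composes: a smoothed Gaussian tissue texture
around a mean grey of 110; wall rings painted at 225 (artery) or 175
(vein); lumens at 18; a 0.8 px Gaussian edge blur; then multiplicative
speckle `I → I (1 + 0.35 n)` with spatially correlated unit-variance
noise. This is an appearance model, not acoustics: no attenuation,
refraction, shadowing, anisotropy, or depth-dependent resolution.
Passing tests therefore demonstrate algorithmic correctness on
controlled imagery, not clinical performance on real ultrasound.

Within ±5 mm (cranio-caudal) of the bifurcation coordinate the vein is
drawn as two merging daughter lobes (0.72× lateral scale, ±0.62 lateral
offsets) and labelled `bifurcation` in the ground truth. Ground-truth
boundaries are exact ellipse polygons (union polygons for the merged
case, via shapely); bounding boxes are the half-open pixel ranges
covering the lumen.

## Segmentation chain

`segment_vessel` crops the detection box plus a 20% margin, inverts so
the lumen is bright, and thresholds with Otsu's criterion computed on
the full 0–255 histogram (classes ≤ t vs > t, ties to the lower
threshold; constant input is an error). The mask is opened and closed
with a radius-2 elliptical element and components under 30 px² are
dropped — sized to erase speckle islands at 0.1 mm spacing without
eroding a 5 mm lumen. A contrast gate rejects ROIs whose "lumen" is not
at least 30% darker than its surround, turning bare-tissue boxes into a
clean failure signal instead of a junk fit.

Thirty-two spokes radiate from the box centre in 0.3 px steps; each
boundary point is the midpoint of the last-inside/first-outside pair,
and at least 60% of spokes must hit within 1.5× the box half-diagonal
(partial-occlusion tolerance with junk rejection). The ellipse is a
direct least-squares conic fit (scikit-image's estimator); if the conic
degenerates the fallback is the boundary centroid with an RMS-radius
circle. On noiseless renders the centre lands well inside one pixel;
under default speckle the median absolute error per axis and class
stays an order of magnitude below the 0.3 mm acceptance bound.

## Classical detector

The default backend smooths (σ = 2 px), thresholds dark blobs with an
adaptive Otsu (re-thresholding within the dark side when more than 30%
of the frame comes out dark), and filters candidates by: area between
25% of the smallest and 400% of the largest prior-mean class area
(the hypotensive vein anchors the lower end), interior/surround
contrast below 0.40, and circularity of at least 0.55. Artery vs vein
is a linear margin on the upper-quartile wall-ring intensity (split at
215) plus a circularity term; the reported score is the
logistic-squashed margin distance (a per-frame min–max normalisation is
ill-defined when a frame holds a single detection). Two
distance-transform lobes separated by a genuine neck classify a blob as
a bifurcation. The backend slot accepts any callable
`frame → detections`; training a convolutional replacement is out of
scope here.

Multi-frame smoothing carries the most recent box of a missing class
forward with its age; nothing at or beyond `max_age = 5` frames
(~0.17 s at 30 Hz) is emitted, so stale boxes cannot steer the needle.

## Guidance

The projected needle path lies in the elevational plane through the
probe centre, so the tracking error x is just the target centroid's
lateral offset in device coordinates. Display gain is 1.0 display-mm
per device-mm beyond the 5 mm yellow radius and 3.0 inside it (finer
control near target; values are display ergonomics, config-exposed).
Colours: red when the target is absent or |x| > 5 mm; green only when
|x| is inside the dynamic insertion window (10% of the effective
diameter), the analytic segment–ellipse safety check finds no
untargeted vessel on the path, no bifurcation is in view, and the
target fit is current (age 0) — everything else is yellow. Repositioning
cues default to cranial, where the common femoral segment lies. A
stateful session adds hysteresis: colour upgrades require 3 consecutive
qualifying frames, downgrades are immediate, and hysteresis never
displays green on a frame whose raw evaluation is unsafe.

## Needle planning and insertion simulation

Planning treats the lumen cross-section in the needle plane as a circle
of the effective radius √(ab): the anterior wall, centroid, and
posterior wall sit at L − r, L, L + r along the path, where L is the
entry-to-centroid distance and the angle from the skin is
arctan(depth / 15 mm entry offset). Waypoints and speeds:
A = posterior − 1 mm at 45 mm/s, B = centroid at 20 mm/s, C = posterior,
D = anterior, E = centroid at 10 mm/s. The fast first leg minimises
kickback exposure; the slow dither gives the flashback sensor time.
Planned paths beyond the 90 mm needle, or vessels too small to hold the
1 mm posterior margin, are planning errors.

The simulator steps the tip at 100 Hz. Per attempt: one Gaussian
kickback draw (0.5 mm lateral, 0.5° angular) perturbs the path at skin
strike; the true chord through the vein follows from the total lateral
offset. The anterior wall deflects rigidly with the tip and punctures
the instant deflection exceeds the effective tenting capacity,
recovering on reversal. Effective capacity carries a per-attempt
lognormal jitter (σ = 0.25) — with a purely deterministic threshold a
retry could never succeed where the first attempt failed, which
contradicts the retry behaviour the device exploits; σ = 0 restores the
deterministic wall. Flashback is sampled every step (ideal sensor; an
optional delay models syringe fill) and halts motion immediately, which
is why a successful stop is always intra-luminal and the posterior wall
survives whenever the lateral error is inside the insertion window.
A full A→E pass without blood fails the attempt; the needle retracts at
45 mm/s and retries up to 3 attempts per trial. Image-change
confirmation (mean |ΔI| in a circular ROI at the predicted tip against
a threshold of 8 grey levels) is secondary and never overrides
flashback.

## Campaigns

`run_campaign` closes the loop per trial: sample an anatomy, render at
the current probe pose, detect (or use ground-truth boxes), smooth,
segment, update guidance, and move a simulated operator by the dot
offset (plus 0.3 mm motor noise) until ready — at most 40 frames,
otherwise the trial is a non-acquisition (reported, not an error;
persistent artery interposition is the usual cause, since this phantom's
vessels run parallel and cranial scanning cannot clear them). Then plan
from the fitted vein and simulate with the anatomy's own tenting
capacity. Summaries report per-attempt success with exact
Clopper–Pearson 95% intervals (the interval construction reproduces
printed clinical-style margins such as 36/39 → 79–98%), mean attempts
over insertion trials, and first-attempt successes. On matched seeds
the hypotensive condition yields strictly more mean attempts than the
normotensive one; its absolute success rate is far below clinical
experience because the default hypotension factors stack harshly — the
direction, not the magnitude, is the validated claim.

## Problem sizes and determinism

The test suite and acceptance script use 200 rendered frames for
centroid accuracy, 150 frames for PR evaluation, 10,000 anatomy draws
for the overlap prevalence, 1,000 seeded geometries/insertions for the
safety and flashback property suites, and 12–16 trials per campaign
condition — sizes at which every statistical assertion is comfortably
inside its tolerance while the whole suite runs in a few minutes on one
CPU. Every stochastic component takes an explicit integer seed through
`numpy.random.default_rng`; identical seeds give bit-identical frames,
fits, plans, and simulation traces.

## Known limitations

- The phantom is an appearance model; detector and segmentation scores
  here do not transfer to real B-mode imagery.
- Vessels are straight, parallel tubes: cranio-caudal scanning changes
  only the bifurcation appearance, not the overlap geometry, so safety
  hazards that a clinician would resolve by scanning resolve here only
  as non-acquisitions.
- Needle depth error is not simulated (the planned centroid distance is
  taken as true along-path centre); only lateral error and kickback
  perturb the chord.
- The cranio-caudal "low positioning" hazard is implemented as a
  caller-injected cue rather than estimated from imagery, since skin
  landmarks are not rendered.
- Guidewire and catheter mechanics are recorded only as
  "guidewire-ready" on success.
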