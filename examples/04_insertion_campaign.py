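"""Plan and simulate needle insertions, then run a small campaign.

First a single planned insertion with its waypoint schedule and timing,
then matched normotensive and hypotensive campaigns through the full
closed loop (sample -> render -> detect -> segment -> guide -> insert)
showing how hypotension (smaller, flatter veins; doubled tenting) raises
the attempt count.
"""

import numpy as np

import vascaccess as va
from vascaccess.evaluate import CampaignConfig, run_campaign
from vascaccess.needle import (NeedleGeometry, TissueParams, plan_duration,
                               plan_trajectory, simulate_insertion)
from vascaccess.segmentation import VesselFit

fit = VesselFit(center_mm=(0.0, 20.0), semi_axes_mm=(5.0, 5.0),
                rotation_deg=0.0, boundary_points_mm=np.empty((0, 2)),
                cls="vein")
plan = plan_trajectory(fit, NeedleGeometry(entry_offset_mm=15.0))
print(f"insertion angle {plan.angle_deg:.1f} deg from skin")
for wp in plan.waypoints:
    print(f"  waypoint {wp.label}: {wp.position_mm:5.1f} mm along path "
          f"at {wp.speed_mm_s:.0f} mm/s")
print(f"total planned time {plan_duration(plan):.2f} s (bound: ~3 s)\n")

anatomy = va.sample_anatomy(va.AnatomyPriors(), seed=3)
tissue = TissueParams(tenting_capacity_mm=anatomy.tenting_capacity_mm)
result = simulate_insertion(plan, anatomy, tissue, lateral_error_mm=0.3,
                            seed=3)
print(f"single trial: success={result.success} after {result.attempts} "
      f"attempt(s), stop at {result.stop_position_mm:.1f} mm, "
      f"flashback at {result.flashback_time_s:.2f} s\n")

seeds = range(12)
for condition in (va.NORMOTENSIVE, va.HYPOTENSIVE):
    summary = run_campaign(CampaignConfig(condition=condition), seeds)
    lo, hi = summary.success_rate_ci95
    print(f"{condition:13s}: {summary.successes}/{summary.n_attempts} "
          f"attempts successful = {100 * summary.success_rate:.0f}% "
          f"({100 * lo:.0f}-{100 * hi:.0f}%), "
          f"mean attempts {summary.mean_attempts:.2f}, "
          f"non-acquisitions {summary.non_acquisitions}")
# The hypotensive campaign needs more attempts per insertion on the same
# seeds - the direction clinical experience predicts.
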