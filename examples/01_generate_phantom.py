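"""Generate a synthetic femoral cross-section and inspect its ground truth.

Samples one subject anatomy from the population priors, renders a
transverse B-mode frame with the probe centred over the vein, and prints
the per-lumen ground truth the evaluation pipeline relies on.
"""

import vascaccess as va

priors = va.AnatomyPriors()
anatomy = va.sample_anatomy(priors, seed=7)
print(f"vein:   depth {anatomy.vein.depth_mm:.1f} mm, "
      f"diameter {anatomy.vein.diameter_mm:.1f} mm")
print(f"artery: depth {anatomy.artery.depth_mm:.1f} mm, "
      f"diameter {anatomy.artery.diameter_mm:.1f} mm")
print(f"anteroposterior artery-over-vein overlap: {anatomy.has_ap_overlap}")

frame, truth = va.render_frame(anatomy,
                               (anatomy.vein.lateral_center_mm, 0.0), seed=7)
print(f"\nframe: {frame.n_rows}x{frame.n_cols} px at "
      f"{frame.pixel_spacing_mm} mm/px "
      f"({frame.depth_extent_mm:.0f} mm depth of view)")
for rec in truth:
    lat, depth = rec.centroid_mm
    print(f"  {rec.cls:6s} centroid ({lat:+.2f}, {depth:.2f}) mm, "
          f"bbox rows {rec.bbox[0]}-{rec.bbox[2]}")
# The centroids are what the segmentation stage must recover to within
# a fraction of a millimetre for safe needle targeting.

hypo = va.apply_hypotension(anatomy, priors)
print(f"\nafter hypotension: vein {hypo.vein.diameter_mm:.1f} mm "
      f"(was {anatomy.vein.diameter_mm:.1f}), tenting capacity "
      f"{hypo.tenting_capacity_mm:.1f} mm (was "
      f"{anatomy.tenting_capacity_mm:.1f})")
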