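"""Measure one eye from raw pixel landmarks.

Builds a synthetic digitization (four Bezier control points, a corneal
limbus pair 240 px apart, a pupil center), normalizes it into the calibrated
pupil-origin frame and prints every contour metric.
"""

from lidcontour import SyntheticEyeSpec, generate_eye, measure_all, normalize_eye

landmarks, _ = generate_eye(
    SyntheticEyeSpec(
        width_mm=25.0,
        peak_height_mm=4.5,
        peak_temporal_offset_mm=1.6,
        obliquity_deg=9.0,
        subject_id="demo",
    )
)
eye = normalize_eye(landmarks)  # 12 mm corneal diameter -> mm scale
m = measure_all(eye)

print(f"scale: {eye.scale_mm_per_px:.4f} mm/px")
print(f"eye width:            {m.eye_width_mm:6.2f} mm   (horizontal canthal extent)")
print(f"MRD1:                 {m.mrd1_mm:6.2f} mm   (pupil center to margin, vertical)")
print(f"contour peak height:  {m.peak_height_mm:6.2f} mm")
print(f"contour peak offset:  {m.peak_temporal_offset_mm:6.2f} mm temporal")
print(f"fissure obliquity:    {m.fissure_obliquity_deg:6.2f} deg  (lateral canthus up-slant)")
print("\nMPLD profile (deg -> mm, 0 = nasal, 180 = temporal):")
for angle in m.mpld.angles:
    d = m.mpld[angle]
    print(f"  {angle:5.0f}  {'—' if d is None else format(d, '5.2f')}")
print(f"\ntemporal:nasal ratio 180/0: {m.tn_ratios[(180.0, 0.0)]:.3f}"
      "  (>1 = temporally fuller contour)")
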