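"""Fit a cubic Bezier to traced margin points.

When a lid margin is available as an ordered point trace rather than four
control points, `fit_bezier` recovers the control polygon by least squares
(chord-length start, parameter-correction refinement).  Here the trace is a
known curve plus 0.05 mm of jitter, so the recovery error is measurable.
"""

import numpy as np

from lidcontour import ControlPolygon, bezier_peak, bezier_point, fit_bezier

rng = np.random.default_rng(3)
true = ControlPolygon((12.5, -3.0), (6.0, 6.5), (-4.0, 7.0), (-12.5, -0.5))
trace = bezier_point(true, np.linspace(0, 1, 150))
trace_noisy = trace + rng.normal(0.0, 0.05, trace.shape)

fitted, rms = fit_bezier(trace_noisy, endpoints=(true.p0, true.p3))
_, peak_true = bezier_peak(true)
_, peak_fit = bezier_peak(fitted)

print(f"fit RMS residual:      {rms:.4f} mm (noise SD was 0.05 mm)")
print(f"true peak height:      {peak_true[1]:.4f} mm")
print(f"recovered peak height: {peak_fit[1]:.4f} mm "
      f"(error {abs(peak_fit[1] - peak_true[1]):.4f} mm)")
print("The residual matching the noise level means the cubic model itself "
      "is not the bottleneck.")
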