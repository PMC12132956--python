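"""Two-rater agreement on contour peak height.

Simulates two raters independently digitizing the same 80 eyes (0.25 mm
control-point jitter each), then computes the intraclass correlation
(two-way random effects, absolute agreement — single and average measures)
and Bland-Altman limits of agreement, and saves the Bland-Altman plot.
"""

import numpy as np

from lidcontour import (
    PopulationSpec,
    bland_altman,
    generate_cohort,
    icc_2_1,
    icc_2_k,
    measure_all,
    normalize_eye,
    simulate_raters,
)
from lidcontour.plots import bland_altman_plot

rng = np.random.default_rng(7)
cohort = generate_cohort(PopulationSpec(), 40, 40, rng)
r1, r2 = simulate_raters(cohort.landmarks, rater_sd_mm=0.25, rng=rng)

h1 = np.array([measure_all(normalize_eye(lm)).peak_height_mm for lm in r1])
h2 = np.array([measure_all(normalize_eye(lm)).peak_height_mm for lm in r2])

single = icc_2_1(np.column_stack([h1, h2]))
average = icc_2_k(np.column_stack([h1, h2]))
ba = bland_altman(h1, h2)

print(f"ICC(A,1) = {single.icc:.3f}  (95% CI {single.ci_low:.3f}–{single.ci_high:.3f})")
print(f"ICC(A,k) = {average.icc:.3f}  (95% CI {average.ci_low:.3f}–{average.ci_high:.3f})")
print(f"Bland-Altman bias {ba.bias:+.3f} mm, limits "
      f"[{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] mm")
print("ICC near 1 and narrow limits mean the contour digitization, not the "
      "rater, dominates the measurement.")

bland_altman_plot(ba, "bland_altman_peak_height.png")
print("plot written to bland_altman_peak_height.png")
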