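"""Simulate a normative cohort and print its summary table.

Draws 40 female and 40 male right eyes from the default population moments,
measures each through the full pixel pipeline and prints the mean +/- SD by
sex with the Welch p-value for the sex difference — the layout normative
eyelid-contour tables are reported in.
"""

import numpy as np

from lidcontour import (
    PopulationSpec,
    generate_cohort,
    measure_all,
    normalize_eye,
    summarize_cohort,
)

rng = np.random.default_rng(2024)
cohort = generate_cohort(PopulationSpec(), n_female=40, n_male=40, rng=rng)
measured = [measure_all(normalize_eye(lm)) for lm in cohort.landmarks]
table = summarize_cohort(measured, cohort.sex)

rows = ["eye_width_mm", "fissure_obliquity_deg", "mrd1_mm",
        "peak_temporal_offset_mm", "peak_height_mm", "ratio_180_0"]
print(f"{'metric':26s} {'female':>14s} {'male':>14s} {'p':>8s}")
for r in rows:
    f = f"{table.loc[r, 'female_mean']:.2f} ± {table.loc[r, 'female_sd']:.2f}"
    m = f"{table.loc[r, 'male_mean']:.2f} ± {table.loc[r, 'male_sd']:.2f}"
    print(f"{r:26s} {f:>14s} {m:>14s} {table.loc[r, 'p_value']:8.3f}")
print("\nSmall p-values for MRD1 / peak height / obliquity reflect the "
      "sex differences built into the population moments.")
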