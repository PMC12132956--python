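# Methods

## Model

The upper-lid margin is modelled as a cubic Bézier curve: two canthal
endpoints and two interior control points, B(t) on the Bernstein basis for
t ∈ [0, 1]. A cubic is the lowest degree that can represent the asymmetric,
single-peaked arch of a lid margin, and matches how such margins are
digitized in practice (two draggable control points). Rational Béziers,
higher degrees and splines are out of scope.

All metrics are read in a canonical anatomical frame. A raw digitization is
pixels with y down; normalization (i) subtracts the manually marked pupil
center, (ii) flips y so superior is positive, (iii) scales by
`corneal_diameter_mm / ‖limbus_a − limbus_b‖` (default 12.0 mm white-to-white,
the conventional adult value; configurable), and (iv) mirrors x by laterality
so nasal is always +x. Distances are therefore relative lengths anchored to
the corneal diameter, not absolute lengths — adequate because contour
assessment works with ratios and within-frame distances. The mirror step
depends on whether photographs are viewer-oriented or mirrored, which is a
property of the acquisition pipeline, not the anatomy; it is a `mirror_policy`
argument (default `"viewer"`: OD nasal = image +x) rather than an assumption.

### Metric definitions

- Eye width: |Δx| of the endpoints (horizontal extent, not chord length).
- Fissure obliquity θ: atan2(y_lat − y_med, |Δx|), positive when the lateral
  canthus is higher; baseline is the image horizontal (no head-pose
  correction).
- MPLD at angle θ: solve sin θ·x(t) − cos θ·y(t) = 0 — a cubic in t via the
  companion matrix (imaginary parts < 1e−9 treated as real) — keep roots with
  t ∈ [0, 1] and radius r = x cos θ + y sin θ ≥ 0, and return the smallest r:
  walking outward from the pupil center, the first margin crossing is the
  anatomical distance. An angle with no admissible root is *missing*, not an
  error: a horizontal ray legitimately misses an arch that stays above the
  pupil line. MRD1 is the 90° entry, by identity (the same profile cell, not
  a second computation).
- Contour peak: the global maximum of y(t); y′ is quadratic, so candidates
  are its real roots in [0, 1] plus the endpoints. Ties break toward smaller
  t, making flat curves deterministic. The temporal offset is −x of the
  maximizer (temporal positive).
- Temporal:nasal ratios: MPLD(temporal)/MPLD(nasal) for the six mirror pairs.
  The per-eye "ratio total" has no single established definition; the default
  is the arithmetic mean of the six pair ratios, a `sum_ratio` variant
  (Σ temporal / Σ nasal) is selectable, and outputs are labelled with the
  definition used. Note a ratio of cohort-mean profiles is not the cohort
  mean of per-eye ratios; tables built from this package use per-eye ratios.

### Curve fitting

`fit_bezier` recovers a control polygon from an ordered margin trace:
chord-length initial parameters, a few Hoschek parameter-correction rounds
(project each sample onto the current fit, re-solve the linear problem for
the interior points), then a variable-projection least-squares polish over
the sample parameters with the interior control points always solved
linearly. Plain chord-length fitting was measurably inadequate: with noisy
or unevenly spaced samples the parameterization error appears as a
systematic peak-height bias of ~0.1 mm, whereas the corrected fit recovers
noiseless cubics to machine precision and keeps the mean peak-height error
an order of magnitude below the sample noise SD. The procedure is
deterministic; endpoints are held fixed when supplied.

## Reliability statistics

ICC uses the two-way random-effects, absolute-agreement model:
ICC(A,1) = (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)) from the ANOVA
mean squares, with F-distribution confidence bounds (McGraw–Wong,
Satterthwaite df); ICC(A,k) follows by the Spearman–Brown step-up, applied
to the estimate and both bounds. Both forms are always reported, since
single- vs average-measure coefficients are easy to conflate when reading
published values. The mean-squares path is written out here (rather than
delegated) so the confidence level is a free parameter; pingouin serves as
an independent cross-check in the tests. Bland–Altman limits are
bias ± 1.96·SD(d) with the n−1 SD — the conventional large-sample form, not
the t-quantile variant. Group comparisons default to Welch's t (variance
assumption-free) with a pooled-variance toggle.

## Synthetic data

The generator is construction, not simulation-of-an-image: endpoints are
placed from width, obliquity and the pupil offset; requiring the curve at
t = ½ to sit at the requested peak with horizontal tangent fixes the interior
y-coordinates (two linear equations) and the interior x-sum; the remaining
x degree of freedom is a symmetric spread of w/4, which keeps x(t) monotone
for realistic anatomy. Ground-truth metrics are therefore analytic, and the
noise-free pipeline round-trip is an identity to ≤ 1e−6 mm/deg (tested).
Infeasible requests (peak outside the horizontal extent, peak below the
canthi) raise rather than silently distort.

By default the pupil sits on the canthal-endpoint midline horizontally, and
vertically so that the lateral canthus lies 0.5 mm below the pupil
horizontal (the medial canthus lower still, by the up-slant). This encodes
the primary-gaze configuration in which both canthi fall below the pupil
center and the temporal 180° ray meets the margin close to the temporal
half-width — the pattern seen in normative adult MPLD profiles. It is
overridable per eye (`pupil_offset_mm`).

Cohorts draw per-subject width, peak height/offset and obliquity from
truncated normals (±4 SD and physical bounds) with sex-specific default
moments for healthy young Asian adults — female: width 24.82 ± 1.82 mm, peak
height 4.74 ± 0.68 mm, peak offset 1.67 ± 1.02 mm, obliquity 9.98 ± 3.07°;
male: 25.25 ± 2.00, 3.84 ± 0.93, 1.49 ± 1.33, 7.52 ± 2.89. The reference
configuration is 40 + 40 right eyes. Rater simulation jitters each rater's
four control points independently; the default 0.25 mm SD (≈ 5 px at
0.05 mm/px) represents careful manual digitization and maps to ≈ 0.14 mm of
peak-height noise (the Bernstein weights at the apex give σ_peak ≈ 0.559·σ
per rater), i.e. an expected peak-height ICC in the high 0.9s. An optional
systematic vertical bias for rater 2 exercises the Bland–Altman bias line.

What the generator does **not** emulate: digitization is drawn around an
exactly-cubic truth, so tests quantify pipeline correctness and rater noise
propagation — they cannot detect model misfit of a real lid margin to a
cubic, pupil-center marking error, head tilt, or camera perspective.
Calibration landmarks are kept exact under jitter, so calibration error is
likewise out of scope. Parameters are drawn independently per subject (no
width–height correlation).

## Numerical choices

- Cubic/quadratic roots via the companion matrix; |Im| < 1e−9 → real;
  parameters clipped to [0, 1] with 1e−9 edge tolerance; radii ≥ −1e−9
  clamped to 0.
- All randomness flows through one `numpy.random.Generator`; identical seeds
  give byte-identical output files.
- Output tables display 2 decimals (the conventional reporting precision);
  full precision is always available (`precision=None`).
- Test problem sizes: the brute-force geometry check uses 1,000 random
  curves against a 10⁶-point sampling oracle (1e−4 mm agreement on ray
  crossings, 1e−6 on peaks); pipeline round-trips use 500 eyes; ICC recovery
  uses 500 replicates of n = 200 tables; Bland–Altman coverage uses 10⁴
  pairs.

## Known limitations

- Landmarks are inputs: no image processing, pupil/limbus detection or
  tilt correction.
- The medial endpoint convention (medial palpebral commissure, suited to
  eyes with an epicanthal fold) is whatever the digitizer used; the package
  cannot verify it.
- Lower-lid metrics (MRD2) and canthal height metrics are not defined.
- ICC confidence bounds assume a complete n × k table; missing cells must be
  removed listwise upstream.
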