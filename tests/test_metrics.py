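import math

import numpy as np
import pytest

from lidcontour import (
    CANONICAL_ANGLES_DEG,
    MPLDProfile,
    NormalizedEye,
    SyntheticEyeSpec,
    contour_peak,
    eye_width,
    fissure_obliquity,
    generate_eye,
    measure_all,
    mpld_profile,
    mrd1,
    normalize_eye,
    solve_control_polygon,
    tn_ratios,
)
from lidcontour.geometry import ControlPolygon

from .conftest import make_landmarks
from .oracles import dense_samples, ray_crossing


def _eye_from_curve(curve: ControlPolygon) -> NormalizedEye:
    return NormalizedEye(curve=curve, scale_mm_per_px=0.05, laterality="OD")


class TestScalarMetrics:
    def test_eye_width_symmetric(self, symmetric_eye):
        assert eye_width(symmetric_eye) == pytest.approx(25.0, abs=1e-12)

    def test_eye_width_ignores_vertical_offset(self):
        curve = ControlPolygon((10, 0), (4, 5), (-4, 5), (-10, 4))
        assert eye_width(_eye_from_curve(curve)) == pytest.approx(20.0)

    def test_obliquity_zero_for_level_endpoints(self, symmetric_eye):
        assert fissure_obliquity(symmetric_eye) == pytest.approx(0.0, abs=1e-9)

    def test_obliquity_constructed_ten_degrees(self):
        lateral_y = 24.0 * math.tan(math.radians(10.0))
        curve = ControlPolygon((12, 0), (4, 6), (-4, 6), (-12, lateral_y))
        assert fissure_obliquity(_eye_from_curve(curve)) == pytest.approx(
            10.0, abs=1e-9
        )

    def test_obliquity_hand_trigonometry(self):
        curve = ControlPolygon((12.5, -0.8), (4, 6), (-4, 6), (-12.3, 2.9))
        expected = math.degrees(math.atan2(2.9 - (-0.8), 12.5 + 12.3))
        assert fissure_obliquity(_eye_from_curve(curve)) == pytest.approx(
            expected, abs=1e-12
        )


class TestMPLDProfile:
    def test_symmetric_profile_mirrors(self, symmetric_eye):
        prof = mpld_profile(symmetric_eye)
        for theta in (0.0, 15.0, 30.0, 45.0, 60.0, 75.0):
            assert prof[theta] == pytest.approx(prof[180.0 - theta], abs=1e-9)

    def test_thirteen_canonical_angles(self, default_eye):
        prof = mpld_profile(default_eye)
        assert len(prof) == 13
        assert prof.angles == CANONICAL_ANGLES_DEG

    def test_mrd1_is_profile_at_90(self, default_eye):
        prof = mpld_profile(default_eye)
        assert mrd1(default_eye) == prof[90.0]

    def test_matches_sampling_oracle(self, rng, default_eye):
        grid = dense_samples(default_eye.curve.points)
        prof = mpld_profile(default_eye)
        for theta in CANONICAL_ANGLES_DEG:
            r_oracle = ray_crossing(default_eye.curve.points, theta, grid)
            if prof[theta] is None:
                assert r_oracle is None
            else:
                assert prof[theta] == pytest.approx(r_oracle, abs=1e-4)

    def test_positive_distances_enforced(self):
        with pytest.raises(Exception):
            MPLDProfile({90.0: -1.0})


class TestContourPeak:
    def test_symmetric_arch_centered(self, symmetric_eye):
        offset, height = contour_peak(symmetric_eye)
        assert offset == pytest.approx(0.0, abs=1e-9)
        assert height == pytest.approx(4.0, abs=1e-9)

    def test_nasal_shift_flips_sign(self, symmetric_eye):
        # translate the whole curve 1.5 mm nasally (+x): the peak moves
        # nasally, so the temporal-positive offset reads -1.5
        pts = symmetric_eye.curve.points + np.array([1.5, 0.0])
        shifted = _eye_from_curve(ControlPolygon(*pts))
        offset, height = contour_peak(shifted)
        assert offset == pytest.approx(-1.5, abs=1e-9)
        assert height == pytest.approx(4.0, abs=1e-9)

    def test_mrd1_when_pupil_under_peak(self):
        spec = SyntheticEyeSpec(
            peak_temporal_offset_mm=0.0, obliquity_deg=0.0,
            pupil_offset_mm=(0.0, 1.0),
        )
        eye = _eye_from_curve(solve_control_polygon(spec))
        assert mrd1(eye) == pytest.approx(spec.peak_height_mm, abs=1e-9)


class TestTNRatios:
    def test_symmetric_profile_gives_unit_ratios(self, symmetric_eye):
        ratios = tn_ratios(mpld_profile(symmetric_eye))
        for v in ratios.ratios.values():
            assert v == pytest.approx(1.0, abs=1e-9)
        assert ratios.ratio_total == pytest.approx(1.0, abs=1e-9)

    def test_direct_division(self):
        prof = MPLDProfile({a: 5.0 for a in CANONICAL_ANGLES_DEG} | {180.0: 12.0, 0.0: 9.0})
        ratios = tn_ratios(prof)
        assert ratios[(180.0, 0.0)] == pytest.approx(12.0 / 9.0)

    def test_cohort_mean_profile_ratio(self):
        """Female mean temporal/nasal horizontal distances divide to 1.332.

        (A ratio of means — deliberately not the mean of per-subject ratios,
        which is a different statistic.)
        """
        female_means = {
            180.0: 12.15, 165.0: 9.73, 150.0: 7.66, 135.0: 6.28, 120.0: 5.40,
            105.0: 4.87, 90.0: 4.62, 75.0: 4.59, 60.0: 4.78, 45.0: 5.23,
            30.0: 6.00, 15.0: 7.24, 0.0: 9.12,
        }
        ratios = tn_ratios(MPLDProfile(female_means))
        assert ratios[(180.0, 0.0)] == pytest.approx(12.15 / 9.12, abs=1e-12)
        assert ratios[(180.0, 0.0)] == pytest.approx(1.332, abs=5e-4)

    def test_missing_entry_propagates(self):
        prof = MPLDProfile(
            {a: 5.0 for a in CANONICAL_ANGLES_DEG} | {0.0: None}
        )
        ratios = tn_ratios(prof)
        assert ratios[(180.0, 0.0)] is None
        assert ratios.ratio_total is None

    def test_sum_ratio_definition(self):
        prof = MPLDProfile({a: 5.0 for a in CANONICAL_ANGLES_DEG} | {180.0: 12.0, 0.0: 9.0})
        r = tn_ratios(prof, total="sum_ratio")
        expected = (12.0 + 5.0 * 5) / (9.0 + 5.0 * 5)
        assert r.ratio_total == pytest.approx(expected)
        assert r.definition == "sum_ratio"


class TestMeasureAll:
    def test_symmetric_reference_eye(self, symmetric_eye):
        m = measure_all(symmetric_eye)
        assert m.eye_width_mm == pytest.approx(25.0, abs=1e-9)
        assert m.mrd1_mm == pytest.approx(4.0, abs=1e-9)
        assert m.peak_temporal_offset_mm == pytest.approx(0.0, abs=1e-9)
        assert m.fissure_obliquity_deg == pytest.approx(0.0, abs=1e-9)
        assert m.tn_ratios.ratio_total == pytest.approx(1.0, abs=1e-9)

    def test_mrd1_identical_to_profile_entry(self, default_eye):
        m = measure_all(default_eye)
        assert m.mrd1_mm == m.mpld[90.0]  # bitwise, not approximate

    def test_peak_dominates_mrd1_over_random_eyes(self, rng):
        from lidcontour import PopulationSpec, generate_cohort

        cohort = generate_cohort(PopulationSpec(), 15, 15, rng)
        for lm in cohort.landmarks:
            m = measure_all(normalize_eye(lm))
            assert m.peak_height_mm >= m.mrd1_mm - 1e-12

    def test_translation_invariance_in_pixels(self):
        bez = [(712, 377), (655, 302), (404, 315), (303, 391)]
        lm1 = make_landmarks(bez, pupil=(512, 401))
        shift = np.array([37.0, -12.0])
        lm2 = make_landmarks(
            [tuple(np.asarray(p) + shift) for p in bez],
            pupil=tuple(np.asarray((512, 401)) + shift),
        )
        m1 = measure_all(normalize_eye(lm1))
        m2 = measure_all(normalize_eye(lm2))
        assert m1.eye_width_mm == pytest.approx(m2.eye_width_mm, abs=1e-9)
        assert m1.peak_height_mm == pytest.approx(m2.peak_height_mm, abs=1e-9)
        assert m1.mrd1_mm == pytest.approx(m2.mrd1_mm, abs=1e-9)

    def test_calibration_invariance_under_uniform_rescale(self):
        """Upsampling the image (all pixels x c) changes no mm metric."""
        c = 1.7
        bez = np.array([(712, 377), (655, 302), (404, 315), (303, 391)], float)
        lm1 = make_landmarks(bez, pupil=(512, 401), limbus_sep_px=240.0)
        lm2 = make_landmarks(bez * c, pupil=(512 * c, 401 * c),
                             limbus_sep_px=240.0 * c)
        m1 = measure_all(normalize_eye(lm1))
        m2 = measure_all(normalize_eye(lm2))
        assert m1.eye_width_mm == pytest.approx(m2.eye_width_mm, rel=1e-12)
        assert m1.peak_height_mm == pytest.approx(m2.peak_height_mm, rel=1e-12)
        assert m1.fissure_obliquity_deg == pytest.approx(
            m2.fissure_obliquity_deg, rel=1e-12
        )
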