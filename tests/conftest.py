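import numpy as np
import pytest

from lidcontour import (
    LandmarkSet,
    NormalizedEye,
    SyntheticEyeSpec,
    generate_eye,
    normalize_eye,
    solve_control_polygon,
)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250603)


@pytest.fixture
def default_eye() -> NormalizedEye:
    """A realistic noise-free eye measured through the pixel pipeline."""
    landmarks, _ = generate_eye(SyntheticEyeSpec(subject_id="S001"))
    return normalize_eye(landmarks)


@pytest.fixture
def symmetric_eye() -> NormalizedEye:
    """Mirror-symmetric arch: width 25 mm, peak 4 mm dead over the pupil."""
    spec = SyntheticEyeSpec(
        width_mm=25.0,
        peak_height_mm=4.0,
        peak_temporal_offset_mm=0.0,
        obliquity_deg=0.0,
        pupil_offset_mm=(0.0, 1.0),
    )
    return NormalizedEye(
        curve=solve_control_polygon(spec),
        scale_mm_per_px=spec.scale_mm_per_px,
        laterality="OD",
    )


def make_landmarks(
    bez, pupil=(500.0, 400.0), limbus_sep_px=240.0, laterality="OD", **kw
) -> LandmarkSet:
    """Convenience constructor with a horizontal limbus pair (scale 12/sep)."""
    pupil = np.asarray(pupil, dtype=float)
    half = np.array([limbus_sep_px / 2.0, 0.0])
    return LandmarkSet(
        bezier_px=np.asarray(bez, dtype=float),
        limbus_a_px=pupil - half,
        limbus_b_px=pupil + half,
        pupil_px=pupil,
        laterality=laterality,
        **kw,
    )
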