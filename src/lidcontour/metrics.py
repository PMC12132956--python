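"""Eyelid contour metrics read from a normalized eye.

The metric set mirrors standard oculoplastic morphometry:

* eye width — horizontal extent between the canthal endpoints;
* palpebral fissure obliquity — up-slant of the canthal line, positive when
  the lateral canthus sits higher than the medial one;
* MPLD profile — mid-pupil lid distances along rays every 15 deg from
  0 deg (nasal) to 180 deg (temporal), 13 angles in all;
* MRD1 — identically the MPLD at 90 deg;
* contour peak — highest point of the margin curve, reported as height above
  the pupil center and signed horizontal offset (temporal positive);
* temporal-to-nasal ratios — the six mirror-pair MPLD ratios
  (105:75, 120:60, 135:45, 150:30, 165:15, 180:0) plus a per-eye total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

from .errors import (
    DegenerateGeometryError,
    InternalConsistencyError,
    ValidationError,
)
from .frame import NormalizedEye
from .geometry import bezier_peak, ray_intersection

__all__ = [
    "CANONICAL_ANGLES_DEG",
    "TN_RATIO_PAIRS",
    "MPLDProfile",
    "TNRatios",
    "EyelidMetrics",
    "eye_width",
    "fissure_obliquity",
    "mpld_profile",
    "mrd1",
    "contour_peak",
    "tn_ratios",
    "measure_all",
]

#: the canonical 13-angle radial grid, nasal (0) to temporal (180), step 15
CANONICAL_ANGLES_DEG: tuple[float, ...] = tuple(float(a) for a in range(0, 181, 15))

#: temporal:nasal mirror pairs, equal angles off the vertical midline
TN_RATIO_PAIRS: tuple[tuple[float, float], ...] = (
    (105.0, 75.0),
    (120.0, 60.0),
    (135.0, 45.0),
    (150.0, 30.0),
    (165.0, 15.0),
    (180.0, 0.0),
)

RatioTotalDefinition = Literal["mean_of_pairs", "sum_ratio"]


@dataclass(frozen=True)
class MPLDProfile:
    """Mid-pupil lid distances (mm) on a fixed angle grid; entries may be missing."""

    distances: Mapping[float, float | None]

    def __post_init__(self) -> None:
        dist = {float(a): (None if d is None else float(d))
                for a, d in self.distances.items()}
        for a, d in dist.items():
            if d is not None and d <= 0.0:
                raise ValidationError(f"MPLD at {a} deg must be positive, got {d}")
        object.__setattr__(self, "distances", dist)

    def __getitem__(self, angle_deg: float) -> float | None:
        return self.distances[float(angle_deg)]

    def __len__(self) -> int:
        return len(self.distances)

    @property
    def angles(self) -> tuple[float, ...]:
        return tuple(sorted(self.distances))

    @property
    def missing_angles(self) -> tuple[float, ...]:
        return tuple(a for a in self.angles if self.distances[a] is None)


@dataclass(frozen=True)
class TNRatios:
    """Six temporal-to-nasal MPLD pair ratios and a per-eye total."""

    ratios: Mapping[tuple[float, float], float | None]
    ratio_total: float | None
    definition: RatioTotalDefinition = "mean_of_pairs"

    def __getitem__(self, pair: tuple[float, float]) -> float | None:
        return self.ratios[(float(pair[0]), float(pair[1]))]


@dataclass(frozen=True)
class EyelidMetrics:
    """The full scalar metric set for one eye."""

    eye_width_mm: float
    mrd1_mm: float | None
    peak_temporal_offset_mm: float
    peak_height_mm: float
    fissure_obliquity_deg: float
    mpld: MPLDProfile
    tn_ratios: TNRatios
    laterality: str = ""
    subject_id: str = ""
    rater_id: str = ""


def eye_width(eye: NormalizedEye) -> float:
    """Horizontal extent |x(p0) - x(p3)| in mm (not the oblique chord length)."""
    return abs(eye.curve.p0[0] - eye.curve.p3[0])


def fissure_obliquity(eye: NormalizedEye) -> float:
    """Up-slant of the canthal line, degrees; positive = lateral canthus higher.

    The angle between the medial-to-lateral canthal line and the image
    horizontal: ``atan2(y_lateral - y_medial, |x_medial - x_lateral|)``.
    """
    (x_med, y_med) = eye.curve.p0
    (x_lat, y_lat) = eye.curve.p3
    dx = abs(x_med - x_lat)
    if dx <= 0.0:
        raise DegenerateGeometryError("zero horizontal extent; obliquity undefined")
    return math.degrees(math.atan2(y_lat - y_med, dx))


def mpld_profile(
    eye: NormalizedEye, angles_deg: Iterable[float] = CANONICAL_ANGLES_DEG
) -> MPLDProfile:
    """Radial MPLD at each requested angle; misses propagate as None."""
    out: dict[float, float | None] = {}
    for a in angles_deg:
        hit = ray_intersection(eye.curve, a)
        out[float(a)] = None if hit is None else hit.r
    return MPLDProfile(out)


def mrd1(eye: NormalizedEye) -> float | None:
    """Margin reflex distance 1: the MPLD at 90 deg (vertical ray)."""
    return mpld_profile(eye, angles_deg=(90.0,))[90.0]


def contour_peak(eye: NormalizedEye) -> tuple[float, float]:
    """(temporal offset, height) of the margin's highest point, mm.

    Offset is signed positive temporally (``-x`` of the maximizer, since
    temporal is the -x half-plane); a nasally displaced peak comes out
    negative.
    """
    _, pt = bezier_peak(eye.curve)
    return -float(pt[0]), float(pt[1])


def tn_ratios(
    profile: MPLDProfile,
    total: RatioTotalDefinition = "mean_of_pairs",
) -> TNRatios:
    """Temporal-to-nasal ratios for the six mirror pairs plus a total.

    Each pair ratio is MPLD(temporal angle) / MPLD(nasal angle); a missing or
    zero nasal entry yields a missing ratio.  ``ratio_total`` is, by default,
    the arithmetic mean of the six pair ratios (missing if any pair is);
    ``"sum_ratio"`` instead divides the summed temporal distances by the
    summed nasal ones.  The definition used is recorded on the result.
    """
    ratios: dict[tuple[float, float], float | None] = {}
    for tem, nas in TN_RATIO_PAIRS:
        try:
            dt, dn = profile[tem], profile[nas]
        except KeyError:
            ratios[(tem, nas)] = None
            continue
        ratios[(tem, nas)] = None if (dt is None or dn is None or dn == 0) else dt / dn

    vals = [v for v in ratios.values() if v is not None]
    if len(vals) < len(TN_RATIO_PAIRS):
        total_val: float | None = None
    elif total == "mean_of_pairs":
        total_val = sum(vals) / len(vals)
    elif total == "sum_ratio":
        temporal = [profile[t] for t, _ in TN_RATIO_PAIRS]
        nasal = [profile[n] for _, n in TN_RATIO_PAIRS]
        total_val = sum(temporal) / sum(nasal)  # type: ignore[arg-type]
    else:
        raise ValidationError(f"unknown ratio_total definition {total!r}")
    return TNRatios(ratios=ratios, ratio_total=total_val, definition=total)


def measure_all(
    eye: NormalizedEye,
    angles_deg: Iterable[float] = CANONICAL_ANGLES_DEG,
    ratio_total: RatioTotalDefinition = "mean_of_pairs",
) -> EyelidMetrics:
    """Assemble every metric for one eye, enforcing cross-metric invariants.

    MRD1 is read out of the profile's 90-deg entry (identical by
    construction), and the contour peak height must dominate it: the peak is
    the global maximum of y, which the vertical crossing cannot exceed.
    """
    angles = tuple(float(a) for a in angles_deg)
    profile = mpld_profile(eye, angles)
    mrd1_val = profile[90.0] if 90.0 in profile.distances else mrd1(eye)
    offset, height = contour_peak(eye)
    if mrd1_val is not None and height < mrd1_val - 1e-9:
        raise InternalConsistencyError(
            f"peak height {height} below MRD1 {mrd1_val}; geometry is inconsistent"
        )
    return EyelidMetrics(
        eye_width_mm=eye_width(eye),
        mrd1_mm=mrd1_val,
        peak_temporal_offset_mm=offset,
        peak_height_mm=height,
        fissure_obliquity_deg=fissure_obliquity(eye),
        mpld=profile,
        tn_ratios=tn_ratios(profile, total=ratio_total),
        laterality=eye.laterality,
        subject_id=eye.subject_id,
        rater_id=eye.rater_id,
    )
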