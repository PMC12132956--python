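"""Pixel-to-millimetre calibration and canonical eye frames.

Raw digitizations live in image pixel coordinates (origin top-left, y down).
Every metric is instead read in a canonical anatomical frame:

* origin at the pupil center,
* millimetres, scaled by the white-to-white corneal diameter (12.0 mm by
  convention, configurable),
* y up (superior positive),
* nasal = +x, temporal = -x regardless of which eye it is.

With that convention the radial angle grid runs 0 deg (nasal) through 90 deg
(superior, where MRD1 is read) to 180 deg (temporal), for the right and the
left eye alike.  Whether the photograph is viewer-oriented or mirrored is a
per-dataset property (``mirror_policy``), since acquisition pipelines differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import CalibrationError, OrientationError, ValidationError
from .geometry import ControlPolygon

__all__ = [
    "DEFAULT_CORNEAL_DIAMETER_MM",
    "LandmarkSet",
    "NormalizedEye",
    "compute_scale",
    "normalize_eye",
    "denormalize_eye",
]

#: conventional horizontal white-to-white corneal diameter used for calibration
DEFAULT_CORNEAL_DIAMETER_MM = 12.0

Laterality = Literal["OD", "OS"]
MirrorPolicy = Literal["viewer", "mirrored"]


@dataclass(frozen=True)
class LandmarkSet:
    """One eye's raw digitization, in image pixels (y down).

    Attributes
    ----------
    bezier_px
        (4, 2) control points in digitization order (endpoints first/last;
        the digitizer's click order is preserved — canonicalization happens
        in :func:`normalize_eye`).
    limbus_a_px, limbus_b_px
        Endpoints of the horizontal white-to-white corneal diameter.
    pupil_px
        Manually marked pupil center.
    laterality
        ``"OD"`` (right eye) or ``"OS"`` (left eye).
    """

    bezier_px: np.ndarray
    limbus_a_px: np.ndarray
    limbus_b_px: np.ndarray
    pupil_px: np.ndarray
    laterality: Laterality
    subject_id: str = ""
    rater_id: str = ""

    def __post_init__(self) -> None:
        bez = np.array(self.bezier_px, dtype=float)
        la = np.array(self.limbus_a_px, dtype=float).reshape(2)
        lb = np.array(self.limbus_b_px, dtype=float).reshape(2)
        pu = np.array(self.pupil_px, dtype=float).reshape(2)
        if bez.shape != (4, 2):
            raise ValidationError("bezier_px must be a (4, 2) array")
        coords = np.concatenate([bez.ravel(), la, lb, pu])
        if not np.all(np.isfinite(coords)):
            raise ValidationError("landmark coordinates must be finite")
        if np.any(coords < 0):
            raise ValidationError("pixel coordinates must be non-negative")
        if np.allclose(la, lb):
            raise CalibrationError("limbus points coincide; cannot calibrate")
        if self.laterality not in ("OD", "OS"):
            raise ValidationError(f"laterality must be OD or OS, got {self.laterality!r}")
        side0 = bez[0, 0] - pu[0]
        side3 = bez[3, 0] - pu[0]
        if side0 * side3 >= 0:
            raise OrientationError(
                "Bezier endpoints must lie on opposite horizontal sides of the pupil"
            )
        bez.setflags(write=False)
        la.setflags(write=False)
        lb.setflags(write=False)
        pu.setflags(write=False)
        object.__setattr__(self, "bezier_px", bez)
        object.__setattr__(self, "limbus_a_px", la)
        object.__setattr__(self, "limbus_b_px", lb)
        object.__setattr__(self, "pupil_px", pu)


@dataclass(frozen=True)
class NormalizedEye:
    """One eye in the canonical mm / pupil-origin / y-up / nasal-+x frame."""

    curve: ControlPolygon
    scale_mm_per_px: float
    laterality: Laterality
    subject_id: str = ""
    rater_id: str = ""
    # provenance needed to invert the normalization exactly
    pupil_px: tuple[float, float] = (0.0, 0.0)
    mirrored_x: bool = False
    reversed_order: bool = False

    def __post_init__(self) -> None:
        x0 = self.curve.p0[0]
        x3 = self.curve.p3[0]
        if not (x0 > 0 and x3 < 0):
            raise OrientationError(
                "normalized curve must run nasal (p0, x>0) to temporal (p3, x<0)"
            )


def compute_scale(
    limbus_a_px,
    limbus_b_px,
    corneal_diameter_mm: float = DEFAULT_CORNEAL_DIAMETER_MM,
) -> float:
    """Millimetres per pixel from the imaged corneal diameter.

    The visible horizontal corneal diameter is assumed to span
    ``corneal_diameter_mm`` (default 12.0 mm), so the scale is simply
    ``corneal_diameter_mm / ||a - b||``.
    """
    a = np.asarray(limbus_a_px, dtype=float)
    b = np.asarray(limbus_b_px, dtype=float)
    dist = float(np.linalg.norm(a - b))
    if dist <= 0.0:
        raise CalibrationError("limbus points coincide; cannot calibrate")
    if corneal_diameter_mm <= 0.0:
        raise ValidationError("corneal diameter must be positive")
    return corneal_diameter_mm / dist


def _nasal_image_sign(laterality: Laterality, mirror_policy: MirrorPolicy) -> float:
    """Sign of the image-x direction that points nasally.

    Under the default ``"viewer"`` policy the photograph is as an observer
    facing the subject sees it: the right eye (OD) sits left of the image
    center with the nose to its right, so nasal is +x in image coordinates;
    for OS nasal is -x.  A ``"mirrored"`` dataset flips both.
    """
    if mirror_policy not in ("viewer", "mirrored"):
        raise ValidationError(f"unknown mirror policy {mirror_policy!r}")
    sign = 1.0 if laterality == "OD" else -1.0
    return sign if mirror_policy == "viewer" else -sign


def normalize_eye(
    landmarks: LandmarkSet,
    corneal_diameter_mm: float = DEFAULT_CORNEAL_DIAMETER_MM,
    mirror_policy: MirrorPolicy = "viewer",
) -> NormalizedEye:
    """Map a raw pixel digitization into the canonical anatomical frame.

    Steps, in order: subtract the pupil center; flip the vertical axis
    (image y-down to anatomical y-up); scale to millimetres; mirror x where
    needed so nasal is always +x; reorder control points so p0 is the medial
    (nasal) endpoint.  The transform is invertible — see
    :func:`denormalize_eye`.
    """
    scale = compute_scale(
        landmarks.limbus_a_px, landmarks.limbus_b_px, corneal_diameter_mm
    )
    sign = _nasal_image_sign(landmarks.laterality, mirror_policy)
    rel = landmarks.bezier_px - landmarks.pupil_px
    xy = np.column_stack([sign * rel[:, 0], -rel[:, 1]]) * scale

    reversed_order = xy[0, 0] < xy[3, 0]
    if reversed_order:
        xy = xy[::-1]
    curve = ControlPolygon(tuple(xy[0]), tuple(xy[1]), tuple(xy[2]), tuple(xy[3]),
                           frame="mm")
    return NormalizedEye(
        curve=curve,
        scale_mm_per_px=scale,
        laterality=landmarks.laterality,
        subject_id=landmarks.subject_id,
        rater_id=landmarks.rater_id,
        pupil_px=(float(landmarks.pupil_px[0]), float(landmarks.pupil_px[1])),
        mirrored_x=sign < 0,
        reversed_order=reversed_order,
    )


def denormalize_eye(eye: NormalizedEye) -> np.ndarray:
    """Invert :func:`normalize_eye`: control points back in image pixels.

    Returns a (4, 2) array in the original digitization order.
    """
    xy = eye.curve.points
    if eye.reversed_order:
        xy = xy[::-1]
    sign = -1.0 if eye.mirrored_x else 1.0
    rel = np.column_stack([sign * xy[:, 0], -xy[:, 1]]) / eye.scale_mm_per_px
    return rel + np.asarray(eye.pupil_px, dtype=float)
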