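"""Cubic Bezier geometry: evaluation, peak finding, ray intersection, fitting.

Everything downstream (MRD1, the radial MPLD profile, the contour peak) reduces
to one of four primitives on a cubic Bezier curve

    B(t) = (1-t)^3 p0 + 3(1-t)^2 t p1 + 3(1-t) t^2 p2 + t^3 p3,   t in [0, 1],

with endpoints p0, p3 and interior control points p1, p2.  The primitives are
solved in closed form (quadratic for the y-extremum, cubic companion-matrix
roots for ray crossings) rather than iteratively, so results are deterministic
and exact to floating-point precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DomainError, FitError, ValidationError

__all__ = [
    "ControlPolygon",
    "RayHit",
    "bezier_point",
    "bezier_peak",
    "ray_intersection",
    "fit_bezier",
]

#: imaginary parts below this magnitude are treated as numerical noise
_IMAG_TOL = 1e-9
#: slack when clipping curve parameters / radii to their admissible range
_EDGE_TOL = 1e-9


@dataclass(frozen=True)
class ControlPolygon:
    """Four 2-D control points defining a cubic Bezier eyelid margin.

    Canonical order puts ``p0`` at the medial (nasal) endpoint and ``p3`` at
    the lateral (temporal) endpoint; re-ordering raw digitizations is the
    frame-normalization step's job, not this class's.

    Parameters
    ----------
    p0, p1, p2, p3
        2-D points, each a length-2 sequence.  Units (px or mm) are carried
        by ``frame``; the geometry itself is unit-agnostic.
    frame
        Free-form tag, e.g. ``"px"`` or ``"mm"``.
    """

    p0: tuple[float, float]
    p1: tuple[float, float]
    p2: tuple[float, float]
    p3: tuple[float, float]
    frame: str = "mm"

    def __post_init__(self) -> None:
        pts = np.asarray([self.p0, self.p1, self.p2, self.p3], dtype=float)
        if pts.shape != (4, 2):
            raise ValidationError("control polygon needs four 2-D points")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("control points must be finite")
        if np.allclose(self.p0, self.p3):
            raise ValidationError("degenerate chord: p0 == p3")
        # freeze as tuples so the dataclass stays hashable
        object.__setattr__(self, "p0", (float(pts[0, 0]), float(pts[0, 1])))
        object.__setattr__(self, "p1", (float(pts[1, 0]), float(pts[1, 1])))
        object.__setattr__(self, "p2", (float(pts[2, 0]), float(pts[2, 1])))
        object.__setattr__(self, "p3", (float(pts[3, 0]), float(pts[3, 1])))

    @property
    def points(self) -> np.ndarray:
        """(4, 2) array of control points."""
        return np.asarray([self.p0, self.p1, self.p2, self.p3], dtype=float)

    def reversed(self) -> "ControlPolygon":
        """Same curve traversed in the opposite direction."""
        return ControlPolygon(self.p3, self.p2, self.p1, self.p0, frame=self.frame)

    def power_coefficients(self) -> np.ndarray:
        """Monomial coefficients ``c`` with B(t) = c[0] t^3 + c[1] t^2 + c[2] t + c[3].

        Returns a (4, 2) array (rows: t^3, t^2, t, 1; columns: x, y), the form
        :func:`numpy.polyval` expects.
        """
        p = self.points
        return np.asarray(
            [
                p[3] - 3.0 * p[2] + 3.0 * p[1] - p[0],
                3.0 * (p[2] - 2.0 * p[1] + p[0]),
                3.0 * (p[1] - p[0]),
                p[0],
            ]
        )


@dataclass(frozen=True)
class RayHit:
    """Intersection of a pupil-origin ray with the lid margin."""

    r: float  #: radial distance from the pupil center (the MPLD at this angle)
    t: float  #: curve parameter of the crossing


def bezier_point(curve: ControlPolygon, t: float | np.ndarray) -> np.ndarray:
    """Evaluate B(t) on the cubic Bernstein basis.

    ``t`` may be a scalar or an array; the result has shape ``(2,)`` or
    ``(len(t), 2)``.  Endpoint interpolation is exact: B(0) = p0, B(1) = p3.

    Raises
    ------
    DomainError
        If any ``t`` lies outside ``[0, 1]``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0) or np.any(t_arr > 1.0):
        raise DomainError(f"curve parameter outside [0, 1]: {t!r}")
    p = curve.points
    u = 1.0 - t_arr
    b = (
        np.multiply.outer(u**3, p[0])
        + np.multiply.outer(3.0 * u**2 * t_arr, p[1])
        + np.multiply.outer(3.0 * u * t_arr**2, p[2])
        + np.multiply.outer(t_arr**3, p[3])
    )
    return b if t_arr.ndim else b.reshape(2)


def _real_roots_in_unit(coeffs: Sequence[float]) -> list[float]:
    """Real roots of a polynomial restricted to [0, 1] (with edge tolerance)."""
    c = np.trim_zeros(np.asarray(coeffs, dtype=float), trim="f")
    if c.size <= 1:
        return []
    roots = np.roots(c)
    out = []
    for z in roots:
        if abs(z.imag) < _IMAG_TOL:
            t = float(z.real)
            if -_EDGE_TOL <= t <= 1.0 + _EDGE_TOL:
                out.append(min(1.0, max(0.0, t)))
    return out


def bezier_peak(curve: ControlPolygon) -> tuple[float, np.ndarray]:
    """Global maximum of the y-component of the curve — the contour peak.

    y(t) is a cubic, so y'(t) is a quadratic whose real roots in [0, 1],
    together with the endpoints, exhaust the candidate maximizers.  Ties are
    broken toward smaller ``t`` so flat (collinear-horizontal) curves report
    a deterministic location.

    Returns
    -------
    (t_peak, point)
        Maximizing parameter and the 2-D point ``B(t_peak)``.
    """
    cy = curve.power_coefficients()[:, 1]
    dy = np.polyder(cy)  # quadratic
    candidates = sorted({0.0, 1.0, *_real_roots_in_unit(dy)})
    best_t = candidates[0]
    best_y = float(np.polyval(cy, best_t))
    for t in candidates[1:]:
        y = float(np.polyval(cy, t))
        if y > best_y:  # strict: earlier t wins ties
            best_t, best_y = t, y
    return best_t, bezier_point(curve, best_t)


def ray_intersection(
    curve: ControlPolygon, theta_deg: float
) -> RayHit | None:
    """First crossing of the lid margin along a ray from the origin.

    The curve must already live in a pupil-centered frame.  A point lies on
    the ray at angle ``theta_deg`` iff

        sin(theta) * x(t) - cos(theta) * y(t) = 0      (a cubic in t)

    with radial coordinate ``r = x cos(theta) + y sin(theta) >= 0``.  The
    admissible root with the smallest ``r`` is returned: walking outward from
    the pupil center, the first margin crossing is the anatomical mid-pupil
    lid distance.  ``None`` (missing, not an error) when no admissible root
    exists — horizontal rays may legitimately miss an arch that stays above
    the pupil line.
    """
    th = math.radians(float(theta_deg))
    s, c = math.sin(th), math.cos(th)
    coeffs = curve.power_coefficients()
    line = s * coeffs[:, 0] - c * coeffs[:, 1]
    best: RayHit | None = None
    for t in _real_roots_in_unit(line):
        x, y = bezier_point(curve, t)
        r = x * c + y * s
        if r < -_EDGE_TOL:
            continue  # opposite half-line
        r = max(0.0, float(r))
        if best is None or r < best.r:
            best = RayHit(r=r, t=t)
    return best


def _bernstein_matrix(t: np.ndarray) -> np.ndarray:
    """(n, 4) Bernstein basis values at parameters t."""
    u = 1.0 - t
    return np.column_stack([u**3, 3.0 * u**2 * t, 3.0 * u * t**2, t**3])


def chord_length_parameters(points: np.ndarray) -> np.ndarray:
    """Normalized cumulative chord-length parameterization of ordered samples."""
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total = seg.sum()
    if total <= 0.0:
        raise FitError("all sample points coincide")
    return np.concatenate([[0.0], np.cumsum(seg)]) / total


def _solve_interior(
    pts: np.ndarray, t: np.ndarray, e0: np.ndarray, e3: np.ndarray
) -> np.ndarray:
    """Interior control points minimizing ||B(t_i) - pts_i|| with fixed ends."""
    basis = _bernstein_matrix(t)
    # move the fixed-endpoint contribution to the right-hand side
    rhs = pts - np.outer(basis[:, 0], e0) - np.outer(basis[:, 3], e3)
    design = basis[:, 1:3]
    if np.linalg.matrix_rank(design) < 2:
        raise FitError("rank-deficient design: samples do not constrain the fit")
    sol, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    return np.vstack([e0, sol[0], sol[1], e3])


def _project_parameters(
    ctrl: np.ndarray, t: np.ndarray, pts: np.ndarray, newton_steps: int = 2
) -> np.ndarray:
    """Move each parameter toward the foot point of its sample on the curve.

    Newton iteration on f(t) = (B(t) - q) . B'(t), vectorized over samples;
    endpoints stay pinned at 0 and 1.
    """
    c = np.asarray(
        [
            ctrl[3] - 3 * ctrl[2] + 3 * ctrl[1] - ctrl[0],
            3 * (ctrl[2] - 2 * ctrl[1] + ctrl[0]),
            3 * (ctrl[1] - ctrl[0]),
            ctrl[0],
        ]
    )
    for _ in range(newton_steps):
        b = ((c[0] * t[:, None] + c[1]) * t[:, None] + c[2]) * t[:, None] + c[3]
        db = (3 * c[0] * t[:, None] + 2 * c[1]) * t[:, None] + c[2]
        d2b = 6 * c[0] * t[:, None] + 2 * c[1]
        diff = b - pts
        num = np.sum(diff * db, axis=1)
        den = np.sum(db * db, axis=1) + np.sum(diff * d2b, axis=1)
        safe = np.abs(den) > 1e-30
        t = np.where(safe, t - num / np.where(safe, den, 1.0), t)
        t = np.clip(t, 0.0, 1.0)
    t[0], t[-1] = 0.0, 1.0
    return t


def fit_bezier(
    points: Sequence[Sequence[float]],
    endpoints: tuple[Sequence[float], Sequence[float]] | None = None,
    refine_iterations: int = 10,
    polish: bool = True,
) -> tuple[ControlPolygon, float]:
    """Least-squares cubic Bezier through ordered margin samples.

    Samples start at chord-length parameters, which are then treated as free:
    a few Hoschek-style correction rounds (project each sample onto the
    current fit, re-solve the linear problem) followed by a
    variable-projection least-squares polish over the sample parameters.
    Without the correction, the parameterization error of noisy or unevenly
    spaced samples leaks into the fit as a systematic bias of the recovered
    peak; without the polish, the alternation converges only linearly and
    noiseless samples are not recovered exactly.  Endpoints are fixed — to
    ``endpoints`` when given, else to the first and last samples — and the
    two interior control points always solve the inner linear least-squares
    problem.  The procedure is deterministic.

    Returns
    -------
    (curve, rms)
        The fitted polygon and the root-mean-square residual at the final
        parameters.

    Raises
    ------
    FitError
        Fewer than four samples, or a rank-deficient system.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("expected an (n, 2) array of samples")
    if pts.shape[0] < 4:
        raise FitError(f"need at least 4 samples, got {pts.shape[0]}")
    if endpoints is None:
        e0, e3 = pts[0], pts[-1]
    else:
        e0 = np.asarray(endpoints[0], dtype=float)
        e3 = np.asarray(endpoints[1], dtype=float)

    t = chord_length_parameters(pts)
    ctrl = _solve_interior(pts, t, e0, e3)
    for _ in range(max(0, refine_iterations)):
        t_new = _project_parameters(ctrl, t, pts)
        ctrl = _solve_interior(pts, t_new, e0, e3)
        if np.max(np.abs(t_new - t)) < 1e-14:
            t = t_new
            break
        t = t_new

    if polish and pts.shape[0] > 4:
        from scipy.optimize import least_squares

        def _residual(t_free: np.ndarray) -> np.ndarray:
            t_full = np.concatenate([[0.0], np.clip(t_free, 0.0, 1.0), [1.0]])
            c = _solve_interior(pts, t_full, e0, e3)
            return (_bernstein_matrix(t_full) @ c - pts).ravel()

        sol = least_squares(
            _residual, t[1:-1], method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
        )
        t = np.concatenate([[0.0], np.clip(sol.x, 0.0, 1.0), [1.0]])
        ctrl = _solve_interior(pts, t, e0, e3)

    curve = ControlPolygon(tuple(ctrl[0]), tuple(ctrl[1]), tuple(ctrl[2]),
                           tuple(ctrl[3]))
    resid = _bernstein_matrix(t) @ ctrl - pts
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return curve, rms
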