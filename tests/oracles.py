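"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's closed-form code paths: curve points
come from de Casteljau subdivision or monomial evaluation on dense parameter
grids, extrema from grid search, ray crossings from sign-change bracketing,
and the ICC from a longhand ANOVA decomposition.
"""

from __future__ import annotations

import math

import numpy as np


def de_casteljau(points: np.ndarray, t: float) -> np.ndarray:
    """Evaluate a Bezier curve by repeated linear interpolation."""
    pts = np.asarray(points, dtype=float).copy()
    while len(pts) > 1:
        pts = (1.0 - t) * pts[:-1] + t * pts[1:]
    return pts[0]


def dense_samples(points: np.ndarray, n: int = 1_000_000) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(t, x, y) arrays from monomial-basis evaluation on a uniform grid."""
    p = np.asarray(points, dtype=float)
    c3 = p[3] - 3 * p[2] + 3 * p[1] - p[0]
    c2 = 3 * (p[2] - 2 * p[1] + p[0])
    c1 = 3 * (p[1] - p[0])
    c0 = p[0]
    t = np.linspace(0.0, 1.0, n)
    x = ((c3[0] * t + c2[0]) * t + c1[0]) * t + c0[0]
    y = ((c3[1] * t + c2[1]) * t + c1[1]) * t + c0[1]
    return t, x, y


def grid_peak(points: np.ndarray, n: int = 1_000_000) -> tuple[float, float]:
    """(t, y) of the y-maximum over a dense uniform grid."""
    t, _, y = dense_samples(points, n)
    i = int(np.argmax(y))
    return float(t[i]), float(y[i])


def ray_crossing(
    points: np.ndarray,
    theta_deg: float,
    grid: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> float | None:
    """Smallest non-negative radial distance where the ray meets the curve.

    Sign-change bracketing on the dense grid followed by linear
    interpolation inside each bracket; returns None when no admissible
    crossing exists.
    """
    t, x, y = grid
    th = math.radians(theta_deg)
    s, c = math.sin(th), math.cos(th)
    g = s * x - c * y
    sign_change = np.nonzero(g[:-1] * g[1:] <= 0.0)[0]
    best = None
    for i in sign_change:
        g0, g1 = g[i], g[i + 1]
        frac = 0.5 if g1 == g0 else g0 / (g0 - g1)
        xr = x[i] + frac * (x[i + 1] - x[i])
        yr = y[i] + frac * (y[i + 1] - y[i])
        r = xr * c + yr * s
        if r < -1e-9:
            continue
        r = max(0.0, float(r))
        if best is None or r < best:
            best = r
    return best


def anova_icc_a1(matrix: np.ndarray) -> float:
    """ICC(A,1) from a longhand two-way ANOVA written with explicit loops."""
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = sum(m[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(m[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(m[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_tot = sum((m[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def welch_formulas(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t, Welch-Satterthwaite df and two-sided p from first principles."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = sum((v - a.mean()) ** 2 for v in a) / (na - 1)
    vb = sum((v - b.mean()) ** 2 for v in b) / (nb - 1)
    se2 = va / na + vb / nb
    t_stat = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * t_dist.sf(abs(t_stat), df)
    return t_stat, df, p


def random_arch_points(rng: np.random.Generator) -> np.ndarray:
    """Random eyelid-like control polygon in a pupil-origin frame (mm)."""
    x0 = rng.uniform(6.0, 15.0)
    x3 = -rng.uniform(6.0, 15.0)
    y0, y3 = rng.uniform(-6.0, 2.0, size=2)
    xi = rng.uniform(-12.0, 12.0, size=2)
    yi = rng.uniform(0.0, 10.0, size=2)
    return np.array([[x0, y0], [xi[0], yi[0]], [xi[1], yi[1]], [x3, y3]])
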