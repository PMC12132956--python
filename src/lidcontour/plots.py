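"""Figure helpers: Bland-Altman agreement plot and contour overlays."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .frame import NormalizedEye
from .geometry import bezier_point
from .reliability import BlandAltmanResult

__all__ = ["bland_altman_plot", "contour_overlay_plot"]


def bland_altman_plot(
    result: BlandAltmanResult,
    path: str | Path,
    metric_label: str = "contour peak height (mm)",
) -> None:
    """Differences vs means with bias and 95% limits of agreement."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.means, result.diffs, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(result.bias, color="k", lw=1.2, label=f"bias {result.bias:+.3f}")
    for y, ls in ((result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, color="gray", lw=1.0, ls=ls)
    ax.set_xlabel(f"mean of raters, {metric_label}")
    ax.set_ylabel(f"difference (rater 1 - rater 2), {metric_label}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def contour_overlay_plot(
    eyes: Sequence[NormalizedEye],
    path: str | Path,
    labels: Sequence[str] | None = None,
    corneal_diameter_mm: float = 12.0,
) -> None:
    """Overlay normalized lid contours around the pupil center.

    Draws each margin curve in the canonical mm frame with the pupil center
    at the origin and the corneal outline for scale — the standard way to
    compare average contours between groups in a single image.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    t = np.linspace(0.0, 1.0, 400)
    for i, eye in enumerate(eyes):
        pts = bezier_point(eye.curve, t)
        lbl = labels[i] if labels is not None else None
        ax.plot(pts[:, 0], pts[:, 1], lw=1.5, label=lbl)
    theta = np.linspace(0, 2 * np.pi, 200)
    r = corneal_diameter_mm / 2.0
    ax.plot(r * np.cos(theta), r * np.sin(theta), color="goldenrod", lw=1.0)
    ax.plot(0, 0, "k.", ms=6)
    ax.set_aspect("equal")
    ax.set_xlabel("nasal  ←  x (mm)  →  temporal (negative)")
    ax.set_ylabel("y (mm, superior positive)")
    if labels is not None:
        ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
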