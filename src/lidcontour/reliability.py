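"""Inter-rater agreement and group-comparison statistics.

Implements the agreement toolkit used to validate landmark-based eyelid
measurements: the single-measure intraclass correlation under a two-way
random-effects, absolute-agreement model — ICC(A,1) in McGraw & Wong's
nomenclature, ICC(2,1) in Shrout & Fleiss's — together with its
average-measure form ICC(A,k), Bland–Altman limits of agreement, and the
two-sample t test (Welch by default) for female/male comparisons.

The ICC is computed from the two-way ANOVA mean squares

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the subject, rater and residual mean squares of an
n-subject x k-rater complete table, and confidence bounds from the
F-distribution (McGraw & Wong 1996).  It is written out here rather than
delegated so the confidence level is a free parameter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ICCResult",
    "BlandAltmanResult",
    "anova_mean_squares",
    "icc_2_1",
    "icc_2_k",
    "bland_altman",
    "welch_t",
    "summarize_cohort",
]


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    form: str  #: "A,1" (single measure) or "A,k" (average of k raters)


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    means: np.ndarray  #: per-pair means, for plotting
    diffs: np.ndarray  #: per-pair differences (x - y)


def _as_ratings(m) -> np.ndarray:
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
        raise ValidationError("ratings matrix must be n>=2 subjects x k>=2 raters")
    if not np.all(np.isfinite(a)):
        raise ValidationError("ratings matrix must be complete and finite")
    return a


def anova_mean_squares(m) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares (MSR, MSC, MSE, n, k) of a ratings table."""
    a = _as_ratings(m)
    n, k = a.shape
    grand = a.mean()
    row = a.mean(axis=1)
    col = a.mean(axis=0)
    msr = k * float(((row - grand) ** 2).sum()) / (n - 1)
    msc = n * float(((col - grand) ** 2).sum()) / (k - 1)
    resid = a - row[:, None] - col[None, :] + grand
    mse = float((resid**2).sum()) / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_2_1(m, ci_level: float = 0.95) -> ICCResult:
    """Single-measure ICC, two-way random effects, absolute agreement.

    Raises
    ------
    ValidationError
        If the table has no variance at all (every cell equal), which leaves
        the coefficient undefined.
    """
    msr, msc, mse, n, k = anova_mean_squares(m)
    if msr == 0.0 and mse == 0.0:
        raise ValidationError("all ratings identical; ICC undefined")
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) confidence bounds via Satterthwaite's approximation
    alpha = 1.0 - ci_level
    a_coef = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    b_coef = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 else np.inf
    if np.isinf(a_coef):
        lo = hi = 1.0
    else:
        num = (a_coef * msc + b_coef * mse) ** 2
        den = (a_coef * msc) ** 2 / (k - 1) + (b_coef * mse) ** 2 / ((n - 1) * (k - 1))
        v = num / den if den > 0 else 1.0
        f_lo = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_hi = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
    return ICCResult(icc=float(icc), ci_low=float(lo), ci_high=float(hi), form="A,1")


def icc_2_k(m, ci_level: float = 0.95) -> ICCResult:
    """Average-measure ICC(A,k): reliability of the k-rater mean.

    Obtained from the single-measure form by the Spearman-Brown step-up
    relation, applied to the estimate and both confidence bounds.
    """
    single = icc_2_1(m, ci_level=ci_level)
    k = _as_ratings(m).shape[1]

    def step_up(r: float) -> float:
        return k * r / (1.0 + (k - 1) * r)

    return ICCResult(
        icc=step_up(single.icc),
        ci_low=step_up(single.ci_low),
        ci_high=step_up(single.ci_high),
        form="A,k",
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland–Altman agreement: bias and 95% limits of agreement.

    Differences are ``x - y``; limits are bias +/- 1.96 * SD(diff) with the
    sample (n-1) standard deviation — the conventional large-sample form.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValidationError("bland_altman expects two equal-length 1-D vectors")
    if xv.size < 2:
        raise ValidationError("need at least 2 paired measurements")
    d = xv - yv
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        means=(xv + yv) / 2.0,
        diffs=d,
    )


def welch_t(a, b, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sample t test: (t, df, p), Welch by default.

    Welch's unequal-variance form with Welch–Satterthwaite degrees of freedom
    is the robust default; ``equal_var=True`` selects the classical pooled
    Student t.
    """
    av = np.asarray(a, dtype=float)
    bv = np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if not (np.all(np.isfinite(av)) and np.all(np.isfinite(bv))):
        raise ValidationError("groups must be finite")
    if av.std(ddof=1) == 0.0 and bv.std(ddof=1) == 0.0 and av.mean() != bv.mean():
        raise ValidationError("both groups degenerate (zero variance)")
    res = stats.ttest_ind(av, bv, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def summarize_cohort(
    metrics: Sequence,
    sex: Sequence[str],
    equal_var: bool = False,
) -> pd.DataFrame:
    """Cohort summary table: mean +/- SD overall and by sex, with group p.

    One row per metric (scalar metrics, each MPLD angle, each
    temporal:nasal ratio and the ratio total), columns for the total, female
    and male mean/SD and the two-sample p-value (Welch by default) comparing
    the sexes — the layout such normative-cohort tables are reported in.
    ``sex`` holds ``"F"``/``"M"`` labels aligned with ``metrics``.
    """
    from .io import metrics_to_frame  # local import avoids a module cycle

    if len(metrics) == 0:
        raise ValidationError("empty cohort")
    if len(sex) != len(metrics):
        raise ValidationError("sex labels must align with metrics")
    wide = metrics_to_frame(list(metrics), precision=None)
    wide = wide.drop(columns=["subject_id", "rater_id", "laterality",
                              "ratio_total_definition"], errors="ignore")
    labels = pd.Series([s.upper()[0] for s in sex], index=wide.index)
    if not set(labels) <= {"F", "M"}:
        raise ValidationError("sex labels must be F or M")

    rows = []
    for col in wide.columns:
        vals = pd.to_numeric(wide[col], errors="coerce")
        f = vals[labels == "F"].dropna()
        m = vals[labels == "M"].dropna()
        both = vals.dropna()
        if len(f) >= 2 and len(m) >= 2 and (f.std() > 0 or m.std() > 0):
            _, _, p = welch_t(f, m, equal_var=equal_var)
        elif len(f) >= 2 and len(m) >= 2:
            # zero variance in both groups: no evidence of difference unless
            # the constants differ, where the test is undefined
            p = 1.0 if f.mean() == m.mean() else float("nan")
        else:
            p = float("nan")
        rows.append(
            {
                "metric": col,
                "total_mean": both.mean(),
                "total_sd": both.std(ddof=1),
                "female_mean": f.mean() if len(f) else float("nan"),
                "female_sd": f.std(ddof=1) if len(f) > 1 else float("nan"),
                "male_mean": m.mean() if len(m) else float("nan"),
                "male_sd": m.std(ddof=1) if len(m) > 1 else float("nan"),
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("metric")
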