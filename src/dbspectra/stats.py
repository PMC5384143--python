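"""Cohort inference: paired change-from-baseline contrasts and OLS.

The longitudinal design nests eyes within mice, so each mouse first
contributes the average of its eyes per timepoint; the contrast is then
a paired t-test on the per-mouse (timepoint − baseline) differences.
Histology-vs-imaging couplings are assessed by simple linear
regression with a two-sided slope test. Tests are two-sided and
unadjusted for multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ContrastResult", "RegressionResult", "change_from_baseline", "linear_regression"]


@dataclass(frozen=True)
class ContrastResult:
    """Paired change-from-baseline contrast for one metric."""

    metric: str
    timepoint: str
    estimate: float
    se: float
    t: float
    df: int
    p: float
    n_pairs: int
    degenerate: bool = False
    single_eye_mice: tuple = ()


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression with a two-sided slope test."""

    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p: float
    n: int


def change_from_baseline(
    cohort: pd.DataFrame,
    metric: str,
    timepoint: str,
    baseline_label: str = "baseline",
) -> ContrastResult:
    """Paired t-test of a metric's change from baseline, eyes averaged.

    Each mouse contributes the mean of its available eyes at each
    timepoint (mice with a single eye are flagged, not dropped). At
    least two complete (baseline, timepoint) pairs are required. If
    every difference is identical and non-zero the variance is
    degenerate: the result is flagged and p is reported at the
    smallest positive float.
    """
    for col in ("mouse", "eye", "timepoint", metric):
        if col not in cohort.columns:
            raise ValueError(f"cohort table lacks column {col!r}")
    sub = cohort[cohort["timepoint"].isin([baseline_label, timepoint])]
    cohort_eyes = sub["eye"].nunique()
    single_eye = []
    diffs = []
    for mouse, grp in sub.groupby("mouse"):
        base = grp[grp["timepoint"] == baseline_label][metric].dropna()
        post = grp[grp["timepoint"] == timepoint][metric].dropna()
        if base.empty or post.empty:
            continue
        if min(base.size, post.size) < cohort_eyes:
            single_eye.append(mouse)
        diffs.append(post.mean() - base.mean())
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.size
    if n < 2:
        raise ValueError(f"need >= 2 complete pairs, got {n}")

    estimate = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if estimate == 0.0:
            return ContrastResult(metric, timepoint, 0.0, 0.0, 0.0, df, 1.0, n,
                                  degenerate=False, single_eye_mice=tuple(single_eye))
        tiny = float(np.finfo(float).tiny)
        return ContrastResult(metric, timepoint, estimate, 0.0,
                              float(np.sign(estimate)) * np.inf, df, tiny, n,
                              degenerate=True, single_eye_mice=tuple(single_eye))
    se = sd / np.sqrt(n)
    t = estimate / se
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ContrastResult(metric, timepoint, estimate, float(se), float(t), df,
                          max(p, float(np.finfo(float).tiny)), n,
                          single_eye_mice=tuple(single_eye))


def linear_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares of y on x with a two-sided slope test."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.var(x) == 0.0:
        raise ValueError("var(x) is zero")
    if np.var(y) == 0.0:
        # flat response: zero slope, no explained variance, no evidence
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 1.0, x.size)
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_se=float(res.stderr),
        p=float(res.pvalue),
        n=x.size,
    )
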