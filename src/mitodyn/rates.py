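"""Two-phase linear rate model of tracer migration and group summaries.

Migration curves show a fast early phase (first 2 min, attributed to
diffusion within already-connected mitochondria) and a slow late phase
(fission/fusion-limited).  The early rate is a zero-intercept least
squares fit over points up to 2 min augmented with the implicit (0, 0)
point; the late rate is an ordinary least-squares slope with a free
intercept over points from 2 min on.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import MigrationCurve

__all__ = [
    "TwoPhaseFit",
    "GroupSummary",
    "fit_two_phase",
    "rate_ratio",
    "group_summary",
    "rate_table",
    "EARLY_WINDOW_MIN",
    "ANALYSIS_WINDOW_MIN",
]

EARLY_WINDOW_MIN = 2.0
ANALYSIS_WINDOW_MIN = 18.0
_EPS = 1e-9


@dataclass
class TwoPhaseFit:
    """Early and late migration rates for one fiber."""

    rate_early: float       # m-steps/min, fit through the origin, >= 0
    rate_late: float        # m-steps/min, OLS slope for t >= 2 min
    intercept_late: float   # m-steps
    n_early: int            # points in the early fit (excluding (0,0))
    n_late: int
    window_total: float     # m-steps migrated over the 18-min window
    #                         starting at the first frame


def fit_two_phase(curve: MigrationCurve) -> TwoPhaseFit:
    """Fit the two-phase linear rate model to a migration curve.

    ``window_total`` is the migration accumulated over the 18 minutes
    following the first frame, i.e. steps(t_first + 18) - steps(t_first)
    with linear interpolation inside the sampled range and late-line
    extrapolation beyond it.
    """
    t = np.asarray(curve.times, dtype=float)
    s = np.asarray(curve.steps, dtype=float)
    if t.size != s.size or t.size < 2:
        raise ValueError("curve must have matching times/steps with >= 2 points")

    late = t >= EARLY_WINDOW_MIN - _EPS
    if int(late.sum()) < 2:
        raise ValueError("need at least 2 points at t >= 2 min for the late fit")
    slope, intercept = np.polyfit(t[late], s[late], 1)
    if slope < -1e-12:
        warnings.warn("negative late-phase migration rate", stacklevel=2)

    early = t <= EARLY_WINDOW_MIN + _EPS
    te = np.concatenate([[0.0], t[early]])
    se = np.concatenate([[0.0], s[early]])
    if not early.any():
        # no sample at or before 2 min: fall back to the first frame
        te = np.array([0.0, t[0]])
        se = np.array([0.0, s[0]])
    denom = float(np.sum(te * te))
    rate_early = max(float(np.sum(te * se)) / denom, 0.0) if denom > 0 else 0.0

    t_target = t[0] + ANALYSIS_WINDOW_MIN
    if t_target <= t[-1] + _EPS:
        s_target = float(np.interp(t_target, t, s))
    else:
        s_target = float(intercept + slope * t_target)
    window_total = s_target - float(s[0])

    return TwoPhaseFit(rate_early=rate_early, rate_late=float(slope),
                       intercept_late=float(intercept),
                       n_early=int(early.sum()), n_late=int(late.sum()),
                       window_total=window_total)


def rate_ratio(rate_a: float, rate_b: float) -> float:
    """rate_a / rate_b rounded to one decimal, half away from zero."""
    if not (math.isfinite(rate_a) and math.isfinite(rate_b)):
        raise ValueError("rates must be finite")
    if rate_b <= 0:
        raise ValueError("rate_b must be > 0")
    x = rate_a / rate_b
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5 + 1e-12), x) / 10.0


@dataclass
class GroupSummary:
    """Per-condition cohort summary (mean +/- SEM, t test vs reference)."""

    condition: str
    n: int
    total_mean: float       # m-steps over the 18-min window
    total_sem: float
    rate_early_mean: float
    rate_late_mean: float
    p_value: float          # equal-variance Student's t test vs reference
    degenerate: bool = False


def group_summary(fits: list[TwoPhaseFit], reference: list[TwoPhaseFit],
                  condition: str = "") -> GroupSummary:
    """Summarize a cohort of per-fiber fits against a reference cohort."""
    if len(fits) < 2 or len(reference) < 2:
        raise ValueError("need n >= 2 fibers in each group")
    totals = np.array([f.window_total for f in fits], dtype=float)
    ref = np.array([f.window_total for f in reference], dtype=float)

    degenerate = totals.std(ddof=1) == 0 and ref.std(ddof=1) == 0
    if degenerate:
        p = float("nan")
    else:
        p = float(stats.ttest_ind(totals, ref, equal_var=True).pvalue)

    return GroupSummary(
        condition=condition,
        n=len(fits),
        total_mean=float(totals.mean()),
        total_sem=float(totals.std(ddof=1) / math.sqrt(len(fits))),
        rate_early_mean=float(np.mean([f.rate_early for f in fits])),
        rate_late_mean=float(np.mean([f.rate_late for f in fits])),
        p_value=p,
        degenerate=degenerate,
    )


def rate_table(fits_by_condition: dict[str, list[TwoPhaseFit]],
               reference: str = "control") -> pd.DataFrame:
    """Table of per-condition rates plus ratios vs the reference group."""
    if reference not in fits_by_condition:
        raise KeyError(f"reference condition {reference!r} not present")
    ref_fits = fits_by_condition[reference]
    rows = []
    ref_sum = group_summary(ref_fits, ref_fits, reference)
    for name, fits in fits_by_condition.items():
        gs = group_summary(fits, ref_fits, name)
        rows.append({
            "condition": name,
            "n": gs.n,
            "total_18min_mean": gs.total_mean,
            "total_18min_sem": gs.total_sem,
            "rate_first2min": gs.rate_early_mean,
            "rate_after2min": gs.rate_late_mean,
            "ratio_ref_over_cond_first2min": rate_ratio(
                ref_sum.rate_early_mean, gs.rate_early_mean)
            if gs.rate_early_mean > 0 else float("nan"),
            "ratio_ref_over_cond_after2min": rate_ratio(
                ref_sum.rate_late_mean, gs.rate_late_mean)
            if gs.rate_late_mean > 0 else float("nan"),
            "p_vs_reference": gs.p_value if name != reference else float("nan"),
        })
    return pd.DataFrame(rows)
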