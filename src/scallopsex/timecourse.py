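"""Per-month cohort summaries, coexpression correlation and phase regressions.

A month's differentiation rate is the fraction of called individuals that
are female or male; ``intermediate`` calls count as not-yet-differentiated
(conservative).  Within each month the Pearson correlation between
log10(FOXL2) and log10(DMRT1L) is tracked: before differentiation the two
markers rise and fall together (positive r, pooled line near
y = 1.018x + 0.370), after differentiation they become antagonistic
(negative r, pooled line near y = -0.684x + 1.584).  The switch report
locates the month at which the sign flips; it is descriptive only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

DIFFERENTIATED_CALLS = ("female", "male")
PRE_CALLS = ("undifferentiated", "intermediate")


@dataclass(frozen=True)
class CohortSummary:
    month_age: int
    n: int  # called (non-missing) individuals
    n_undifferentiated: int
    n_female: int
    n_male: int
    n_intermediate: int
    n_missing: int
    differentiation_rate: float  # in [0, 1]
    pearson_r: float  # NaN when < 3 pairs or degenerate
    r_p_value: float

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r: float
    n: int
    phase: str  # undifferentiated / differentiated


def pearson(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with a two-sided t-based p-value.

    Requires >= 3 finite pairs; zero variance in either variable yields
    (NaN, NaN) rather than an arbitrary sign.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson: x and y lengths differ")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"pearson needs >=3 paired values, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def summarize_cohort(
    month_age: int,
    calls: Sequence[str],
    log_foxl2: Sequence[float],
    log_dmrt1l: Sequence[float],
) -> CohortSummary:
    """Counts, differentiation rate and marker correlation for one month."""
    if len(calls) == 0:
        raise ValidationError(f"month {month_age}: empty cohort")
    counts = pd.Series(calls).value_counts()
    n_f = int(counts.get("female", 0))
    n_m = int(counts.get("male", 0))
    n_u = int(counts.get("undifferentiated", 0))
    n_i = int(counts.get("intermediate", 0))
    n_missing = int(counts.get("missing", 0))
    called = n_f + n_m + n_u + n_i
    rate = (n_f + n_m) / called if called else math.nan
    try:
        r, p = pearson(log_foxl2, log_dmrt1l)
    except InsufficientDataError:
        r, p = math.nan, math.nan
    return CohortSummary(
        month_age=int(month_age),
        n=called,
        n_undifferentiated=n_u,
        n_female=n_f,
        n_male=n_m,
        n_intermediate=n_i,
        n_missing=n_missing,
        differentiation_rate=rate,
        pearson_r=r,
        r_p_value=p,
    )


def summarize_by_month(scored: pd.DataFrame) -> list[CohortSummary]:
    """Apply :func:`summarize_cohort` per month of a scored sample table.

    ``scored`` columns: sample_id, month_age, call, log_foxl2, log_dmrt1l.
    """
    out = []
    for month, sub in scored.groupby("month_age", sort=True):
        out.append(
            summarize_cohort(
                int(month),
                sub["call"].tolist(),
                sub["log_foxl2"].to_numpy(),
                sub["log_dmrt1l"].to_numpy(),
            )
        )
    return out


def fit_phase_regression(
    log_foxl2: Sequence[float], log_dmrt1l: Sequence[float], phase: str
) -> RegressionFit:
    """OLS of log10(DMRT1L) on log10(FOXL2) for one pooled phase."""
    x = np.asarray(log_foxl2, dtype=float)
    y = np.asarray(log_dmrt1l, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise InsufficientDataError(f"phase regression needs >=3 pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValidationError("phase regression: degenerate x variance")
    fit = stats.linregress(x, y)
    return RegressionFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        n=len(x),
        phase=phase,
    )


def pool_phases(
    summaries: Sequence[CohortSummary], scored: pd.DataFrame
) -> dict[str, RegressionFit | None]:
    """Pooled regressions over fully undifferentiated (rate 0) and fully
    differentiated (rate 1) months; partially differentiated months are
    excluded from both pools."""
    undiff_months = {s.month_age for s in summaries if s.differentiation_rate == 0.0}
    diff_months = {s.month_age for s in summaries if s.differentiation_rate == 1.0}
    fits: dict[str, RegressionFit | None] = {}
    for phase, months in (("undifferentiated", undiff_months), ("differentiated", diff_months)):
        sub = scored[scored["month_age"].isin(months)]
        try:
            fits[phase] = fit_phase_regression(
                sub["log_foxl2"].to_numpy(), sub["log_dmrt1l"].to_numpy(), phase
            )
        except (InsufficientDataError, ValidationError):
            fits[phase] = None
    return fits


def detect_switch(summaries: Sequence[CohortSummary], alpha: float = 0.05) -> dict:
    """Locate the month at which marker correlation changes sign.

    The positive regime is the initial run of months with significantly
    positive r (two-sided p < alpha).  The switch is bracketed between the
    last month of that regime and the first subsequent month with r <= 0.
    Purely descriptive; no test of difference between correlations.
    """
    if len(summaries) < 2:
        raise InsufficientDataError("detect_switch needs >=2 months")
    per_month = []
    for s in summaries:
        sig = bool(np.isfinite(s.r_p_value) and s.r_p_value < alpha)
        per_month.append(
            {
                "month_age": s.month_age,
                "pearson_r": s.pearson_r,
                "p_value": s.r_p_value,
                "significant": sig,
            }
        )
    last_pos = None
    for m in per_month:
        if m["significant"] and np.isfinite(m["pearson_r"]) and m["pearson_r"] > 0:
            last_pos = m["month_age"]
        else:
            break
    first_nonpos = None
    for m in per_month:
        if np.isfinite(m["pearson_r"]) and m["pearson_r"] <= 0:
            first_nonpos = m["month_age"]
            break
    report = {
        "alpha": alpha,
        "per_month": per_month,
        "switch_detected": first_nonpos is not None,
    }
    if first_nonpos is None:
        report["note"] = "no switch detected"
    else:
        report["last_positive_month"] = last_pos
        report["first_nonpositive_month"] = first_nonpos
    return report
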