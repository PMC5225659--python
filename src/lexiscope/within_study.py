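"""The within-study risk: stratified survival, the weighted average of
end-of-follow-up incidences, its variance, and Wald confidence intervals.

Let U be the end-of-follow-up variable (U = t_i in stratum i).  The
within-study cumulative incidence CI'(t) = P(T <= t ^ U) is the probability
of an event before time t *and* before the end of follow-up — an estimand
that is identified under calendar time trends without extrapolation.  It is
estimated by

    CI_w(t) = 1 - sum_i (n_i/n) S_i(t ^ t_i),

the weighted average of stratum Kaplan-Meier curves truncated at their own
end of follow-up.  At t = t_1 this is the weighted average of the
end-of-follow-up incidence estimates, with variance

    Var(S_w(t_1)) = (1/n) [ sum_i w_i S_i(t_i)^2 - (sum_i w_i S_i(t_i))^2 ]
                    + sum_i w_i^2 Var(S_i(t_i)),      w_i = n_i/n,

the first term capturing the multinomial variation of the stratum weights and
the second the within-stratum (Greenwood) sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import Status, StepCurve
from .estimators import aj, km, risk_table
from .lexis import StratifiedCohort

__all__ = [
    "StratumEstimate",
    "WithinStudySummary",
    "stratified_survival",
    "within_study_curve",
    "within_study_risk",
    "within_study_risk_cr",
    "from_end_of_followup",
    "trend_diagnostic",
    "per_ten_thousand",
]


@dataclass(frozen=True)
class StratumEstimate:
    """One stratum's end-of-follow-up summary."""

    t_end: float
    n: int
    incidence: float
    variance: float


@dataclass(frozen=True)
class WithinStudySummary:
    """Scalar within-study risk estimate with variance and Wald interval."""

    estimate: float
    variance: float | None
    ci_lower: float | None
    ci_upper: float | None
    level: float
    per_stratum: tuple[StratumEstimate, ...]
    weights: tuple[float, ...]
    variance_complete: bool = True


def _stratum_curves(cohort: StratifiedCohort, cause: int | None = None):
    """Per-stratum incidence curves on [0, t_i]: 1-KM, or AJ for a cause."""
    curves = []
    for i, (stratum, t_i) in enumerate(zip(cohort.strata, cohort.t), start=1):
        if not stratum:
            raise ValueError(f"stratum {i} is empty; check the study design")
        table = risk_table(stratum, domain_end=t_i)
        if cause is None:
            curves.append(km(table))
        else:
            if cause in table.causes:
                curves.append(aj(table, cause))
            else:
                # no events of this cause in the stratum: flat zero incidence
                curves.append(
                    StepCurve(
                        times=np.array([]),
                        values=np.array([]),
                        domain_end=t_i,
                        variances=np.array([]),
                        start_value=0.0,
                    )
                )
    return curves


def stratified_survival(cohort: StratifiedCohort, t: float | None = None) -> StepCurve:
    """Stratified survival S_s(t) = sum_i (n_i/n) S_i(t) on [0, t_k].

    By the law of total probability this estimates the population survival,
    but only up to the shortest end of follow-up t_k — beyond t_k some strata
    carry no information.  ``t`` optionally restricts the domain further;
    requesting t > t_k is an error.
    """
    t_k = cohort.t[-1]
    if t is None:
        t = t_k
    if t > t_k + 1e-12:
        raise ValueError(
            f"stratified survival is only defined up to t_k = {t_k}; got t = {t}"
        )
    curve = within_study_curve(cohort)
    keep = curve.times <= t + 1e-12
    return StepCurve(
        times=curve.times[keep],
        values=1.0 - curve.values[keep],
        domain_end=float(t),
        variances=curve.variances[keep] if curve.variances is not None else None,
        start_value=1.0,
    )


def within_study_curve(cohort: StratifiedCohort) -> StepCurve:
    """Incidence curve CI_w(t) = 1 - sum_i (n_i/n) S_i(t ^ t_i) on [0, t_1].

    Below t_k it coincides exactly with 1 - S_s(t); with no loss-to-follow-up
    censoring it equals the binomial count (1/n) sum_i e_i(t), the number of
    events in the truncated Lexis region divided by the sample size.
    Pointwise variances use the t_1 variance formula evaluated at t ^ t_i.
    """
    if not cohort.truncated:
        raise ValueError("apply truncate_triangles before within-study estimation")
    curves = _stratum_curves(cohort)
    w = np.asarray(cohort.weights)
    n = cohort.n
    jump_times = np.unique(
        np.concatenate([c.times for c in curves] or [np.array([])])
    )
    jump_times = jump_times[jump_times <= cohort.t[0] + 1e-12]
    values = np.empty_like(jump_times)
    variances = np.empty_like(jump_times)
    for idx, t in enumerate(jump_times):
        s = np.array([c(min(t, t_i)) for c, t_i in zip(curves, cohort.t)])
        v = np.array(
            [c.variance_at(min(t, t_i)) for c, t_i in zip(curves, cohort.t)]
        )
        sw = float(np.dot(w, s))
        values[idx] = 1.0 - sw
        variances[idx] = (np.dot(w, s**2) - sw**2) / n + float(np.dot(w**2, v))
    return StepCurve(
        times=jump_times,
        values=values,
        domain_end=cohort.t[0],
        variances=variances,
        start_value=0.0,
        start_variance=0.0,
    )


def _summarize(
    incidences: np.ndarray,
    weights: np.ndarray,
    variances: np.ndarray | None,
    n: int | None,
    level: float,
    t_end: Sequence[float],
    n_per: Sequence[int],
) -> WithinStudySummary:
    estimate = float(np.dot(weights, incidences))
    surv = 1.0 - incidences
    variance = None
    lower = upper = None
    complete = True
    if variances is not None:
        within = float(np.dot(weights**2, variances))
        if n is not None:
            sw = float(np.dot(weights, surv))
            between = (float(np.dot(weights, surv**2)) - sw**2) / n
        else:
            between = 0.0
            complete = False
        variance = max(between + within, 0.0)
        z = stats.norm.ppf(0.5 + level / 2)
        half = z * np.sqrt(variance)
        lower = float(np.clip(estimate - half, 0.0, 1.0))
        upper = float(np.clip(estimate + half, 0.0, 1.0))
    else:
        complete = False
    per = tuple(
        StratumEstimate(
            t_end=float(t_end[i]),
            n=int(n_per[i]),
            incidence=float(incidences[i]),
            variance=float(variances[i]) if variances is not None else float("nan"),
        )
        for i in range(len(incidences))
    )
    return WithinStudySummary(
        estimate=estimate,
        variance=variance,
        ci_lower=lower,
        ci_upper=upper,
        level=level,
        per_stratum=per,
        weights=tuple(float(w) for w in weights),
        variance_complete=complete,
    )


def within_study_risk(
    cohort: StratifiedCohort, level: float = 0.95
) -> WithinStudySummary:
    """Within-study risk CI_w(t_1) = sum_i (n_i/n) CI_i(t_i) with variance and
    a Wald interval (probability scale, clipped to [0, 1])."""
    if not cohort.truncated:
        raise ValueError("apply truncate_triangles before within-study estimation")
    curves = _stratum_curves(cohort)
    incidences = np.array([1.0 - c(t_i) for c, t_i in zip(curves, cohort.t)])
    variances = np.array([c.variance_at(t_i) for c, t_i in zip(curves, cohort.t)])
    return _summarize(
        incidences,
        np.asarray(cohort.weights),
        variances,
        cohort.n,
        level,
        cohort.t,
        cohort.n_per_stratum,
    )


def within_study_risk_cr(
    cohort: StratifiedCohort, cause: int, level: float = 0.95
) -> WithinStudySummary:
    """Competing-risks within-study risk for one cause.

    The stratum incidences are Aalen-Johansen estimates CI_ih(t_i); in the
    between-stratum variance term the survival is replaced by 1 - CI_ih(t_i)
    and the within-stratum term uses the Aalen-Johansen variance.  With no
    competing events present this reduces exactly to the Kaplan-Meier form.
    """
    if not cohort.truncated:
        raise ValueError("apply truncate_triangles before within-study estimation")
    curves = _stratum_curves(cohort, cause=cause)
    incidences = np.array([c(t_i) for c, t_i in zip(curves, cohort.t)])
    variances = np.array([c.variance_at(t_i) for c, t_i in zip(curves, cohort.t)])
    return _summarize(
        incidences,
        np.asarray(cohort.weights),
        variances,
        cohort.n,
        level,
        cohort.t,
        cohort.n_per_stratum,
    )


def from_end_of_followup(
    estimates: Sequence[float],
    weights: Sequence[float] | None = None,
    variances: Sequence[float] | None = None,
    n: int | None = None,
    level: float = 0.95,
    t_end: Sequence[float] | None = None,
) -> WithinStudySummary:
    """Within-study risk from published end-of-follow-up incidences.

    Entry point when only summary numbers (one incidence per stratum, on the
    probability scale) are available.  Weights default to equal and must sum
    to one.  The between-stratum variance term requires the total sample size
    ``n``; when ``n`` or the stratum variances are unknown the variance is
    reported as incomplete (``None`` without ``variances``).
    """
    est = np.asarray(estimates, dtype=float)
    if weights is None:
        w = np.full(est.size, 1.0 / est.size)
    else:
        w = np.asarray(weights, dtype=float)
    if w.size != est.size:
        raise ValueError("weights and estimates must have equal length")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must be nonnegative and sum to 1")
    var = np.asarray(variances, dtype=float) if variances is not None else None
    if var is not None and var.size != est.size:
        raise ValueError("variances and estimates must have equal length")
    return _summarize(
        est,
        w,
        var,
        n,
        level,
        t_end if t_end is not None else [float("nan")] * est.size,
        [0] * est.size,
    )


def trend_diagnostic(
    cohort: StratifiedCohort,
    grid: Sequence[float] | None = None,
    level: float = 0.95,
    cause: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Assess calendar time trends by comparing stratum incidence curves.

    Returns a table of stratum incidence estimates with pointwise Wald bands
    on a common grid within [0, t_k], and a summary with the maximum pairwise
    standardized difference per grid time.  Under no trend (iid strata) each
    pointwise comparison flags at roughly the nominal rate; a large
    standardized difference signals a trend and hence dependent
    administrative censoring in a pooled analysis.
    """
    if cohort.k < 2:
        raise ValueError("trend diagnostic requires at least two strata")
    t_k = cohort.t[-1]
    if grid is None:
        grid = np.linspace(0.0, t_k, 21)[1:]
    grid = np.asarray(grid, dtype=float)
    if np.any(grid > t_k + 1e-12):
        raise ValueError(f"grid must lie within [0, t_k] = [0, {t_k}]")
    curves = _stratum_curves(cohort, cause=cause)
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    for i, curve in enumerate(curves, start=1):
        for t in grid:
            inc = curve(t) if cause is not None else 1.0 - curve(t)
            var = curve.variance_at(t)
            se = np.sqrt(var)
            rows.append(
                {
                    "stratum": i,
                    "time": float(t),
                    "incidence": float(inc),
                    "variance": float(var),
                    "lower": float(np.clip(inc - z * se, 0.0, 1.0)),
                    "upper": float(np.clip(inc + z * se, 0.0, 1.0)),
                }
            )
    table = pd.DataFrame(rows)

    max_z_per_time = {}
    for t, sub in table.groupby("time"):
        inc = sub["incidence"].to_numpy()
        var = sub["variance"].to_numpy()
        zmax = 0.0
        for a in range(inc.size):
            for b in range(a + 1, inc.size):
                diff = abs(inc[a] - inc[b])
                denom = np.sqrt(var[a] + var[b])
                if diff == 0.0:
                    continue
                zmax = max(zmax, diff / denom if denom > 0 else np.inf)
        max_z_per_time[float(t)] = zmax
    overall = max(max_z_per_time.values())
    summary = {
        "max_standardized_difference": overall,
        "per_time": max_z_per_time,
        "critical_value": float(z),
        "flag": bool(overall > z),
        "flag_per_time": {t: bool(v > z) for t, v in max_z_per_time.items()},
        "level": level,
    }
    return table, summary


def per_ten_thousand(probability: float, ndigits: int = 1) -> float:
    """Present a probability on the per-10,000 scale, rounded half away from
    zero to ``ndigits`` decimals (the convention used for reported risks)."""
    scaled = Decimal(repr(probability * 1e4))
    # absorb float representation noise well below any reported precision
    scaled = scaled.quantize(Decimal("1e-9"), rounding=ROUND_HALF_UP)
    quant = Decimal(1).scaleb(-ndigits)
    return float(scaled.quantize(quant, rounding=ROUND_HALF_UP))
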