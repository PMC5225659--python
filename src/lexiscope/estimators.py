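"""Product-limit machinery: risk tables, Kaplan-Meier with Greenwood variance,
Aalen-Johansen cause-specific cumulative incidence, and the pooled estimator.

Conventions: at tied times events occur before censorings, so a subject
censored at time s is still at risk at s.  All-cause events (cause of interest
and competing causes together) drive the all-cause survival used inside the
Aalen-Johansen estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_io import EVENT_STATUSES, Status, StepCurve, SubjectRecord
from .lexis import StratifiedCohort

__all__ = ["RiskTable", "risk_table", "km", "aj", "pooled_km"]

#: flag set on a curve when Greenwood's variance is degenerate (Y == d at the
#: last event time) and the preceding value was carried forward.
VARIANCE_DEGENERATE = "variance-degenerate"


@dataclass(frozen=True)
class RiskTable:
    """Event-time counts for a (sub)sample.

    ``times`` are the distinct all-cause event times (ascending); ``at_risk``
    the number at risk just before each (ties: events first); ``events`` the
    all-cause event count; ``events_by_cause`` per-cause counts (rows keyed by
    ``causes``); ``censored_between[j]`` the number of censorings in
    ``[times[j], times[j+1])`` with ``censored_between[0]`` counting
    censorings before the first event time.
    """

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    causes: tuple[int, ...]
    events_by_cause: np.ndarray  # shape (len(causes), len(times))
    censored_between: np.ndarray  # length len(times) + 1
    n: int
    domain_end: float

    def __post_init__(self) -> None:
        if np.any(self.events > self.at_risk) or np.any(self.events <= 0):
            raise ValueError("require 0 < d(s) <= Y(s) at every event time")
        if self.times.size and np.any(np.diff(self.at_risk) > 0):
            raise ValueError("at-risk counts must be nonincreasing")


def risk_table(
    records: Sequence[SubjectRecord], domain_end: float | None = None
) -> RiskTable:
    """Tabulate at-risk and event counts from subject records.

    Only event times ``<= domain_end`` are included; ``domain_end`` defaults
    to the largest observed follow-up.
    """
    followups = np.array([r.followup for r in records], dtype=float)
    is_event = np.array([r.is_event for r in records], dtype=bool)
    cause = np.array([r.cause if r.cause is not None else -1 for r in records])
    n = followups.size
    if domain_end is None:
        domain_end = float(followups.max()) if n else 0.0

    keep = is_event & (followups <= domain_end + 1e-12)
    etimes = np.unique(followups[keep])
    sorted_fu = np.sort(followups)
    # events precede censorings at ties: at risk at s means followup >= s
    at_risk = n - np.searchsorted(sorted_fu, etimes, side="left")
    events = np.array(
        [np.count_nonzero(keep & (followups == s)) for s in etimes], dtype=int
    )
    causes = tuple(sorted({int(c) for c in cause[is_event]}))
    by_cause = np.zeros((len(causes), etimes.size), dtype=int)
    for row, c in enumerate(causes):
        sel = keep & (cause == c)
        by_cause[row] = [np.count_nonzero(sel & (followups == s)) for s in etimes]

    cens_times = np.sort(followups[~is_event])
    edges = np.concatenate(([-np.inf], etimes, [np.inf]))
    censored_between = np.histogram(cens_times, bins=edges)[0]

    return RiskTable(
        times=etimes,
        at_risk=at_risk.astype(int),
        events=events,
        causes=causes,
        events_by_cause=by_cause,
        censored_between=censored_between,
        n=n,
        domain_end=float(domain_end),
    )


def km(table: RiskTable) -> StepCurve:
    """Kaplan-Meier product-limit survival curve with Greenwood variance.

    Var(S(t)) = S(t)^2 * sum_{s_j <= t} d_j / (Y_j (Y_j - d_j)).  Where
    Y_j == d_j (everyone remaining fails) the Greenwood term is undefined and
    the survival hits zero; the variance there is carried forward from the
    last computable value and the curve is flagged.
    """
    Y = table.at_risk.astype(float)
    d = table.events.astype(float)
    surv = np.cumprod((Y - d) / Y)
    flags = set()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = d / (Y * (Y - d))
    degenerate = ~np.isfinite(terms)
    if np.any(degenerate):
        flags.add(VARIANCE_DEGENERATE)
        terms = np.where(degenerate, 0.0, terms)
    var = surv**2 * np.cumsum(terms)
    if np.any(degenerate):
        # carry the last computable variance through the degenerate point(s)
        for j in np.nonzero(degenerate)[0]:
            var[j:] = var[j - 1] if j > 0 else 0.0
    return StepCurve(
        times=table.times,
        values=surv,
        domain_end=table.domain_end,
        variances=var,
        start_value=1.0,
        flags=frozenset(flags),
    )


def aj(table: RiskTable, cause: int) -> StepCurve:
    """Aalen-Johansen cause-specific cumulative incidence.

    CI_h(t) = sum_{s_j <= t} S(s_j-) d_h(s_j) / Y(s_j), with S the all-cause
    Kaplan-Meier.  The variance is the recursive estimator of
    Andersen-Borgan-Gill-Keiding form, evaluated at each jump time via
    cumulative sums.  With a single cause it reduces exactly to 1 - KM with
    Greenwood variance.
    """
    if cause not in table.causes:
        raise ValueError(f"unknown cause label {cause!r}; table has {table.causes}")
    Y = table.at_risk.astype(float)
    d = table.events.astype(float)
    dh = table.events_by_cause[table.causes.index(cause)].astype(float)
    surv = np.cumprod((Y - d) / Y)
    surv_minus = np.concatenate(([1.0], surv[:-1]))
    ci = np.cumsum(surv_minus * dh / Y)

    flags = set()
    with np.errstate(divide="ignore", invalid="ignore"):
        a = d / (Y * (Y - d))  # Greenwood increments (all-cause)
    degenerate = ~np.isfinite(a)
    if np.any(degenerate):
        # CI is flat beyond an absorbing event time, so these terms carry a
        # zero coefficient in the variance; drop them but flag the curve.
        flags.add(VARIANCE_DEGENERATE)
        a = np.where(degenerate, 0.0, a)
    b = surv_minus * dh / Y**2

    # Var(CI_h(t_m)) = sum_{j<=m} (CI_m - CI_j)^2 a_j
    #                + sum_{j<=m} S(s_j-)^2 (Y_j - dh_j)/Y_j * dh_j/Y_j^2
    #                - 2 sum_{j<=m} (CI_m - CI_j) b_j
    # expanded into cumulative sums for O(J) evaluation at all jump times.
    A = np.cumsum(a)
    Ac1 = np.cumsum(ci * a)
    Ac2 = np.cumsum(ci**2 * a)
    mid = np.cumsum(surv_minus**2 * (Y - dh) / Y * dh / Y**2)
    B = np.cumsum(b)
    Bc = np.cumsum(ci * b)
    var = (ci**2 * A - 2 * ci * Ac1 + Ac2) + mid - 2 * (ci * B - Bc)
    var = np.maximum(var, 0.0)

    return StepCurve(
        times=table.times,
        values=ci,
        domain_end=table.domain_end,
        variances=var,
        start_value=0.0,
        flags=frozenset(flags),
    )


def _stratum_heterogeneity(cohort: StratifiedCohort) -> float:
    """Max pairwise standardized difference of stratum incidences at the
    common age t_k (the largest age every stratum can reach)."""
    t_k = cohort.t[-1]
    ests, variances = [], []
    for stratum, t_i in zip(cohort.strata, cohort.t):
        if not stratum:
            continue
        curve = km(risk_table(stratum, domain_end=t_i))
        ests.append(1.0 - curve(t_k))
        variances.append(curve.variance_at(t_k))
    zmax = 0.0
    for i in range(len(ests)):
        for j in range(i + 1, len(ests)):
            denom = np.sqrt(variances[i] + variances[j])
            if denom > 0:
                zmax = max(zmax, abs(ests[i] - ests[j]) / denom)
    return zmax


def pooled_km(
    cohort: StratifiedCohort | Sequence[SubjectRecord],
    domain_end: float | None = None,
    warn_on_trend: bool = True,
) -> StepCurve:
    """Kaplan-Meier applied to the merged sample.

    Under calendar time trends this estimator is biased for the population
    cumulative incidence beyond the shortest stratum follow-up t_k, because
    administrative censoring is then dependent; it is provided for comparison
    with the stratified estimators.  When given a :class:`StratifiedCohort`
    whose end-of-follow-up incidences differ significantly across strata
    (max pairwise standardized difference > 3), a warning is emitted.
    """
    if isinstance(cohort, StratifiedCohort):
        records = cohort.merged()
        if domain_end is None:
            domain_end = cohort.t[0]
        if warn_on_trend and cohort.k > 1 and _stratum_heterogeneity(cohort) > 3.0:
            warnings.warn(
                "stratum incidences differ significantly: the pooled "
                "Kaplan-Meier is biased under calendar time trends; prefer "
                "the stratified or within-study estimators",
                stacklevel=2,
            )
    else:
        records = list(cohort)
    return km(risk_table(records, domain_end=domain_end))
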