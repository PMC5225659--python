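"""Proportional-hazards extrapolation of stratum risks.

Under a calendar time trend the cumulative incidence beyond the shortest
follow-up t_k is not identified without further assumptions.  If stratum
hazards are proportional, lambda_i(t) = lambda_1(t) exp(beta_i), a Cox
partial-likelihood fit with stratum-indicator covariates yields beta and a
Breslow baseline survival S_1(t) on the full window [0, t_1]; each stratum's
incidence is then extrapolated beyond its own t_i and the population estimate
is the weighted average

    CI_PH(t) = 1 - sum_i (n_i/n) S_1(t)^{exp(beta_i)},   beta_1 = 0.

The proportionality assumption is checkable only on [0, t_i] per stratum
(log-minus-log plots); beyond that it is an assumption, and any clear
deviation invalidates the extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort_io import Status, StepCurve
from .estimators import km, risk_table
from .lexis import StratifiedCohort

__all__ = ["PHFit", "fit_ph", "extrapolated_incidence", "loglog_diagnostic"]


@dataclass(frozen=True)
class PHFit:
    """Cox fit with stratum indicators: log hazard ratios beta_2..beta_k
    (beta_1 = 0 for the reference, earliest-entry stratum), Breslow baseline
    survival on [0, t_1], and the observed information at the optimum."""

    beta: np.ndarray  # length k-1, strata 2..k
    baseline_survival: StepCurve
    information: np.ndarray  # (k-1, k-1)
    converged: bool
    iterations: int
    n_per_stratum: tuple[int, ...]
    log_likelihood: float

    @property
    def beta_se(self) -> np.ndarray:
        """Standard errors from the inverse observed information."""
        return np.sqrt(np.diag(np.linalg.inv(self.information)))


def _stratum_arrays(cohort: StratifiedCohort):
    """Follow-up times and event indicators per stratum (cause of interest;
    competing events and all censorings are treated as censored for the
    cause-specific hazard)."""
    times, events = [], []
    for stratum in cohort.strata:
        times.append(np.array([r.followup for r in stratum], dtype=float))
        events.append(np.array([r.status is Status.EVENT for r in stratum], dtype=bool))
    return times, events


def fit_ph(
    cohort: StratifiedCohort, max_iter: int = 50, tol: float = 1e-10
) -> PHFit:
    """Maximize the Cox partial likelihood with k-1 stratum indicators.

    Newton-Raphson from beta = 0 with step-halving on non-increase; Breslow
    handling of ties and the Breslow estimator for the baseline cumulative
    hazard.  Because the covariates are stratum indicators, the risk-set
    aggregates reduce to per-stratum at-risk counts Y_i(s_j), making each
    iteration a few vectorized passes over the distinct event times.
    """
    k = cohort.k
    if k < 2:
        raise ValueError("proportional-hazards fit requires at least two strata")
    times, events = _stratum_arrays(cohort)
    d_total = np.array([ev.sum() for ev in events])
    if d_total[0] == 0:
        raise ValueError("no events in the reference stratum; baseline not identified")
    if np.any(d_total[1:] == 0):
        bad = [i + 2 for i in np.nonzero(d_total[1:] == 0)[0]]
        raise ValueError(
            f"strata {bad} have zero events: the partial likelihood is monotone "
            "and the hazard ratio diverges"
        )

    etimes = np.unique(np.concatenate([t[e] for t, e in zip(times, events)]))
    J = etimes.size
    # per-stratum at-risk counts and event counts at each distinct event time
    Y = np.empty((k, J))
    D = np.zeros((k, J))
    for i in range(k):
        st = np.sort(times[i])
        Y[i] = times[i].size - np.searchsorted(st, etimes, side="left")
        ev_sorted = np.sort(times[i][events[i]])
        left = np.searchsorted(ev_sorted, etimes, side="left")
        right = np.searchsorted(ev_sorted, etimes, side="right")
        D[i] = right - left
    d_j = D.sum(axis=0)

    def loglik_parts(beta_full):
        exb = np.exp(beta_full)  # length k
        s0 = exb @ Y  # (J,)
        logpl = float(np.dot(beta_full, d_total) - np.dot(d_j, np.log(s0)))
        p = (Y[1:] * exb[1:, None]) / s0  # (k-1, J) share of risk mass
        score = D[1:].sum(axis=1) - p @ d_j
        info = -((p * d_j) @ p.T)
        np.fill_diagonal(info, (d_j * p * (1.0 - p)).sum(axis=1))
        return logpl, score, info, s0

    beta = np.zeros(k)
    logpl, score, info, s0 = loglik_parts(beta)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        # tolerances are relative: |logPL| grows with n, so an absolute
        # threshold would sit below floating-point noise on large cohorts
        noise = 1e-9 * (abs(logpl) + 1.0)
        step = np.linalg.solve(info, score)
        new_beta = beta.copy()
        new_beta[1:] = beta[1:] + step
        new_logpl, new_score, new_info, new_s0 = loglik_parts(new_beta)
        halvings = 0
        while new_logpl < logpl - noise and halvings < 30:
            step /= 2.0
            new_beta[1:] = beta[1:] + step
            new_logpl, new_score, new_info, new_s0 = loglik_parts(new_beta)
            halvings += 1
        delta = new_logpl - logpl
        beta, logpl, score, info, s0 = new_beta, new_logpl, new_score, new_info, new_s0
        if abs(delta) < max(tol * (abs(logpl) + 1.0), tol) and np.max(
            np.abs(score)
        ) < 1e-8:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Cox partial-likelihood fit did not converge in {max_iter} iterations"
        )

    # Breslow baseline cumulative hazard at the fitted beta
    cumhaz = np.cumsum(d_j / s0)
    baseline = StepCurve(
        times=etimes,
        values=np.exp(-cumhaz),
        domain_end=cohort.t[0],
        variances=None,
        start_value=1.0,
    )
    return PHFit(
        beta=beta[1:].copy(),
        baseline_survival=baseline,
        information=info,
        converged=converged,
        iterations=iterations,
        n_per_stratum=cohort.n_per_stratum,
        log_likelihood=logpl,
    )


def extrapolated_incidence(fit: PHFit, weights=None) -> StepCurve:
    """Weighted proportional-hazards incidence CI_PH on [0, t_1].

    Each stratum's survival S_1(t)^{exp(beta_i)} extends beyond its own end
    of follow-up — the extrapolation is the point — and the population curve
    is their n_i/n-weighted average.  No variance is attached.
    """
    if not fit.converged:
        raise ValueError("refusing to extrapolate from a non-converged fit")
    if weights is None:
        n = sum(fit.n_per_stratum)
        weights = np.array([ni / n for ni in fit.n_per_stratum])
    else:
        weights = np.asarray(weights, dtype=float)
    beta_full = np.concatenate(([0.0], fit.beta))
    base = fit.baseline_survival
    surv = base.values[None, :] ** np.exp(beta_full)[:, None]
    values = 1.0 - weights @ surv
    return StepCurve(
        times=base.times,
        values=values,
        domain_end=base.domain_end,
        variances=None,
        start_value=0.0,
    )


def loglog_diagnostic(cohort: StratifiedCohort):
    """Per-stratum log(-log S_i(t)) curves for graphical proportionality checks.

    Each stratum's transformed Kaplan-Meier curve is reported at its own event
    times within [0, t_i]; under proportional hazards the curves differ by
    constant vertical offsets equal to beta_i.  Points where S_i is 0 or 1
    (transform undefined) are skipped and counted in the returned summary.
    """
    import pandas as pd

    rows = []
    skipped = 0
    for i, (stratum, t_i) in enumerate(zip(cohort.strata, cohort.t), start=1):
        curve = km(risk_table(stratum, domain_end=t_i))
        for t, s in zip(curve.times, curve.values):
            if 0.0 < s < 1.0:
                rows.append(
                    {"stratum": i, "time": float(t), "loglog": float(np.log(-np.log(s)))}
                )
            else:
                skipped += 1
    table = pd.DataFrame(rows, columns=["stratum", "time", "loglog"])
    return table, {"skipped_points": skipped}
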