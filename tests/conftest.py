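"""Shared fixtures and builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from lexiscope import Status, StratifiedCohort, SubjectRecord

#: single base seed for every stochastic test in the suite
BASE_SEED = 2026


def make_records(followups, statuses, causes=None, entry=0.0):
    """Build records from parallel lists; cause defaults to 1 for events."""
    out = []
    for i, (fu, st) in enumerate(zip(followups, statuses)):
        st = Status(st)
        if causes is not None:
            cause = causes[i]
        else:
            cause = 1 if st in (Status.EVENT, Status.COMPETING) else None
        out.append(SubjectRecord(entry=entry, followup=float(fu), status=st, cause=cause))
    return out


def build_cohort(strata_records, t, truncated=True):
    """Assemble a StratifiedCohort directly from per-stratum record lists."""
    boundaries = tuple(float(i) for i in range(len(strata_records) + 1))
    return StratifiedCohort(
        strata=tuple(tuple(s) for s in strata_records),
        t=tuple(float(x) for x in t),
        boundaries=boundaries,
        truncated=truncated,
    )


def censored_exponential_stratum(rng, n, rate, t_end, ltfu_rate=0.0, entry=0.0):
    """One stratum: exponential events, admin censoring at t_end, optional
    exponential loss to follow-up."""
    t = rng.exponential(1.0 / rate, n)
    c2 = rng.exponential(1.0 / ltfu_rate, n) if ltfu_rate > 0 else np.full(n, np.inf)
    out = []
    for ti, ci in zip(t, c2):
        if ti <= min(ci, t_end):
            out.append(SubjectRecord(entry, float(ti), Status.EVENT, 1))
        elif ci < t_end:
            out.append(SubjectRecord(entry, float(ci), Status.LOSS_CENSORED))
        else:
            out.append(SubjectRecord(entry, float(t_end), Status.ADMIN_CENSORED))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(BASE_SEED)
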