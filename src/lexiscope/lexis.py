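"""Entry-time stratification on the Lexis diagram and triangle truncation.

Under staggered entry with a fixed administrative end date D, the censoring
age C1 = D - E depends on the entry time E, so administrative censoring is
dependent whenever the event risk carries a calendar time trend.  Splitting
the recruitment window into k entry-time strata and truncating each stratum at
its common end-of-follow-up age t_i = D - (right window boundary) removes all
administrative censoring from the interior of every stratum: within stratum i
the sample restricted to [0, t_i] is independently censored, at the price of
dropping the events that fall in the Lexis-diagram triangles beyond t_i.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .cohort_io import Status, StudyDesign, SubjectRecord

__all__ = ["StratifiedCohort", "stratify", "truncate_triangles", "dropped_fraction"]


@dataclass(frozen=True)
class StratifiedCohort:
    """Records partitioned into k entry-time strata.

    Stratum 1 holds the earliest entrants and has the longest common
    end-of-follow-up age: t_1 >= t_2 >= ... >= t_k.  ``dropped_events`` /
    ``dropped_competing`` count cause-of-interest and competing events removed
    by :func:`truncate_triangles` (zero before truncation).
    """

    strata: tuple[tuple[SubjectRecord, ...], ...]
    t: tuple[float, ...]
    boundaries: tuple[float, ...]
    design: StudyDesign | None = None
    dropped_events: int = 0
    dropped_competing: int = 0
    truncated: bool = False

    @property
    def k(self) -> int:
        return len(self.strata)

    @property
    def n_per_stratum(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.strata)

    @property
    def n(self) -> int:
        return sum(self.n_per_stratum)

    @property
    def weights(self) -> tuple[float, ...]:
        """Empirical stratum probabilities n_i / n."""
        n = self.n
        return tuple(ni / n for ni in self.n_per_stratum)

    def merged(self) -> list[SubjectRecord]:
        """All records in stratum order (stratum 1 first)."""
        return [rec for stratum in self.strata for rec in stratum]


def stratify(
    records: Sequence[SubjectRecord],
    design: StudyDesign,
    boundaries: Sequence[float] | None = None,
) -> StratifiedCohort:
    """Partition a cohort into entry-time strata.

    The recruitment window [O, P] is split into k half-open windows
    [b_i, b_{i+1}), the last closed on the right so entries exactly at P are
    assigned deterministically.  By default the windows have equal width;
    an explicit ``boundaries`` sequence (length k+1, from O to P) supports
    unequal widths such as mixed 1-year / 3-year birth cohorts.  The common
    end-of-follow-up age of stratum i is t_i = admin_end - b_{i+1}, the worst
    case over the window, so t is data-independent and nonincreasing.
    """
    if not records:
        raise ValueError("cannot stratify an empty cohort")
    if boundaries is None:
        bounds = np.linspace(design.recruit_start, design.recruit_end, design.k + 1)
    else:
        bounds = np.asarray(boundaries, dtype=float)
        if bounds.ndim != 1 or bounds.size < 2 or np.any(np.diff(bounds) <= 0):
            raise ValueError("boundaries must be strictly increasing with length k+1")
        if not (
            np.isclose(bounds[0], design.recruit_start)
            and np.isclose(bounds[-1], design.recruit_end)
        ):
            raise ValueError("boundaries must span [recruit_start, recruit_end]")
    k = bounds.size - 1
    t = tuple(float(design.admin_end - b) for b in bounds[1:])

    entries = np.array([rec.entry for rec in records], dtype=float)
    if np.any(entries < design.recruit_start) or np.any(entries > design.recruit_end):
        bad = int(
            np.argmax(
                (entries < design.recruit_start) | (entries > design.recruit_end)
            )
        )
        raise ValueError(
            f"entry {entries[bad]} (record {bad}) outside recruitment window "
            f"[{design.recruit_start}, {design.recruit_end}]"
        )
    # half-open windows, the last closed on the right
    idx = np.clip(np.searchsorted(bounds, entries, side="right") - 1, 0, k - 1)
    buckets: list[list[SubjectRecord]] = [[] for _ in range(k)]
    for rec, i in zip(records, idx):
        buckets[i].append(rec)

    return StratifiedCohort(
        strata=tuple(tuple(b) for b in buckets),
        t=t,
        boundaries=tuple(float(b) for b in bounds),
        design=design,
    )


def truncate_triangles(cohort: StratifiedCohort) -> StratifiedCohort:
    """Drop observation time beyond each stratum's common end-of-follow-up age.

    Any record in stratum i observed beyond t_i — whatever its status — is
    replaced by administrative censoring exactly at t_i; records with
    followup <= t_i are kept unchanged, so an event exactly at the triangle
    boundary t_i is retained as an event (events precede censorings at tied
    times).  After truncation every administrative censoring in stratum i
    occurs at t_i, hence estimators restricted to [0, t_i] see an
    independently censored sample.
    """
    new_strata: list[tuple[SubjectRecord, ...]] = []
    dropped_events = cohort.dropped_events
    dropped_competing = cohort.dropped_competing
    for stratum, t_i in zip(cohort.strata, cohort.t):
        out = []
        for rec in stratum:
            if rec.followup > t_i:
                if rec.status is Status.EVENT:
                    dropped_events += 1
                elif rec.status is Status.COMPETING:
                    dropped_competing += 1
                rec = SubjectRecord(
                    entry=rec.entry,
                    followup=t_i,
                    status=Status.ADMIN_CENSORED,
                    cause=None,
                )
            elif rec.status is Status.ADMIN_CENSORED and rec.followup < t_i - 1e-12:
                warnings.warn(
                    "administrative censoring observed strictly before the "
                    f"stratum end-of-follow-up age {t_i}; check the study design",
                    stacklevel=2,
                )
            out.append(rec)
        new_strata.append(tuple(out))
    return replace(
        cohort,
        strata=tuple(new_strata),
        dropped_events=dropped_events,
        dropped_competing=dropped_competing,
        truncated=True,
    )


def dropped_fraction(cohort: StratifiedCohort) -> float:
    """Fraction of cause-of-interest events removed by triangle truncation."""
    if not cohort.truncated:
        raise ValueError("apply truncate_triangles before computing dropped_fraction")
    surviving = sum(
        1 for s in cohort.strata for rec in s if rec.status is Status.EVENT
    )
    total = cohort.dropped_events + surviving
    if total == 0:
        raise ValueError("no events in the cohort; dropped fraction undefined")
    return cohort.dropped_events / total
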