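"""Domain types and delimited-text I/O for subject-level cohorts and step curves.

A cohort is a sequence of :class:`SubjectRecord`: one individual's calendar
entry time, observed follow-up duration ``min(T, C)`` (event time vs. censoring
time), and an outcome status.  Two censoring mechanisms are distinguished:
administrative censoring at the fixed end-of-study date (status ``admin``) and
loss to follow-up before that date (status ``ltfu``, e.g. emigration).  All
times are continuous decimal years; callers convert calendar dates before
constructing records.

Every estimator in this package returns a :class:`StepCurve` — a
right-continuous piecewise-constant function with optional pointwise
variances.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Status",
    "SubjectRecord",
    "StudyDesign",
    "StepCurve",
    "NordicIncidenceTable",
    "read_cohort",
    "write_cohort",
    "read_curve",
    "write_curve",
    "load_nordic_incidence_table",
]


class Status(str, Enum):
    """Outcome of one subject's follow-up."""

    EVENT = "event"
    LOSS_CENSORED = "ltfu"
    ADMIN_CENSORED = "admin"
    COMPETING = "competing"


#: Statuses that terminate follow-up with an observed event (of any cause).
EVENT_STATUSES = frozenset({Status.EVENT, Status.COMPETING})


@dataclass(frozen=True)
class SubjectRecord:
    """One individual: entry time, observed follow-up, and outcome.

    ``followup`` is the observed duration since entry, i.e. the minimum of the
    latent event time and all censoring times.  ``cause`` is a small integer
    label and must be present exactly when the status is an event type
    (``event`` or ``competing``); censored records carry no cause.
    """

    entry: float
    followup: float
    status: Status
    cause: int | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.entry):
            raise ValueError(f"entry must be finite, got {self.entry!r}")
        if not (math.isfinite(self.followup) and self.followup >= 0):
            raise ValueError(f"followup must be finite and >= 0, got {self.followup!r}")
        status = self.status if type(self.status) is Status else Status(self.status)
        object.__setattr__(self, "status", status)
        if status in EVENT_STATUSES:
            if self.cause is None:
                raise ValueError(f"status {status.value!r} requires a cause label")
            object.__setattr__(self, "cause", int(self.cause))
        elif self.cause is not None:
            raise ValueError(f"status {status.value!r} must not carry a cause label")

    @property
    def is_event(self) -> bool:
        return self.status in EVENT_STATUSES


@dataclass(frozen=True)
class StudyDesign:
    """Recruitment window [recruit_start, recruit_end], administrative end date,
    and number of entry-time strata."""

    recruit_start: float
    recruit_end: float
    admin_end: float
    k: int = 1

    def __post_init__(self) -> None:
        if not (self.recruit_start < self.recruit_end <= self.admin_end):
            raise ValueError(
                "require recruit_start < recruit_end <= admin_end, got "
                f"{self.recruit_start}, {self.recruit_end}, {self.admin_end}"
            )
        if int(self.k) < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        object.__setattr__(self, "k", int(self.k))


@dataclass(eq=False)
class StepCurve:
    """Right-continuous step function on [0, domain_end].

    ``times`` are the strictly increasing jump times; ``values[j]`` is the
    value on ``[times[j], times[j+1])``.  Before the first jump the curve
    equals ``start_value`` (1 for survival curves, 0 for incidence curves).
    ``variances`` holds the pointwise variance after each jump, or ``None``
    when no variance estimate exists.  Evaluation beyond ``domain_end`` is an
    error: the curve is only identified up to the end of follow-up.
    """

    times: np.ndarray
    values: np.ndarray
    domain_end: float
    variances: np.ndarray | None = None
    start_value: float = 1.0
    start_variance: float = 0.0
    flags: frozenset = field(default_factory=frozenset, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.variances is not None:
            self.variances = np.asarray(self.variances, dtype=float)
            if self.variances.shape != self.times.shape:
                raise ValueError("variances must match times in length")
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be 1-d arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("jump times must be strictly increasing")
        if self.times.size and self.times[-1] > self.domain_end + 1e-12:
            raise ValueError("jump times must not exceed domain_end")
        self.flags = frozenset(self.flags)

    # -- evaluation ---------------------------------------------------------

    def _check_domain(self, t: np.ndarray) -> None:
        if np.any(t < 0) or np.any(t > self.domain_end + 1e-12):
            raise ValueError(
                f"evaluation outside [0, {self.domain_end}] requested; the curve "
                "is not identified beyond its end of follow-up"
            )

    def __call__(self, t):
        """Evaluate the curve at time(s) ``t`` (right-continuous)."""
        arr = np.asarray(t, dtype=float)
        self._check_domain(arr)
        idx = np.searchsorted(self.times, arr, side="right")
        padded = np.concatenate(([self.start_value], self.values))
        out = padded[idx]
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    def variance_at(self, t):
        """Pointwise variance at time(s) ``t``; errors when no variances exist."""
        if self.variances is None:
            raise ValueError("this curve carries no variance estimates")
        arr = np.asarray(t, dtype=float)
        self._check_domain(arr)
        idx = np.searchsorted(self.times, arr, side="right")
        padded = np.concatenate(([self.start_variance], self.variances))
        out = padded[idx]
        return float(out) if np.isscalar(t) or arr.ndim == 0 else out

    # -- equality (flags excluded) ------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, StepCurve):
            return NotImplemented
        same_var = (
            (self.variances is None and other.variances is None)
            or (
                self.variances is not None
                and other.variances is not None
                and np.array_equal(self.variances, other.variances)
            )
        )
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
            and self.domain_end == other.domain_end
            and self.start_value == other.start_value
            and self.start_variance == other.start_variance
            and same_var
        )


# ---------------------------------------------------------------------------
# Cohort files: CSV with header entry,followup,status,cause (cause may be blank)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("entry", "followup", "status")
_STATUS_TOKENS = {s.value: s for s in Status}


def read_cohort(
    path, dialect: Mapping[str, str] | None = None
) -> list[SubjectRecord]:
    """Read a subject-level cohort from delimited text.

    ``dialect`` optionally maps the canonical column names (``entry``,
    ``followup``, ``status``, ``cause``) to the names used in the file.
    Malformed rows are rejected with an error naming the offending data row
    (1-based, excluding the header).
    """
    dialect = dict(dialect or {})
    colname = {c: dialect.get(c, c) for c in (*_REQUIRED_COLUMNS, "cause")}
    records: list[SubjectRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canonical in _REQUIRED_COLUMNS:
            if colname[canonical] not in header:
                raise ValueError(
                    f"missing required column {colname[canonical]!r} in {path}"
                )
        has_cause = colname["cause"] in header
        for rownum, row in enumerate(reader, start=1):
            try:
                status_token = (row[colname["status"]] or "").strip()
                if status_token not in _STATUS_TOKENS:
                    raise ValueError(f"unknown status token {status_token!r}")
                cause_raw = (row.get(colname["cause"]) or "").strip() if has_cause else ""
                record = SubjectRecord(
                    entry=float(row[colname["entry"]]),
                    followup=float(row[colname["followup"]]),
                    status=_STATUS_TOKENS[status_token],
                    cause=int(cause_raw) if cause_raw else None,
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}, data row {rownum}: {exc}") from exc
            records.append(record)
    return records


def write_cohort(records: Iterable[SubjectRecord], path) -> None:
    """Write records as CSV with header ``entry,followup,status,cause``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["entry", "followup", "status", "cause"])
        for rec in records:
            writer.writerow(
                [
                    repr(float(rec.entry)),
                    repr(float(rec.followup)),
                    rec.status.value,
                    "" if rec.cause is None else rec.cause,
                ]
            )


# ---------------------------------------------------------------------------
# Curve files: CSV header time,value,variance; a leading comment line records
# the domain end so read(write(c)) reproduces the curve exactly.
# ---------------------------------------------------------------------------


def write_curve(curve: StepCurve, path) -> None:
    """Write a step curve as CSV.  The first data row is the time-0 start
    value; subsequent rows are the jump times.  Variance cells are blank when
    the curve carries no variances."""
    with open(path, "w", newline="") as fh:
        fh.write(f"# domain_end={curve.domain_end!r} start_value={curve.start_value!r}\n")
        writer = csv.writer(fh)
        writer.writerow(["time", "value", "variance"])
        has_var = curve.variances is not None
        writer.writerow(
            [repr(0.0), repr(curve.start_value), repr(curve.start_variance) if has_var else ""]
        )
        for j, t in enumerate(curve.times):
            writer.writerow(
                [
                    repr(float(t)),
                    repr(float(curve.values[j])),
                    repr(float(curve.variances[j])) if has_var else "",
                ]
            )


def read_curve(path) -> StepCurve:
    """Read a step curve written by :func:`write_curve`.

    A missing/blank variance column yields ``variances=None`` — absence of a
    variance estimate, not a zero variance.
    """
    with open(path, newline="") as fh:
        first = fh.readline()
        meta: dict[str, float] = {}
        if first.startswith("#"):
            for token in first[1:].split():
                if "=" in token:
                    key, val = token.split("=", 1)
                    meta[key] = float(val)
            header_line = fh.readline()
        else:
            header_line = first
        if [c.strip() for c in header_line.strip().split(",")][:2] != ["time", "value"]:
            raise ValueError(f"{path}: expected header time,value[,variance]")
        times, values, variances = [], [], []
        any_var = False
        for row in csv.reader(fh):
            if not row:
                continue
            times.append(float(row[0]))
            values.append(float(row[1]))
            if len(row) > 2 and row[2].strip():
                variances.append(float(row[2]))
                any_var = True
            else:
                variances.append(np.nan)
    if not times or times[0] != 0.0:
        raise ValueError(f"{path}: curve file must start with a time-0 row")
    start_value = values[0]
    start_variance = variances[0] if any_var else 0.0
    domain_end = meta.get("domain_end", times[-1] if len(times) > 1 else 0.0)
    return StepCurve(
        times=np.asarray(times[1:]),
        values=np.asarray(values[1:]),
        domain_end=domain_end,
        variances=np.asarray(variances[1:]) if any_var else None,
        start_value=meta.get("start_value", start_value),
        start_variance=start_variance,
    )


# ---------------------------------------------------------------------------
# Packaged reference table: end-of-follow-up cumulative incidences per 10,000
# for four childhood psychiatric disorders in Denmark and Finland, six 3-year
# birth-cohort strata (1990-2007 births, follow-up through end of 2011).
# ---------------------------------------------------------------------------

_NORDIC_INCIDENCE: dict[tuple[str, str], tuple[float, ...]] = {
    ("TS", "Denmark"): (32.1, 35.1, 46.3, 31.2, 16.5, 1.6),
    ("OCD", "Denmark"): (57.3, 32.1, 40.3, 10.8, 4.5, 0.4),
    ("ASD", "Denmark"): (109.7, 117.0, 160.3, 110.3, 88.5, 35.5),
    ("HKD", "Denmark"): (164.6, 150.5, 222.2, 168.0, 109.9, 19.0),
    ("TS", "Finland"): (9.8, 10.1, 15.1, 8.9, 5.3, 0.3),
    ("OCD", "Finland"): (38.2, 17.4, 26.4, 4.3, 1.6, 0.1),
    ("ASD", "Finland"): (77.1, 83.3, 101.5, 59.8, 51.7, 26.0),
    ("HKD", "Finland"): (133.1, 159.6, 225.6, 142.3, 100.5, 11.6),
}

DISORDERS = ("TS", "OCD", "ASD", "HKD")
COUNTRIES = ("Denmark", "Finland")
BIRTH_COHORTS = ("90-92", "93-95", "96-98", "99-01", "02-04", "05-07")


@dataclass(frozen=True)
class NordicIncidenceTable:
    """End-of-follow-up cumulative incidences per 10,000 by disorder, country
    and 3-year birth-cohort stratum, with stratum weights (default 1/6 each:
    annual birth counts were roughly constant over the recruitment window)."""

    values: Mapping[tuple[str, str], tuple[float, ...]]
    weights: tuple[float, ...] = (1 / 6,) * 6

    def __getitem__(self, key: tuple[str, str]) -> tuple[float, ...]:
        disorder, country = key
        return self.values[(disorder, country)]

    def probabilities(self, disorder: str, country: str) -> tuple[float, ...]:
        """The row rescaled from per-10,000 to probabilities."""
        return tuple(v / 1e4 for v in self[(disorder, country)])


def load_nordic_incidence_table() -> NordicIncidenceTable:
    """Return the packaged per-10,000 end-of-follow-up incidence table."""
    return NordicIncidenceTable(values=dict(_NORDIC_INCIDENCE))
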