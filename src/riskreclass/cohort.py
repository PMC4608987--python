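"""Cohort and sickness-absence register handling.

A *cohort* is a table of workers with baseline predictors (age, self-rated
health, prior sickness absence, fatigue) and 1-year follow-up sickness-absence
(SA) outcomes.  An *episode register* holds dated SA episodes per worker, from
which SA day and episode aggregates are derived.

Register conventions implemented here:

* episodes separated by fewer than ``min_gap_days`` calendar days (default 28,
  the Dutch insurance rule) count as a single episode;
* SA days are the inclusive calendar days of each recorded episode — gap days
  between merged constituents are worked days and are not counted;
* episodes straddling the observation window are clipped to it before
  counting.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Episode",
    "EpisodeRegister",
    "WorkerRecord",
    "Cohort",
    "CohortFormatError",
    "ValidationError",
    "read_cohort",
    "write_cohort",
    "read_register",
    "write_register",
    "merge_episodes",
    "aggregate_register",
    "label_high_sa_days",
    "label_high_sa_episodes",
    "complete_cases",
    "COHORT_COLUMNS",
    "HIGH_SA_DAYS_THRESHOLD",
    "HIGH_SA_EPISODES_THRESHOLD",
    "DEFAULT_MIN_GAP_DAYS",
]


class CohortFormatError(ValueError):
    """Raised when an input file does not match the expected schema."""


class ValidationError(ValueError):
    """Raised when data violate a domain invariant."""


#: Canonical cohort CSV column order.  Empty cell = missing; gender ``M``/``F``.
COHORT_COLUMNS = [
    "worker_id",
    "age",
    "gender",
    "work_hours",
    "srh",
    "prior_sa_days",
    "prior_sa_episodes",
    "fatigue",
    "fu_sa_days",
    "fu_sa_episodes",
]

#: High SA days: >= 30 cumulated SA days in the 1-year follow-up.
HIGH_SA_DAYS_THRESHOLD = 30
#: High SA episodes: >= 3 SA episodes in the 1-year follow-up.
HIGH_SA_EPISODES_THRESHOLD = 3
#: Episodes separated by fewer than this many days count as one episode.
DEFAULT_MIN_GAP_DAYS = 28

# per-column validity ranges; values outside become missing with a warning
_RANGE_CHECKS = {
    "srh": (1, 4),
    "fatigue": (20, 140),
    "fu_sa_days": (0, 366),
    "fu_sa_episodes": (0, None),
    "prior_sa_days": (0, None),
    "prior_sa_episodes": (0, None),
    "age": (0, None),
    "work_hours": (0, None),
}

_INT_COLUMNS = [
    "srh",
    "prior_sa_days",
    "prior_sa_episodes",
    "fatigue",
    "fu_sa_days",
    "fu_sa_episodes",
]
_FLOAT_COLUMNS = ["age", "work_hours"]


@dataclass(frozen=True, order=True)
class Episode:
    """One recorded sickness-absence episode, inclusive of both endpoints."""

    start: dt.date
    end: dt.date
    worker_id: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"episode end {self.end} precedes start {self.start}"
            )

    @property
    def days(self) -> int:
        """Inclusive calendar-day count, start through end."""
        return (self.end - self.start).days + 1

    def clipped(self, window: tuple[dt.date, dt.date]) -> "Episode | None":
        lo, hi = window
        s, e = max(self.start, lo), min(self.end, hi)
        if e < s:
            return None
        return Episode(s, e, self.worker_id)


@dataclass(frozen=True)
class EpisodeRegister:
    """Dated SA episodes with the observation window they were drawn from."""

    episodes: tuple[Episode, ...]
    period: tuple[dt.date, dt.date]

    def __post_init__(self) -> None:
        lo, hi = self.period
        if hi < lo:
            raise ValidationError("register period end precedes start")
        for ep in self.episodes:
            if ep.end < lo or ep.start > hi:
                raise ValidationError(
                    f"episode {ep.start}..{ep.end} of worker "
                    f"{ep.worker_id!r} does not intersect the register period"
                )

    def by_worker(self) -> Mapping[str, list[Episode]]:
        out: dict[str, list[Episode]] = {}
        for ep in self.episodes:
            out.setdefault(ep.worker_id, []).append(ep)
        return out


@dataclass(frozen=True)
class WorkerRecord:
    """One worker's baseline predictors and follow-up outcomes.

    Any field other than ``worker_id`` may be ``None`` (missing).  SRH is coded
    poor=1 .. excellent=4; fatigue is the CIS sum score (20-140, higher = more
    fatigued); prior SA aggregates cover the 2 years before baseline and
    follow-up aggregates the year after.
    """

    worker_id: str
    age: float | None = None
    gender: str | None = None  # "M" / "F"
    work_hours: float | None = None
    srh: int | None = None
    prior_sa_days: int | None = None
    prior_sa_episodes: int | None = None
    fatigue: int | None = None
    fu_sa_days: int | None = None
    fu_sa_episodes: int | None = None

    def __post_init__(self) -> None:
        if self.srh is not None and self.srh not in (1, 2, 3, 4):
            raise ValidationError(f"srh must be 1..4, got {self.srh}")
        if self.fatigue is not None and not 20 <= self.fatigue <= 140:
            raise ValidationError(f"fatigue must be in [20, 140], got {self.fatigue}")
        if self.fu_sa_days is not None and not 0 <= self.fu_sa_days <= 366:
            raise ValidationError(f"fu_sa_days must be in [0, 366], got {self.fu_sa_days}")


class Cohort:
    """A collection of :class:`WorkerRecord`, backed by a pandas DataFrame.

    The frame always carries the columns of :data:`COHORT_COLUMNS` with
    nullable integer dtype for count-valued fields, so missing values survive
    round trips through CSV.
    """

    def __init__(self, frame: pd.DataFrame, provenance: str = "") -> None:
        missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
        if missing:
            raise CohortFormatError(f"cohort frame lacks columns: {missing}")
        frame = frame[COHORT_COLUMNS].reset_index(drop=True).copy()
        if frame["worker_id"].duplicated().any():
            dupes = frame.loc[frame["worker_id"].duplicated(), "worker_id"].tolist()
            raise ValidationError(f"duplicate worker_id values: {dupes[:5]}")
        for col in _INT_COLUMNS:
            frame[col] = frame[col].astype("Int64")
        for col in _FLOAT_COLUMNS:
            frame[col] = frame[col].astype("float64")
        frame["worker_id"] = frame["worker_id"].astype(str)
        self.frame = frame
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[WorkerRecord]:
        return iter(self.records())

    def records(self) -> list[WorkerRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            kwargs = {}
            for k, v in d.items():
                if v is pd.NA or (isinstance(v, float) and np.isnan(v)):
                    kwargs[k] = None
                elif k in _INT_COLUMNS:
                    kwargs[k] = int(v)
                else:
                    kwargs[k] = v
            out.append(WorkerRecord(**kwargs))
        return out

    @classmethod
    def from_records(
        cls, records: Iterable[WorkerRecord], provenance: str = ""
    ) -> "Cohort":
        rows = [
            {c: getattr(r, c) for c in COHORT_COLUMNS} for r in records
        ]
        frame = pd.DataFrame(rows, columns=COHORT_COLUMNS)
        return cls(frame, provenance)

    def equals(self, other: "Cohort") -> bool:
        return self.frame.equals(other.frame)


def read_cohort(path: str | Path, dialect: str = "excel") -> Cohort:
    """Read a cohort CSV (see :data:`COHORT_COLUMNS` for the schema).

    Unparseable or out-of-range cells become missing values with a logged
    warning; the row count is preserved.  Missing mandatory columns raise
    :class:`CohortFormatError`; duplicated worker ids raise
    :class:`ValidationError`.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, dialect=dialect, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    missing = [c for c in COHORT_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortFormatError(
            f"cohort file {path} lacks mandatory columns: {missing}"
        )
    frame = pd.DataFrame({"worker_id": raw["worker_id"].astype(str)})
    for col in _FLOAT_COLUMNS + _INT_COLUMNS:
        vals = raw[col].replace("", None)
        parsed = pd.to_numeric(vals, errors="coerce")
        bad = parsed.isna() & vals.notna()
        if bad.any():
            logger.warning(
                "%s: %d unparseable value(s) in column %r set to missing",
                path.name, int(bad.sum()), col,
            )
        lo, hi = _RANGE_CHECKS.get(col, (None, None))
        out_of_range = pd.Series(False, index=parsed.index)
        if lo is not None:
            out_of_range |= parsed < lo
        if hi is not None:
            out_of_range |= parsed > hi
        if out_of_range.any():
            logger.warning(
                "%s: %d out-of-range value(s) in column %r set to missing",
                path.name, int(out_of_range.sum()), col,
            )
            parsed[out_of_range] = np.nan
        if col in _INT_COLUMNS:
            nonint = parsed.notna() & (parsed != np.floor(parsed))
            if nonint.any():
                logger.warning(
                    "%s: %d non-integer value(s) in column %r set to missing",
                    path.name, int(nonint.sum()), col,
                )
                parsed[nonint] = np.nan
            parsed = parsed.round().astype("Int64")
        frame[col] = parsed
    gender = raw["gender"].replace("", None)
    bad_gender = gender.notna() & ~gender.isin(["M", "F"])
    if bad_gender.any():
        logger.warning(
            "%s: %d invalid gender code(s) set to missing", path.name,
            int(bad_gender.sum()),
        )
        gender[bad_gender] = None
    frame["gender"] = gender
    return Cohort(frame, provenance=f"read from {path}")


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write the cohort in the canonical CSV dialect (empty cell = missing)."""
    cohort.frame.to_csv(path, index=False)


def read_register(
    path: str | Path, period: tuple[dt.date, dt.date] | None = None
) -> EpisodeRegister:
    """Read an episode register CSV (``worker_id,start,end``, ISO-8601 dates).

    When ``period`` is omitted it is inferred as the span of the recorded
    episodes.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str)
    needed = ["worker_id", "start", "end"]
    missing = [c for c in needed if c not in raw.columns]
    if missing:
        raise CohortFormatError(f"register file {path} lacks columns: {missing}")
    episodes = []
    for row in raw.itertuples(index=False):
        try:
            start = dt.date.fromisoformat(row.start)
            end = dt.date.fromisoformat(row.end)
        except ValueError as exc:
            raise CohortFormatError(f"bad date in register {path}: {exc}") from exc
        episodes.append(Episode(start, end, str(row.worker_id)))
    if period is None:
        if not episodes:
            raise CohortFormatError(f"empty register {path} and no period given")
        period = (min(e.start for e in episodes), max(e.end for e in episodes))
    return EpisodeRegister(tuple(episodes), period)


def write_register(register: EpisodeRegister, path: str | Path) -> None:
    rows = [
        {"worker_id": e.worker_id, "start": e.start.isoformat(), "end": e.end.isoformat()}
        for e in sorted(register.episodes, key=lambda e: (e.worker_id, e.start))
    ]
    pd.DataFrame(rows, columns=["worker_id", "start", "end"]).to_csv(path, index=False)


def merge_episodes(
    episodes: Sequence[Episode], min_gap_days: int = DEFAULT_MIN_GAP_DAYS
) -> list[Episode]:
    """Chain one worker's episodes separated by short gaps into single episodes.

    Two consecutive episodes merge when the number of calendar days strictly
    between them is ``< min_gap_days`` (the 28-day rule uses the strict
    inequality, so a gap of exactly 28 days keeps the episodes separate).
    Merging is transitive; output is sorted by start date.

    Raises :class:`ValidationError` on overlapping input episodes.
    """
    if min_gap_days < 0:
        raise ValidationError("min_gap_days must be >= 0")
    if not episodes:
        return []
    eps = sorted(episodes, key=lambda e: (e.start, e.end))
    merged = [eps[0]]
    for ep in eps[1:]:
        prev = merged[-1]
        if ep.start <= prev.end:
            raise ValidationError(
                f"overlapping episodes for worker {ep.worker_id!r}: "
                f"{prev.start}..{prev.end} and {ep.start}..{ep.end}"
            )
        gap = (ep.start - prev.end).days - 1  # days strictly between
        if gap < min_gap_days:
            merged[-1] = Episode(prev.start, max(prev.end, ep.end), prev.worker_id)
        else:
            merged.append(ep)
    return merged


def aggregate_register(
    register: EpisodeRegister, min_gap_days: int = DEFAULT_MIN_GAP_DAYS
) -> dict[str, tuple[int, int]]:
    """Per-worker ``(sa_days, sa_episodes)`` aggregates over the register window.

    Episodes are clipped to the window, then per worker: ``sa_days`` is the sum
    of inclusive day counts of the recorded (pre-merge) episodes — gap days
    between merged constituents are worked days and do not count — and
    ``sa_episodes`` is the number of episodes after merging with the
    ``min_gap_days`` rule.  Workers without episodes are absent from the
    result; callers should treat them as ``(0, 0)``.
    """
    out: dict[str, tuple[int, int]] = {}
    for worker, eps in register.by_worker().items():
        clipped = [c for c in (e.clipped(register.period) for e in eps) if c]
        if not clipped:
            continue
        days = sum(e.days for e in clipped)
        n_episodes = len(merge_episodes(clipped, min_gap_days))
        out[worker] = (days, n_episodes)
    return out


def label_high_sa_days(sa_days: int) -> bool:
    """True iff the worker accumulated >= 30 SA days in the follow-up year."""
    if sa_days < 0:
        raise ValidationError("sa_days must be >= 0")
    return sa_days >= HIGH_SA_DAYS_THRESHOLD


def label_high_sa_episodes(sa_episodes: int) -> bool:
    """True iff the worker had >= 3 SA episodes in the follow-up year."""
    if sa_episodes < 0:
        raise ValidationError("sa_episodes must be >= 0")
    return sa_episodes >= HIGH_SA_EPISODES_THRESHOLD


def complete_cases(cohort: Cohort, fields: Sequence[str] | None = None) -> Cohort:
    """Drop records missing any of the listed fields (complete-case analysis).

    ``fields`` defaults to every cohort column.  The number of removed records
    is logged at INFO, mirroring participant-flow reporting.
    """
    if fields is None:
        fields = [c for c in COHORT_COLUMNS if c != "worker_id"]
    unknown = [f for f in fields if f not in COHORT_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown fields: {unknown}")
    mask = cohort.frame[list(fields)].notna().all(axis=1)
    n_removed = int((~mask).sum())
    if n_removed == len(cohort):
        logger.warning("complete_cases removed every record (%d)", n_removed)
    else:
        logger.info(
            "complete_cases: %d of %d records removed, %d retained",
            n_removed, len(cohort), int(mask.sum()),
        )
    return Cohort(
        cohort.frame[mask],
        provenance=f"{cohort.provenance}; complete cases on {list(fields)}",
    )
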