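"""Reading, validating and normalizing behavioral event logs.

Event logs are tabular exports from event-logging software (BORIS and
compatible tools): one row per logged event with the observation time in
seconds, the subject (focal individual), the behavior label, a status flag
(``START``/``STOP`` for state events with a duration, ``POINT`` for
instantaneous events) and optionally a ``Modifier`` column holding the
recipient individual of a directed behavior and a ``Behavioral category``
column with a coarser grouping of the behavior.

The module parses CSV/XLSX logs into an :class:`EventLog`, reconstructs
:class:`BehaviorBout` intervals by pairing START/STOP rows per
(subject, behavior), and applies subject/behavior/category exclusion
filters.
"""

from __future__ import annotations

import io
import logging
from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

STATUS_START = "START"
STATUS_STOP = "STOP"
STATUS_POINT = "POINT"
_VALID_STATUS = {STATUS_START, STATUS_STOP, STATUS_POINT}

#: Category label assigned to behaviors with no known category.
NO_CATEGORY = "None"

_REQUIRED_COLUMNS = ("time", "subject", "behavior")
_CANONICAL = {
    "time": "time",
    "subject": "subject",
    "behavior": "behavior",
    "status": "status",
    "modifier": "modifier",
    "behavioral category": "category",
}


class ValidationError(ValueError):
    """Raised when an event log fails structural validation."""


@dataclass(frozen=True)
class EventRecord:
    """A single logged event row.

    ``row_index`` is the original data-row position in the source file and
    is used to break ties between records logged at the same time.
    """

    time: float
    subject: str
    behavior: str
    status: str = STATUS_POINT
    modifier: str = ""
    category: str = NO_CATEGORY
    row_index: int = 0


@dataclass
class EventLog:
    """A validated, time-sorted list of event records.

    Two logs compare equal when their records are equal; the source name is
    metadata only (the same content read from CSV and XLSX yields equal
    logs).
    """

    records: list[EventRecord]
    source_name: str = ""

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: (r.time, r.row_index))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        # Content equality: row_index is file provenance, not content (a
        # write/re-parse cycle renumbers rows of an unsorted source).
        key = lambda r: (r.time, r.subject, r.behavior, r.status, r.modifier, r.category)
        return list(map(key, self.records)) == list(map(key, other.records))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def subjects(self) -> list[str]:
        return sorted({r.subject for r in self.records})

    @property
    def behaviors(self) -> list[str]:
        return sorted({r.behavior for r in self.records})

    @property
    def categories(self) -> list[str]:
        return sorted({r.category for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        """Return the log as a DataFrame with canonical BORIS-style columns."""
        return pd.DataFrame(
            {
                "Time": [r.time for r in self.records],
                "Subject": [r.subject for r in self.records],
                "Behavior": [r.behavior for r in self.records],
                "Status": [r.status for r in self.records],
                "Modifier": [r.modifier for r in self.records],
                "Behavioral category": [r.category for r in self.records],
            }
        )


@dataclass(frozen=True)
class BehaviorBout:
    """One continuous display of a behavior by one subject.

    State events span ``[start, stop]``; point events are zero-duration
    bouts with ``start == stop``. ``recipient`` is the individual the
    behavior was directed at (from the Modifier column), if any.
    """

    subject: str
    behavior: str
    start: float
    stop: float
    category: str = NO_CATEGORY
    recipient: str = ""
    row_index: int = 0

    @property
    def duration(self) -> float:
        return self.stop - self.start


@dataclass(frozen=True)
class FilterSpec:
    """Labels to exclude from all downstream computation.

    Unknown labels are permitted and act as no-ops.
    """

    excluded_subjects: frozenset[str] = frozenset()
    excluded_behaviors: frozenset[str] = frozenset()
    excluded_categories: frozenset[str] = frozenset()

    def __init__(
        self,
        excluded_subjects: Iterable[str] = (),
        excluded_behaviors: Iterable[str] = (),
        excluded_categories: Iterable[str] = (),
    ) -> None:
        object.__setattr__(self, "excluded_subjects", frozenset(excluded_subjects))
        object.__setattr__(self, "excluded_behaviors", frozenset(excluded_behaviors))
        object.__setattr__(self, "excluded_categories", frozenset(excluded_categories))


def _read_table(source, fmt: str | None) -> tuple[pd.DataFrame, str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        name = path.name
        if fmt is None:
            fmt = "xlsx" if path.suffix.lower() in {".xlsx", ".xls"} else "csv"
        handle: object = path
    else:
        name = getattr(source, "name", "<stream>")
        if fmt is None:
            fmt = "csv"
        handle = source
    try:
        if fmt == "xlsx":
            df = pd.read_excel(handle, sheet_name=0)
        else:
            df = pd.read_csv(handle)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{name}: file is empty") from None
    return df, name


def parse_event_log(
    source,
    *,
    fmt: str | None = None,
    category_map: Mapping[str, str] | None = None,
    source_name: str | None = None,
) -> EventLog:
    """Read a CSV or XLSX event log into an :class:`EventLog`.

    Column names are matched case-insensitively after stripping whitespace;
    extra columns are ignored. ``Time``, ``Subject`` and ``Behavior`` are
    required. ``Status`` values are normalized case-insensitively to
    START/STOP/POINT; a missing or blank status means POINT. Categories are
    taken from a ``Behavioral category`` column when present, otherwise
    from ``category_map`` (behavior -> category), otherwise ``"None"``.

    Parameters
    ----------
    source
        A file path or a readable text/byte stream.
    fmt
        ``"csv"`` or ``"xlsx"``; inferred from the path suffix when omitted.
    category_map
        Optional behavior -> category mapping used when the file has no
        category column.

    Raises
    ------
    ValidationError
        On a missing required column (naming it), an unparseable or
        negative time (naming the row), an empty subject/behavior cell, an
        unknown status value, or an empty file.
    """
    df, inferred_name = _read_table(source, fmt)
    name = source_name if source_name is not None else inferred_name

    colmap: dict[str, str] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in _CANONICAL and _CANONICAL[key] not in colmap:
            colmap[_CANONICAL[key]] = col
    for required in _REQUIRED_COLUMNS:
        if required not in colmap:
            raise ValidationError(
                f"{name}: missing required column {required.capitalize()!r}"
            )
    if len(df) == 0:
        raise ValidationError(f"{name}: file contains no event rows")

    times = pd.to_numeric(df[colmap["time"]], errors="coerce")
    records: list[EventRecord] = []
    has_status = "status" in colmap
    has_modifier = "modifier" in colmap
    has_category = "category" in colmap
    for i in range(len(df)):
        # +2: header row plus 1-based numbering, matching what users see in a
        # spreadsheet.
        rowno = i + 2
        t = times.iloc[i]
        if pd.isna(t):
            raise ValidationError(
                f"{name}: unparseable time value "
                f"{df[colmap['time']].iloc[i]!r} in row {rowno}"
            )
        if t < 0:
            raise ValidationError(f"{name}: negative time in row {rowno}")
        subject = _cell(df[colmap["subject"]].iloc[i])
        behavior = _cell(df[colmap["behavior"]].iloc[i])
        if not subject:
            raise ValidationError(f"{name}: empty Subject in row {rowno}")
        if not behavior:
            raise ValidationError(f"{name}: empty Behavior in row {rowno}")
        status = _cell(df[colmap["status"]].iloc[i]).upper() if has_status else ""
        if not status:
            status = STATUS_POINT
        if status not in _VALID_STATUS:
            raise ValidationError(
                f"{name}: unknown status {status!r} in row {rowno} "
                f"(expected START, STOP or POINT)"
            )
        modifier = _cell(df[colmap["modifier"]].iloc[i]) if has_modifier else ""
        if has_category:
            category = _cell(df[colmap["category"]].iloc[i]) or NO_CATEGORY
        elif category_map is not None:
            category = category_map.get(behavior, NO_CATEGORY)
        else:
            category = NO_CATEGORY
        records.append(
            EventRecord(
                time=float(t),
                subject=subject,
                behavior=behavior,
                status=status,
                modifier=modifier,
                category=category,
                row_index=i,
            )
        )
    return EventLog(records=records, source_name=name)


def _cell(value) -> str:
    if pd.isna(value):
        return ""
    return str(value).strip()


def write_event_log(log: EventLog, target=None) -> str | None:
    """Write an event log as CSV; round-trips through :func:`parse_event_log`.

    Returns the CSV text when ``target`` is None, else writes to the given
    path or stream.
    """
    df = log.to_frame()
    if target is None:
        return df.to_csv(index=False)
    df.to_csv(target, index=False)
    return None


def reconstruct_bouts(log: EventLog) -> list[BehaviorBout]:
    """Pair START/STOP records per (subject, behavior) into bouts.

    Each START is matched with the earliest subsequent STOP of the same
    (subject, behavior); POINT events become zero-duration bouts. A bout
    carries the modifier and category of its opening record. Malformed
    logs are repaired rather than rejected: a STOP with no open START is
    dropped with a logged warning, and a START never closed is closed at
    the maximum time present in the log, also with a warning.
    """
    if not log.records:
        return []
    open_starts: dict[tuple[str, str], deque[EventRecord]] = {}
    bouts: list[BehaviorBout] = []
    for rec in log.records:
        key = (rec.subject, rec.behavior)
        if rec.status == STATUS_POINT:
            bouts.append(
                BehaviorBout(
                    subject=rec.subject,
                    behavior=rec.behavior,
                    start=rec.time,
                    stop=rec.time,
                    category=rec.category,
                    recipient=rec.modifier,
                    row_index=rec.row_index,
                )
            )
        elif rec.status == STATUS_START:
            open_starts.setdefault(key, deque()).append(rec)
        else:  # STOP
            queue = open_starts.get(key)
            if not queue:
                logger.warning(
                    "dropping STOP with no open START for subject %r, "
                    "behavior %r at t=%s",
                    rec.subject,
                    rec.behavior,
                    rec.time,
                )
                continue
            start_rec = queue.popleft()
            bouts.append(_close(start_rec, rec.time))
    max_time = max(r.time for r in log.records)
    for queue in open_starts.values():
        for start_rec in queue:
            logger.warning(
                "START never closed for subject %r, behavior %r at t=%s; "
                "closing at log end t=%s",
                start_rec.subject,
                start_rec.behavior,
                start_rec.time,
                max_time,
            )
            bouts.append(_close(start_rec, max_time))
    bouts.sort(key=lambda b: (b.start, b.row_index))
    return bouts


def _close(start_rec: EventRecord, stop_time: float) -> BehaviorBout:
    return BehaviorBout(
        subject=start_rec.subject,
        behavior=start_rec.behavior,
        start=start_rec.time,
        stop=stop_time,
        category=start_rec.category,
        recipient=start_rec.modifier,
        row_index=start_rec.row_index,
    )


def filter_bouts(bouts: Sequence[BehaviorBout], spec: FilterSpec) -> list[BehaviorBout]:
    """Drop bouts whose subject, behavior or category is excluded.

    Order is preserved; unknown labels in the spec are no-ops. The
    operation is idempotent and the three exclusion axes commute.
    """
    return [
        b
        for b in bouts
        if b.subject not in spec.excluded_subjects
        and b.behavior not in spec.excluded_behaviors
        and b.category not in spec.excluded_categories
    ]
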