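"""Basic clinical event model: coded events, patient timelines, and the
current-position pointer.

Every piece of EHR data is decomposed into an :class:`Event` — one coded
observation with a timestamp and optional value fields.  Events for one
patient are held in a :class:`PatientTimeline`, sorted chronologically, and
scenario execution walks the timeline through a *current position pointer*
that behaves like a reader's finger in a paper chart: searches scan forward
from it, and jump operations reposition it.
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field, replace
from datetime import datetime
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, TextIO, Union

from dateutil.relativedelta import relativedelta

__all__ = [
    "Coded",
    "Event",
    "Position",
    "PositionKind",
    "PatientTimeline",
    "EventDialect",
    "ReadResult",
    "RowError",
    "SchemaError",
    "read_events",
    "write_events",
    "build_timelines",
    "jump_to_last_ehr_event",
    "jump_forward_months",
    "parse_timestamp",
]


class SchemaError(ValueError):
    """Raised when an event file is missing a required column."""


@dataclass(frozen=True)
class Coded:
    """A code/description pair; at least one side is present."""

    code: Optional[str] = None
    desc: Optional[str] = None

    def __post_init__(self) -> None:
        if self.code is None and self.desc is None:
            raise ValueError("Coded needs a code or a description")

    def matches(self, query: str) -> bool:
        """True if *query* equals the code, or the description when no code
        is recorded.  Codes take precedence so that a descriptive label can
        never shadow a differing code."""
        if self.code is not None:
            return self.code == query or (self.desc is not None and self.desc == query)
        return self.desc == query


def parse_timestamp(text: str) -> datetime:
    """Parse ``YYYY-MM-DD[ HH:MM:SS[.f]]``; a bare date gets time 00:00:00."""
    text = text.strip()
    if not text:
        raise ValueError("empty timestamp")
    return datetime.fromisoformat(text)


@dataclass(frozen=True)
class Event:
    """One coded clinical observation.

    Only ``patient_id``, ``ev_time`` and ``event_type`` are mandatory; every
    other field may be absent (stored as ``None``, never as an empty-string
    code).  ``sequence_id`` breaks ties between events sharing a timestamp.
    """

    patient_id: str
    ev_time: datetime
    event_type: Coded
    event_subtype: Optional[Coded] = None
    observation: Optional[Coded] = None
    coded_value: Optional[Coded] = None
    flag: Optional[Coded] = None
    value_num: Optional[float] = None
    value_text: Optional[str] = None
    terminology2: Optional[Coded] = None
    sequence_id: int = 0

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.sequence_id < 0:
            raise ValueError("sequence_id must be non-negative")

    @property
    def sort_key(self) -> tuple:
        return (self.ev_time, self.sequence_id)


class PositionKind(str, Enum):
    BEFORE_FIRST = "BEFORE_FIRST"
    AT_EVENT = "AT_EVENT"
    AT_TIME = "AT_TIME"
    AFTER_LAST = "AFTER_LAST"


@dataclass(frozen=True)
class Position:
    """The engine's temporal cursor in a patient record."""

    kind: PositionKind
    index: Optional[int] = None
    time: Optional[datetime] = None

    @staticmethod
    def before_first() -> "Position":
        return Position(PositionKind.BEFORE_FIRST)

    @staticmethod
    def after_last() -> "Position":
        return Position(PositionKind.AFTER_LAST)

    @staticmethod
    def at_event(index: int) -> "Position":
        return Position(PositionKind.AT_EVENT, index=index)

    @staticmethod
    def at_time(time: datetime) -> "Position":
        return Position(PositionKind.AT_TIME, time=time)


@dataclass
class PatientTimeline:
    """Chronologically ordered events for one patient plus the pointer.

    The pointer starts ``BEFORE_FIRST`` so that the first search scans the
    entire record, first event included.
    """

    patient_id: str
    events: tuple[Event, ...] = ()
    pointer: Position = field(default_factory=Position.before_first)

    def __post_init__(self) -> None:
        keys = [e.sort_key for e in self.events]
        if any(a > b for a, b in zip(keys, keys[1:])):
            raise ValueError("events must be non-decreasing by (ev_time, sequence_id)")
        if self.pointer.kind is PositionKind.AT_EVENT and not (
            0 <= (self.pointer.index or 0) < len(self.events)
        ):
            raise ValueError("pointer index out of bounds")

    def __len__(self) -> int:
        return len(self.events)

    def effective_time(self) -> Optional[datetime]:
        """Time the pointer currently stands at.

        ``BEFORE_FIRST`` resolves to the first event's time (the record's
        start), ``AFTER_LAST`` to the last event's time; ``None`` on an
        empty record.
        """
        p = self.pointer
        if p.kind is PositionKind.AT_TIME:
            return p.time
        if not self.events:
            return None
        if p.kind is PositionKind.BEFORE_FIRST:
            return self.events[0].ev_time
        if p.kind is PositionKind.AFTER_LAST:
            return self.events[-1].ev_time
        return self.events[p.index].ev_time

    def searchable_indices(self) -> range:
        """Indices a strict forward search may inspect: strictly after an
        ``AT_EVENT`` anchor, everything from ``BEFORE_FIRST``, events at or
        after an ``AT_TIME`` jump target, nothing after ``AFTER_LAST``."""
        p = self.pointer
        n = len(self.events)
        if p.kind is PositionKind.BEFORE_FIRST:
            return range(0, n)
        if p.kind is PositionKind.AFTER_LAST:
            return range(n, n)
        if p.kind is PositionKind.AT_EVENT:
            return range(p.index + 1, n)
        lo = 0
        while lo < n and self.events[lo].ev_time < p.time:
            lo += 1
        return range(lo, n)

    def with_pointer(self, pointer: Position) -> "PatientTimeline":
        return replace(self, pointer=pointer)


# ---------------------------------------------------------------------------
# Delimited-text I/O

#: Default column names, following the printed event-schema layout: each coded
#: field has a ``*_cd`` code column and a ``*_desc`` description column.
DEFAULT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "ev_time",
    "evtype_cd",
    "evtype_desc",
    "evsbtype_cd",
    "evsbtype_desc",
    "obs_cd",
    "obs_desc",
    "cd_val_cd",
    "cd_val_desc",
    "flg_cd",
    "flg_desc",
    "val_num",
    "val_text",
    "term2_cd",
    "term2_desc",
    "sequence_id",
)

#: field name -> (code column, desc column) under the default naming
_CODED_FIELDS: dict[str, tuple[str, str]] = {
    "event_type": ("evtype_cd", "evtype_desc"),
    "event_subtype": ("evsbtype_cd", "evsbtype_desc"),
    "observation": ("obs_cd", "obs_desc"),
    "coded_value": ("cd_val_cd", "cd_val_desc"),
    "flag": ("flg_cd", "flg_desc"),
    "terminology2": ("term2_cd", "term2_desc"),
}


@dataclass(frozen=True)
class EventDialect:
    """Column-mapping configuration for event files.

    ``column_map`` maps *file* header names onto the default names above, so
    foreign schemas (e.g. an observation-fact style table) can be ingested by
    remapping alone.  ``delimiter`` of ``None`` sniffs comma vs tab from the
    header line.
    """

    delimiter: Optional[str] = None
    column_map: Mapping[str, str] = field(default_factory=dict)

    def canonical(self, name: str) -> str:
        return self.column_map.get(name, name)


@dataclass(frozen=True)
class RowError:
    line: int  # 1-based physical line number, header = line 1
    message: str


@dataclass
class ReadResult:
    events: list[Event]
    errors: list[RowError]


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if header_line.count("\t") >= header_line.count(",") else ","


def read_events(
    source: Union[str, TextIO], dialect: Optional[EventDialect] = None
) -> ReadResult:
    """Read events from delimited text (path or open stream).

    Rows that fail to parse are collected as :class:`RowError` with their
    line number; they are never silently dropped.  A missing ``patient_id``,
    ``ev_time`` or event-type column raises :class:`SchemaError`.
    """
    dialect = dialect or EventDialect()
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8", newline="") as fh:
            return read_events(fh, dialect)

    first = source.readline()
    if not first:
        raise SchemaError("empty file: no header row")
    delim = dialect.delimiter or _sniff_delimiter(first)
    header = [dialect.canonical(h.strip()) for h in next(csv.reader([first], delimiter=delim))]
    required = {"patient_id", "ev_time"}
    missing = required - set(header)
    if "evtype_cd" not in header and "evtype_desc" not in header:
        missing.add("evtype_cd/evtype_desc")
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(sorted(missing))}")

    col = {name: i for i, name in enumerate(header)}

    def cell(row: Sequence[str], name: str) -> Optional[str]:
        i = col.get(name)
        if i is None or i >= len(row):
            return None
        v = row[i].strip()
        return v or None

    events: list[Event] = []
    errors: list[RowError] = []
    for lineno, row in enumerate(csv.reader(source, delimiter=delim), start=2):
        if not row or all(not c.strip() for c in row):
            continue
        try:
            coded: dict[str, Optional[Coded]] = {}
            for fname, (ccol, dcol) in _CODED_FIELDS.items():
                c, d = cell(row, ccol), cell(row, dcol)
                coded[fname] = Coded(c, d) if (c is not None or d is not None) else None
            if coded["event_type"] is None:
                raise ValueError("event_type missing")
            pid = cell(row, "patient_id")
            if pid is None:
                raise ValueError("patient_id missing")
            vn = cell(row, "val_num")
            seq = cell(row, "sequence_id")
            events.append(
                Event(
                    patient_id=pid,
                    ev_time=parse_timestamp(cell(row, "ev_time") or ""),
                    event_type=coded["event_type"],
                    event_subtype=coded["event_subtype"],
                    observation=coded["observation"],
                    coded_value=coded["coded_value"],
                    flag=coded["flag"],
                    value_num=float(vn) if vn is not None else None,
                    value_text=cell(row, "val_text"),
                    terminology2=coded["terminology2"],
                    sequence_id=int(seq) if seq is not None else 0,
                )
            )
        except (ValueError, TypeError) as exc:
            errors.append(RowError(lineno, str(exc)))
    return ReadResult(events, errors)


def _fmt_time(t: datetime) -> str:
    # matches the printed chart layout: fractional second kept to one digit
    return t.strftime("%Y-%m-%d %H:%M:%S.") + f"{t.microsecond // 100000}"


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def write_events(
    events: Iterable[Event], dest: Union[str, TextIO], delimiter: str = ","
) -> None:
    """Write events as delimited text in the default column order.

    Output is bit-stable for a fixed event sequence, so read/write round
    trips are exact on the event field set.
    """
    if isinstance(dest, str):
        with open(dest, "w", encoding="utf-8", newline="") as fh:
            write_events(events, fh, delimiter)
            return
    w = csv.writer(dest, delimiter=delimiter, lineterminator="\n")
    w.writerow(DEFAULT_COLUMNS)
    for e in events:
        row: dict[str, str] = {
            "patient_id": e.patient_id,
            "ev_time": _fmt_time(e.ev_time),
            "val_num": _fmt_num(e.value_num) if e.value_num is not None else "",
            "val_text": e.value_text or "",
            "sequence_id": str(e.sequence_id),
        }
        for fname, (ccol, dcol) in _CODED_FIELDS.items():
            cv: Optional[Coded] = getattr(e, fname)
            row[ccol] = (cv.code or "") if cv else ""
            row[dcol] = (cv.desc or "") if cv else ""
        w.writerow([row[c] for c in DEFAULT_COLUMNS])


def events_to_text(events: Iterable[Event], delimiter: str = ",") -> str:
    buf = io.StringIO()
    write_events(events, buf, delimiter)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Timelines and pointer operations


def build_timelines(events: Iterable[Event]) -> dict[str, PatientTimeline]:
    """Group events per patient and sort by (ev_time, sequence_id).

    The sort is stable, so events sharing both keys keep input order.  Every
    pointer starts ``BEFORE_FIRST``.
    """
    per: dict[str, list[Event]] = {}
    for e in events:
        per.setdefault(e.patient_id, []).append(e)
    return {
        pid: PatientTimeline(pid, tuple(sorted(evs, key=lambda e: e.sort_key)))
        for pid, evs in per.items()
    }


def jump_to_last_ehr_event(timeline: PatientTimeline) -> Position:
    """Move the pointer onto the final event of the record."""
    if not timeline.events:
        warnings.warn(f"patient {timeline.patient_id}: record is empty", stacklevel=2)
        pos = Position.after_last()
    else:
        pos = Position.at_event(len(timeline.events) - 1)
    timeline.pointer = pos
    return pos


def jump_forward_months(timeline: PatientTimeline, n: int) -> Position:
    """Advance the pointer by *n* calendar months (day clamped to month
    length, e.g. Jan 31 + 1 month = Feb 28)."""
    if n <= 0:
        raise ValueError("n must be a positive number of months")
    anchor = timeline.effective_time()
    if anchor is None:
        raise ValueError(f"patient {timeline.patient_id}: empty record has no pointer time")
    pos = Position.at_time(anchor + relativedelta(months=n))
    timeline.pointer = pos
    return pos
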