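"""Reading, validating and writing the pipeline's CSV formats.

All timestamps are ISO-8601 local clock at minute resolution; a 24-h
recording is treated as a monotone clock (no daylight-saving arithmetic).
Pressures and heart rates are stored as floats but written back without
trailing zeros, so integer-valued device exports round-trip bit-exactly.

Formats
-------
trace CSV      : subject_id,timestamp,sbp_mmHg,dbp_mmHg,hr_bpm
journal CSV    : subject_id,event,timestamp        (event in {sleep,wake,meal,symptom})
office CSV     : subject_id,posture,minutes_after_standing,sbp_mmHg,dbp_mmHg,hr_bpm
cass CSV       : subject_id,sudomotor,cardiovagal,adrenergic
covariates CSV : subject_id,age,sex,htn,dm,cad,lipid,cancer,neuro,stroke
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import (
    DegenerateTraceError,
    FormatError,
    RowError,
    ValidationError,
)

JOURNAL_KINDS = frozenset({"sleep", "wake", "meal", "symptom"})
POSTURES = frozenset({"supine", "sitting", "standing"})

TRACE_COLUMNS = ["subject_id", "timestamp", "sbp_mmHg", "dbp_mmHg", "hr_bpm"]
JOURNAL_COLUMNS = ["subject_id", "event", "timestamp"]
OFFICE_COLUMNS = [
    "subject_id", "posture", "minutes_after_standing", "sbp_mmHg", "dbp_mmHg", "hr_bpm",
]
CASS_COLUMNS = ["subject_id", "sudomotor", "cardiovagal", "adrenergic"]
COVARIATE_COLUMNS = [
    "subject_id", "age", "sex", "htn", "dm", "cad", "lipid", "cancer", "neuro", "stroke",
]
COVARIATE_FLAGS = ["htn", "dm", "cad", "lipid", "cancer", "neuro", "stroke"]

MAX_TRACE_SPAN = timedelta(hours=30)


@dataclass(frozen=True)
class BPReading:
    """One cuff measurement: systolic/diastolic pressure (mmHg) and heart rate (bpm)."""

    time: datetime
    sbp: float
    dbp: float
    hr: float


@dataclass(frozen=True)
class ABPTrace:
    """Ordered 24-h ambulatory recording for one subject."""

    subject_id: str
    readings: tuple[BPReading, ...]

    def __post_init__(self):
        times = [r.time for r in self.readings]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"trace {self.subject_id}: readings not strictly increasing in time"
            )
        if times and times[-1] - times[0] > MAX_TRACE_SPAN:
            raise ValidationError(
                f"trace {self.subject_id}: span exceeds {MAX_TRACE_SPAN}"
            )

    def __len__(self) -> int:
        return len(self.readings)

    @property
    def start(self) -> datetime:
        return self.readings[0].time

    @property
    def end(self) -> datetime:
        return self.readings[-1].time


@dataclass(frozen=True)
class JournalEvent:
    """A patient-journal entry: sleep, wake, meal or symptom at a clock time."""

    subject_id: str
    kind: str
    time: datetime

    def __post_init__(self):
        if self.kind not in JOURNAL_KINDS:
            raise ValidationError(
                f"unknown journal event kind {self.kind!r} for {self.subject_id}"
            )


@dataclass(frozen=True)
class OfficeBPRecord:
    """One office BP measurement in a stated posture.

    ``minutes_after_standing`` is present only for standing readings; standing
    readings used for orthostatic-hypotension classification must be taken
    within 3 min of standing.
    """

    subject_id: str
    posture: str
    sbp: float
    dbp: float
    minutes_after_standing: Optional[float] = None
    hr: Optional[float] = None

    def __post_init__(self):
        if self.posture not in POSTURES:
            raise ValidationError(f"unknown posture {self.posture!r}")
        if self.minutes_after_standing is not None and self.minutes_after_standing < 0:
            raise ValidationError("minutes_after_standing must be >= 0")


@dataclass(frozen=True)
class PlausibilityBounds:
    """Physiological plausibility windows used to reject cuff artifacts."""

    sbp: tuple[float, float] = (60.0, 260.0)
    dbp: tuple[float, float] = (30.0, 150.0)
    hr: tuple[float, float] = (25.0, 220.0)


@dataclass(frozen=True)
class Rejection:
    """One reading removed by the plausibility filter, with its reason."""

    subject_id: str
    time: datetime
    reason: str


@dataclass
class FilterResult:
    trace: ABPTrace
    rejections: list[Rejection] = field(default_factory=list)


def _parse_timestamp(raw: str, line_no: int) -> datetime:
    try:
        ts = datetime.fromisoformat(raw.strip())
    except (ValueError, AttributeError) as exc:
        raise RowError(f"unparseable timestamp {raw!r}", line_no) from exc
    return ts.replace(second=0, microsecond=0)


def _parse_number(raw: str, column: str, line_no: int) -> float:
    try:
        return float(raw)
    except (TypeError, ValueError) as exc:
        raise RowError(f"non-numeric {column} value {raw!r}", line_no) from exc


def _open_rows(path, expected: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        missing = [c for c in expected if c not in header]
        if missing:
            raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
        idx = {c: header.index(c) for c in expected}
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            yield line_no, {c: row[idx[c]] if idx[c] < len(row) else "" for c in expected}


def read_trace_csv(path) -> list[ABPTrace]:
    """Parse a trace CSV into one time-sorted :class:`ABPTrace` per subject.

    Duplicate timestamps within a subject are collapsed to the last
    occurrence with a warning.  Unparseable rows raise :class:`RowError`
    with the file line number.
    """
    per_subject: dict[str, dict[datetime, BPReading]] = {}
    for line_no, row in _open_rows(path, TRACE_COLUMNS):
        sid = row["subject_id"].strip()
        ts = _parse_timestamp(row["timestamp"], line_no)
        reading = BPReading(
            time=ts,
            sbp=_parse_number(row["sbp_mmHg"], "sbp_mmHg", line_no),
            dbp=_parse_number(row["dbp_mmHg"], "dbp_mmHg", line_no),
            hr=_parse_number(row["hr_bpm"], "hr_bpm", line_no),
        )
        bucket = per_subject.setdefault(sid, {})
        if ts in bucket:
            warnings.warn(
                f"{sid}: duplicate timestamp {ts.isoformat()} at line {line_no};"
                " keeping last occurrence",
                stacklevel=2,
            )
        bucket[ts] = reading
    return [
        ABPTrace(sid, tuple(readings[t] for t in sorted(readings)))
        for sid, readings in per_subject.items()
    ]


def filter_plausible(
    trace: ABPTrace,
    bounds: PlausibilityBounds = PlausibilityBounds(),
    min_readings: int = 10,
) -> FilterResult:
    """Remove physiologically implausible readings, keeping order.

    A reading is rejected when SBP, DBP or HR fall outside their plausibility
    window or when DBP >= SBP.  Raises :class:`DegenerateTraceError` when
    fewer than ``min_readings`` readings survive.
    """
    kept: list[BPReading] = []
    rejections: list[Rejection] = []

    def reject(r: BPReading, reason: str):
        rejections.append(Rejection(trace.subject_id, r.time, reason))

    for r in trace.readings:
        if not bounds.sbp[0] <= r.sbp <= bounds.sbp[1]:
            reject(r, "sbp out of range")
        elif not bounds.dbp[0] <= r.dbp <= bounds.dbp[1]:
            reject(r, "dbp out of range")
        elif not bounds.hr[0] <= r.hr <= bounds.hr[1]:
            reject(r, "hr out of range")
        elif r.dbp >= r.sbp:
            reject(r, "dbp >= sbp")
        else:
            kept.append(r)
    if len(kept) < min_readings:
        raise DegenerateTraceError(
            f"trace {trace.subject_id}: only {len(kept)} plausible readings"
            f" (need >= {min_readings})"
        )
    return FilterResult(ABPTrace(trace.subject_id, tuple(kept)), rejections)


def read_journal_csv(path) -> list[JournalEvent]:
    """Parse journal events; unknown event kinds are rejected."""
    events = []
    for line_no, row in _open_rows(path, JOURNAL_COLUMNS):
        kind = row["event"].strip()
        if kind not in JOURNAL_KINDS:
            raise RowError(f"unknown event kind {kind!r}", line_no)
        events.append(
            JournalEvent(
                subject_id=row["subject_id"].strip(),
                kind=kind,
                time=_parse_timestamp(row["timestamp"], line_no),
            )
        )
    return events


def read_office_csv(path) -> list[OfficeBPRecord]:
    """Parse office supine/sitting/standing BP readings."""
    records = []
    for line_no, row in _open_rows(path, OFFICE_COLUMNS):
        posture = row["posture"].strip()
        if posture not in POSTURES:
            raise RowError(f"unknown posture {posture!r}", line_no)
        mas_raw = row["minutes_after_standing"].strip()
        mas = _parse_number(mas_raw, "minutes_after_standing", line_no) if mas_raw else None
        if posture == "standing" and mas is None:
            raise RowError("standing reading lacks minutes_after_standing", line_no)
        hr_raw = row["hr_bpm"].strip()
        records.append(
            OfficeBPRecord(
                subject_id=row["subject_id"].strip(),
                posture=posture,
                minutes_after_standing=mas,
                sbp=_parse_number(row["sbp_mmHg"], "sbp_mmHg", line_no),
                dbp=_parse_number(row["dbp_mmHg"], "dbp_mmHg", line_no),
                hr=_parse_number(hr_raw, "hr_bpm", line_no) if hr_raw else None,
            )
        )
    return records


CASS_RANGES = {"sudomotor": 3, "cardiovagal": 3, "adrenergic": 4}


def read_cass_csv(path) -> pd.DataFrame:
    """Parse CASS subscores, validating each against its subscale maximum."""
    rows = []
    for line_no, row in _open_rows(path, CASS_COLUMNS):
        sid = row["subject_id"].strip()
        parsed = {"subject_id": sid}
        for col, cap in CASS_RANGES.items():
            val = _parse_number(row[col], col, line_no)
            if val != int(val) or not 0 <= val <= cap:
                raise ValidationError(
                    f"subject {sid}: {col} subscore {row[col]} outside 0..{cap}"
                )
            parsed[col] = int(val)
        rows.append(parsed)
    return pd.DataFrame(rows, columns=CASS_COLUMNS)


def read_covariates_csv(path) -> pd.DataFrame:
    """Parse the cohort covariate table; comorbidity flags must be 0/1."""
    rows = []
    for line_no, row in _open_rows(path, COVARIATE_COLUMNS):
        sid = row["subject_id"].strip()
        parsed = {"subject_id": sid, "sex": row["sex"].strip()}
        parsed["age"] = _parse_number(row["age"], "age", line_no)
        for col in COVARIATE_FLAGS:
            val = _parse_number(row[col], col, line_no)
            if val not in (0.0, 1.0):
                raise ValidationError(f"subject {sid}: flag {col}={row[col]} is not binary")
            parsed[col] = int(val)
        rows.append(parsed)
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


def _fmt_num(v) -> str:
    if v is None:
        return ""
    f = float(v)
    return str(int(f)) if f == int(f) else repr(f)


def _fmt_time(t: datetime) -> str:
    return t.strftime("%Y-%m-%dT%H:%M")


def write_trace_csv(traces: Iterable[ABPTrace], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(TRACE_COLUMNS)
        for trace in traces:
            for r in trace.readings:
                w.writerow(
                    [trace.subject_id, _fmt_time(r.time), _fmt_num(r.sbp),
                     _fmt_num(r.dbp), _fmt_num(r.hr)]
                )


def write_journal_csv(events: Iterable[JournalEvent], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(JOURNAL_COLUMNS)
        for e in events:
            w.writerow([e.subject_id, e.kind, _fmt_time(e.time)])


def write_office_csv(records: Iterable[OfficeBPRecord], path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(OFFICE_COLUMNS)
        for r in records:
            w.writerow(
                [r.subject_id, r.posture, _fmt_num(r.minutes_after_standing),
                 _fmt_num(r.sbp), _fmt_num(r.dbp), _fmt_num(r.hr)]
            )
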