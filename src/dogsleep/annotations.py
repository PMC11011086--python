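"""Human behavioural-observation event logs (BORIS-style CSV export).

Ethologists score sleep by focal sampling with continuous recording: every
behaviour transition is timestamped, producing an event log of START/STOP
rows per subject and behaviour label. This module converts such logs into
the same :class:`~dogsleep.sleep_state.StateSequence` container the
automated pipeline produces, so human and system scoring are compared
through one code path, and writes logs back out for round-tripping
synthetic observer output.

The dialect is the minimal aggregated-export column set — Time, Subject,
Behavior, Status — with configurable column names. Times are seconds from
session start; logs using absolute clock time must be normalised first.
Which behaviour labels count as sleep is configurable; the default accepts
"sleep" and "rest" (a resting posture with no perceivable movement is the
standard video operationalisation of behavioural sleep).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set

from .sleep_state import Bout, State, StateSequence, extract_bouts

__all__ = [
    "ObservationEvent",
    "LogDialect",
    "read_observation_log",
    "write_observation_log",
    "DEFAULT_SLEEP_LABELS",
]

DEFAULT_SLEEP_LABELS = frozenset({"sleep", "rest"})


@dataclass(frozen=True)
class ObservationEvent:
    """One timestamped row of a behavioural event log."""

    time: float
    subject: str
    behaviour: str
    marker: str  # START | STOP | POINT

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.marker not in ("START", "STOP", "POINT"):
            raise ValueError(f"marker must be START/STOP/POINT, got {self.marker!r}")


@dataclass(frozen=True)
class LogDialect:
    """Column names of the event-log CSV."""

    time: str = "Time"
    subject: str = "Subject"
    behaviour: str = "Behavior"
    status: str = "Status"


def read_observation_log(
    path,
    session_duration: float,
    fps: float,
    sleep_labels: Iterable[str] = DEFAULT_SLEEP_LABELS,
    dialect: LogDialect = LogDialect(),
) -> Dict[str, StateSequence]:
    """Read an event log into one StateSequence per subject.

    Time between a matched START/STOP of any sleep label is ASLEEP; all
    other time is AWAKE (continuous focal observation leaves no unknown
    time). The sequence is discretised at ``fps``: frame ``i`` is asleep
    when its start time ``i/fps`` falls inside a sleep interval, with
    interval endpoints snapped to the frame grid by rounding.

    Raises
    ------
    ValueError
        STOP without a prior START, overlapping STARTs for the same
        subject and label, or an event beyond ``session_duration`` — each
        reported with the offending CSV line number.
    """
    if session_duration <= 0:
        raise ValueError("session_duration must be > 0")
    sleep_labels = {s.lower() for s in sleep_labels}
    n_frames = round(session_duration * fps)

    # (subject, label) -> (start time, line number) for open intervals
    open_intervals: Dict[tuple, tuple] = {}
    intervals: Dict[str, List[tuple]] = {}
    subjects: Set[str] = set()

    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {dialect.time, dialect.subject, dialect.behaviour, dialect.status}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ValueError(f"event log {path} lacks required columns: {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):  # header is line 1
            t = float(row[dialect.time])
            subject = row[dialect.subject]
            label = row[dialect.behaviour].lower()
            marker = row[dialect.status].upper()
            subjects.add(subject)
            if t > session_duration:
                raise ValueError(
                    f"line {lineno}: event time {t} exceeds session duration {session_duration}"
                )
            if label not in sleep_labels or marker == "POINT":
                continue
            key = (subject, label)
            if marker == "START":
                if key in open_intervals:
                    raise ValueError(
                        f"line {lineno}: overlapping START for subject {subject!r} "
                        f"label {label!r} (previous START at line {open_intervals[key][1]})"
                    )
                open_intervals[key] = (t, lineno)
            elif marker == "STOP":
                if key not in open_intervals:
                    raise ValueError(
                        f"line {lineno}: STOP without prior START for subject "
                        f"{subject!r} label {label!r}"
                    )
                start, _ = open_intervals.pop(key)
                intervals.setdefault(subject, []).append((start, t))
            else:
                raise ValueError(f"line {lineno}: unrecognised status {marker!r}")

    if open_intervals:
        (subject, label), (start, lineno) = next(iter(open_intervals.items()))
        raise ValueError(
            f"line {lineno}: START for subject {subject!r} label {label!r} "
            "never closed by a STOP"
        )

    out: Dict[str, StateSequence] = {}
    for subject in sorted(subjects) or [""]:
        states = [State.AWAKE] * n_frames
        for start, stop in intervals.get(subject, []):
            a = max(0, round(start * fps))
            b = min(n_frames, round(stop * fps))
            for i in range(a, b):
                states[i] = State.ASLEEP
        out[subject] = StateSequence(subject_id=subject, fps=fps, states=states)
    return out


def write_observation_log(
    seq: StateSequence,
    path,
    sleep_label: str = "sleep",
    dialect: LogDialect = LogDialect(),
) -> None:
    """Write a StateSequence as START/STOP event rows, one pair per bout.

    Reading the file back with :func:`read_observation_log` (same fps and
    duration) reproduces the sequence's bouts and total sleep exactly.
    """
    bouts = extract_bouts(seq)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([dialect.time, dialect.subject, dialect.behaviour, dialect.status])
        subject = "" if seq.subject_id is None else str(seq.subject_id)
        for b in bouts:
            w.writerow([repr(b.start), subject, sleep_label, "START"])
            w.writerow([repr(b.end), subject, sleep_label, "STOP"])
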