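"""Asleep/awake state sequences, sleeping bouts, and session summaries.

A subject's per-frame motion measurements are turned into a per-frame
behavioural state (ASLEEP, AWAKE, or UNKNOWN when the subject was not
detected) by a sliding-window rule: a dog is scored asleep at a frame when
the recent window of frames contains at most a tolerated number of
movement flags. From the state sequence, sleeping bouts — maximal episodes
of sleep delimited by wakefulness — are extracted, and the session is
summarised as total sleep seconds, bout count, and percent of known time
spent asleep. Bout count per session is the standard operationalisation of
sleep fragmentation.

The same :class:`StateSequence` container is produced by the human
annotation reader (:mod:`dogsleep.annotations`), so system and observer
outputs flow through one comparison path.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .motion import MotionMeasurement

__all__ = [
    "State",
    "StateSequence",
    "Bout",
    "SleepSummary",
    "StateParams",
    "classify_states",
    "extract_bouts",
    "summarize",
    "format_hms",
]


class State(enum.Enum):
    ASLEEP = "asleep"
    AWAKE = "awake"
    UNKNOWN = "unknown"


@dataclass
class StateSequence:
    """Per-frame behavioural states for one subject at a fixed frame rate."""

    subject_id: object
    fps: float
    states: List[State]

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        bad = [s for s in self.states if not isinstance(s, State)]
        if bad:
            raise ValueError(f"invalid state values: {bad[:3]}")

    def __len__(self) -> int:
        return len(self.states)

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return len(self.states) / self.fps

    def as_array(self) -> np.ndarray:
        """States as a small-int array (0 asleep, 1 awake, 2 unknown)."""
        code = {State.ASLEEP: 0, State.AWAKE: 1, State.UNKNOWN: 2}
        return np.array([code[s] for s in self.states], dtype=np.int8)


@dataclass(frozen=True)
class Bout:
    """One maximal sleeping episode, in seconds from session start."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bout must satisfy 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SleepSummary:
    """Per-session sleep metrics for one subject.

    ``percent_asleep`` is relative to known (non-UNKNOWN) time and is
    ``None`` when the whole session is unknown.
    """

    subject_id: object
    total_sleep_s: float
    total_awake_s: float
    total_unknown_s: float
    observed_s: float
    bout_count: int
    percent_asleep: Optional[float]

    def to_dict(self) -> Dict[str, object]:
        return {
            "subject_id": self.subject_id,
            "total_sleep_s": self.total_sleep_s,
            "total_awake_s": self.total_awake_s,
            "total_unknown_s": self.total_unknown_s,
            "observed_s": self.observed_s,
            "bout_count": self.bout_count,
            "percent_asleep": self.percent_asleep,
            "total_sleep_hms": format_hms(self.total_sleep_s),
        }


@dataclass(frozen=True)
class StateParams:
    """Sliding-window classification parameters.

    ``window`` frames ending at the current frame are examined; the frame
    is scored ASLEEP when at most ``max_awake_frames_in_window`` of them
    carry a movement flag. A window of roughly 3 seconds of frames with
    zero tolerance suppresses single-frame noise while still catching the
    brief arousals that delimit bouts.
    """

    window: int = 15
    max_awake_frames_in_window: int = 0

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not 0 <= self.max_awake_frames_in_window < self.window:
            raise ValueError("max_awake_frames_in_window must be in [0, window)")

    @classmethod
    def for_fps(cls, fps: float, window_seconds: float = 3.0,
                max_awake_frames_in_window: int = 0) -> "StateParams":
        """Window sized to ``window_seconds`` at the given frame rate."""
        return cls(max(1, round(window_seconds * fps)), max_awake_frames_in_window)


def classify_states(
    measurements: Sequence[MotionMeasurement],
    params: StateParams,
    n_frames: int,
    fps: float,
    subject_id: object = None,
) -> StateSequence:
    """Convert one subject's motion measurements into per-frame states.

    Frames without a measurement (the detector missed the subject) are
    UNKNOWN. For measured frames, the window of the last ``params.window``
    frame positions is examined and the movement flags of the measured
    frames inside it are counted. The first measured frames, before a full
    window has elapsed, inherit the first state computed with a full
    window (or, if the whole sequence is shorter than the window, the
    state computed from all of it).
    """
    if not measurements:
        raise ValueError("empty measurement list")
    ms = sorted(measurements, key=lambda m: m.frame_index)
    if subject_id is None:
        subject_id = ms[0].subject_id
    moved_by_frame: Dict[int, bool] = {}
    for m in ms:
        if not 0 <= m.frame_index < n_frames:
            raise ValueError(f"measurement frame index {m.frame_index} outside [0, {n_frames})")
        moved_by_frame[m.frame_index] = m.moved

    states = [State.UNKNOWN] * n_frames
    first_frame = ms[0].frame_index
    full_from = first_frame + params.window - 1

    def window_state(t: int) -> State:
        lo = t - params.window + 1
        count = sum(1 for f in range(max(lo, 0), t + 1) if moved_by_frame.get(f, False))
        return State.ASLEEP if count <= params.max_awake_frames_in_window else State.AWAKE

    pending: List[int] = []  # measured frames awaiting the first full-window state
    first_full_state: Optional[State] = None
    for t in sorted(moved_by_frame):
        if t >= full_from:
            states[t] = window_state(t)
            if first_full_state is None:
                first_full_state = states[t]
        else:
            pending.append(t)
    if first_full_state is None:
        # Sequence shorter than a window: one state from everything.
        last = max(moved_by_frame)
        first_full_state = window_state(last)
    for t in pending:
        states[t] = first_full_state

    return StateSequence(subject_id=subject_id, fps=fps, states=states)


def bridge_unknown(seq: StateSequence, max_gap_s: float) -> StateSequence:
    """Relabel short UNKNOWN gaps flanked by ASLEEP on both sides as ASLEEP.

    Opt-in smoothing for footage with brief detector dropouts; gaps longer
    than ``max_gap_s`` are left untouched, as are gaps at the boundaries.
    """
    max_gap = int(max_gap_s * seq.fps)
    states = list(seq.states)
    n = len(states)
    i = 0
    while i < n:
        if states[i] is State.UNKNOWN:
            j = i
            while j < n and states[j] is State.UNKNOWN:
                j += 1
            flanked = (i > 0 and states[i - 1] is State.ASLEEP
                       and j < n and states[j] is State.ASLEEP)
            if flanked and (j - i) <= max_gap:
                for k in range(i, j):
                    states[k] = State.ASLEEP
            i = j
        else:
            i += 1
    return StateSequence(seq.subject_id, seq.fps, states)


def extract_bouts(seq: StateSequence, strict_wsw: bool = False,
                  bridge_unknown_max_s: Optional[float] = None) -> List[Bout]:
    """Extract sleeping bouts: maximal runs of ASLEEP frames.

    UNKNOWN frames terminate a run (unless bridged via
    ``bridge_unknown_max_s``). Runs touching the sequence boundary count
    as bouts by default; with ``strict_wsw=True`` only runs flanked by
    wakefulness on both sides (the literal wake-sleep-wake reading) are
    kept. Bout times are frame index / fps, end-exclusive, so bout
    durations sum exactly to total sleep time.
    """
    if bridge_unknown_max_s is not None:
        seq = bridge_unknown(seq, bridge_unknown_max_s)
    bouts: List[Bout] = []
    n = len(seq.states)
    i = 0
    while i < n:
        if seq.states[i] is State.ASLEEP:
            j = i
            while j < n and seq.states[j] is State.ASLEEP:
                j += 1
            keep = True
            if strict_wsw:
                left_wake = i > 0 and seq.states[i - 1] is State.AWAKE
                right_wake = j < n and seq.states[j] is State.AWAKE
                keep = left_wake and right_wake
            if keep:
                bouts.append(Bout(i / seq.fps, j / seq.fps))
            i = j
        else:
            i += 1
    return bouts


def summarize(seq: StateSequence, strict_wsw: bool = False) -> SleepSummary:
    """Session summary: total sleep/awake/unknown seconds, bouts, percent."""
    counts = {State.ASLEEP: 0, State.AWAKE: 0, State.UNKNOWN: 0}
    for s in seq.states:
        counts[s] += 1
    sleep_s = counts[State.ASLEEP] / seq.fps
    awake_s = counts[State.AWAKE] / seq.fps
    unknown_s = counts[State.UNKNOWN] / seq.fps
    known = sleep_s + awake_s
    percent = 100.0 * sleep_s / known if known > 0 else None
    return SleepSummary(
        subject_id=seq.subject_id,
        total_sleep_s=sleep_s,
        total_awake_s=awake_s,
        total_unknown_s=unknown_s,
        observed_s=len(seq.states) / seq.fps,
        bout_count=len(extract_bouts(seq, strict_wsw=strict_wsw)),
        percent_asleep=percent,
    )


def format_hms(seconds: float) -> str:
    """Render seconds as H:MM:SS (zero-padded, sub-second part truncated)."""
    total = int(seconds)
    h, rem = divmod(total, 3600)
    m, s = divmod(rem, 60)
    return f"{h:02d}:{m:02d}:{s:02d}"


def parse_hms(text: str) -> int:
    """Parse an H:MM:SS duration into whole seconds."""
    parts = text.strip().split(":")
    if len(parts) != 3:
        raise ValueError(f"expected H:MM:SS, got {text!r}")
    h, m, s = (int(p) for p in parts)
    if not (0 <= m < 60 and 0 <= s < 60 and h >= 0):
        raise ValueError(f"invalid H:MM:SS duration {text!r}")
    return h * 3600 + m * 60 + s
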