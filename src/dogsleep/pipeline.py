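"""End-to-end analysis: frame stream -> detections -> motion -> sleep summary.

Stage 1 (detection) localises each dog with a bounding box; stage 2 crops
the current frame's box out of both the current and the previous frame and
runs the frame-differencing motion detector on the pair. Using the current
box on both frames means slow box drift from the tracker is not itself
counted as motion. Frames where a subject is not detected, or where no
previous frame exists, yield no measurement and are scored UNKNOWN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

from .detection import Detector, Tracker
from .motion import MotionMeasurement, MotionParams, measure_motion
from .sleep_state import (
    SleepSummary,
    StateParams,
    StateSequence,
    classify_states,
    summarize,
)
from .video_io import FrameStream, gray_pixels

__all__ = ["AnalysisResult", "analyze_stream"]


@dataclass
class AnalysisResult:
    """Everything the pipeline produced for one session."""

    fps: float
    n_frames: int
    sequences: Dict[int, StateSequence] = field(default_factory=dict)
    summaries: Dict[int, SleepSummary] = field(default_factory=dict)
    measurements: List[MotionMeasurement] = field(default_factory=list)
    failed_frames: int = 0


def analyze_stream(
    stream: FrameStream,
    detector: Detector,
    motion_params: MotionParams = MotionParams(),
    state_params: Optional[StateParams] = None,
    min_iou: float = 0.3,
    strict_wsw: bool = False,
    bridge_unknown_max_s: Optional[float] = None,
) -> AnalysisResult:
    """Run the full two-stage analysis over a frame stream.

    ``state_params`` defaults to a 3-second window at the stream's frame
    rate with zero movement tolerance. Frames whose detection raises are
    logged as failed and contribute UNKNOWN states rather than aborting
    the session.
    """
    if state_params is None:
        state_params = StateParams.for_fps(stream.fps)

    tracker = Tracker(min_iou=min_iou)
    per_subject: Dict[int, List[MotionMeasurement]] = {}
    prev_gray = None
    n_frames = 0
    failed = 0

    for frame in stream:
        n_frames = frame.index + 1
        gray = gray_pixels(frame)
        try:
            detections = tracker.update(detector.detect(frame))
        except Exception:
            failed += 1
            prev_gray = gray
            continue
        if prev_gray is not None:
            for det in detections:
                box = det.box
                m = measure_motion(
                    box.crop(prev_gray), box.crop(gray), motion_params,
                    frame_index=frame.index, subject_id=det.subject_id,
                )
                per_subject.setdefault(det.subject_id, []).append(m)
        prev_gray = gray

    result = AnalysisResult(fps=stream.fps, n_frames=n_frames, failed_frames=failed)
    for subject_id, ms in sorted(per_subject.items()):
        seq = classify_states(ms, state_params, n_frames, stream.fps,
                              subject_id=subject_id)
        result.sequences[subject_id] = seq
        result.summaries[subject_id] = summarize(
            seq, strict_wsw=strict_wsw) if bridge_unknown_max_s is None else _summarize_bridged(
            seq, strict_wsw, bridge_unknown_max_s)
        result.measurements.extend(ms)
    return result


def _summarize_bridged(seq: StateSequence, strict_wsw: bool,
                       bridge_unknown_max_s: float) -> SleepSummary:
    from .sleep_state import bridge_unknown

    return summarize(bridge_unknown(seq, bridge_unknown_max_s), strict_wsw=strict_wsw)
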