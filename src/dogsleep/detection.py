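"""Per-frame dog detections, the pluggable detector contract, and tracking.

Dog localisation is a separate concern from sleep scoring: any detector
that can put a bounding box around each dog in a frame can drive the motion
pipeline. The production systems this package models use a trained neural
network for that stage; here the detector is an interface with two bundled
implementations that need no trained weights:

* :class:`GroundTruthDetector` — replays boxes from a synthetic scenario's
  ground truth (for testing and validation);
* :class:`StaticRoiDetector` — a fixed, user-configured region of interest,
  adequate for single-kennel footage where the dog's resting spot is known.

Detections are associated across frames into per-subject tracks by greedy
intersection-over-union matching; kennelled dogs move slowly relative to
the frame interval, so greedy matching suffices.
"""

from __future__ import annotations

import abc
import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from .video_io import Frame

__all__ = [
    "BoundingBox",
    "Detection",
    "Track",
    "Detector",
    "GroundTruthDetector",
    "StaticRoiDetector",
    "iou",
    "associate",
    "Tracker",
    "read_detections_csv",
    "write_detections_csv",
]

DEFAULT_MIN_IOU = 0.3


@dataclass(frozen=True, order=True)
class BoundingBox:
    """Axis-aligned pixel box, half-open: [x_min, x_max) x [y_min, y_max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box ({self.x_min},{self.y_min},{self.x_max},{self.y_max}): "
                "require x_min < x_max and y_min < y_max"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    def clipped(self, frame_height: int, frame_width: int) -> "BoundingBox":
        """Clip to frame bounds; raises if nothing remains inside."""
        return BoundingBox(
            max(self.x_min, 0),
            max(self.y_min, 0),
            min(self.x_max, frame_width),
            min(self.y_max, frame_height),
        )

    def crop(self, pixels):
        """Extract this box's content from a (H, W[, C]) pixel array."""
        return pixels[self.y_min:self.y_max, self.x_min:self.x_max]


@dataclass
class Detection:
    """One dog found in one frame."""

    frame_index: int
    box: BoundingBox
    confidence: float = 1.0
    subject_id: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")


@dataclass
class Track:
    """Ordered detections of one subject, at most one per frame."""

    subject_id: int
    detections: List[Detection] = field(default_factory=list)

    def append(self, det: Detection) -> None:
        if self.detections and det.frame_index <= self.detections[-1].frame_index:
            raise ValueError(
                f"track {self.subject_id}: frame indices must strictly increase "
                f"({det.frame_index} after {self.detections[-1].frame_index})"
            )
        self.detections.append(det)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def associate(
    prev: Sequence[Detection],
    cur: Sequence[Detection],
    min_iou: float = DEFAULT_MIN_IOU,
    next_id: Optional[int] = None,
) -> List[Detection]:
    """Assign subject ids to current detections by greedy IoU matching.

    Pairs are matched in descending IoU order; pairs below ``min_iou`` stay
    unmatched and unmatched current detections receive fresh ids. Returns
    the current detections with ``subject_id`` filled in (mutated in place
    and returned for convenience). No id is ever assigned twice in a frame.
    """
    used_prev: set = set()
    used_cur: set = set()
    pairs = sorted(
        (
            (iou(p.box, c.box), pi, ci)
            for pi, p in enumerate(prev)
            for ci, c in enumerate(cur)
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    for score, pi, ci in pairs:
        if score < min_iou:
            break
        if pi in used_prev or ci in used_cur:
            continue
        cur[ci].subject_id = prev[pi].subject_id
        used_prev.add(pi)
        used_cur.add(ci)

    if next_id is None:
        taken = [p.subject_id for p in prev if p.subject_id is not None]
        next_id = max(taken, default=-1) + 1
    for ci, c in enumerate(cur):
        if ci not in used_cur:
            c.subject_id = next_id
            next_id += 1
    return list(cur)


class Tracker:
    """Stateful frame-to-frame association building per-subject tracks."""

    def __init__(self, min_iou: float = DEFAULT_MIN_IOU) -> None:
        self.min_iou = min_iou
        self.tracks: Dict[int, Track] = {}
        self._prev: List[Detection] = []
        self._next_id = 0

    def update(self, detections: Sequence[Detection]) -> List[Detection]:
        """Assign ids to this frame's detections and extend tracks."""
        dets = list(detections)
        associate(self._prev, dets, self.min_iou, next_id=self._next_id)
        for d in dets:
            if d.subject_id >= self._next_id:
                self._next_id = d.subject_id + 1
            self.tracks.setdefault(d.subject_id, Track(d.subject_id)).append(d)
        self._prev = dets
        return dets


class Detector(abc.ABC):
    """Contract for per-frame dog detection: frame in, detections out."""

    @abc.abstractmethod
    def detect(self, frame: Frame) -> List[Detection]:
        """Return 0+ detections with boxes clipped to frame bounds."""


class GroundTruthDetector(Detector):
    """Replays known boxes (e.g. from a synthetic scenario's ground truth).

    ``boxes_by_frame`` maps frame index -> list of BoundingBox. Frames the
    map lacks raise ``KeyError`` (or yield an empty arena when
    ``missing_ok`` is set, for sources that omit empty frames); an empty
    list means an empty arena.
    """

    def __init__(self, boxes_by_frame: Dict[int, List[BoundingBox]],
                 missing_ok: bool = False) -> None:
        self.boxes_by_frame = boxes_by_frame
        self.missing_ok = missing_ok

    def detect(self, frame: Frame) -> List[Detection]:
        if frame.index not in self.boxes_by_frame:
            if self.missing_ok:
                return []
            raise KeyError(
                f"ground truth has no entry for frame index {frame.index}"
            )
        h, w = frame.shape
        return [
            Detection(frame.index, b.clipped(h, w), confidence=1.0)
            for b in self.boxes_by_frame[frame.index]
        ]


class StaticRoiDetector(Detector):
    """Always reports one fixed region of interest (single-kennel footage)."""

    def __init__(self, box: BoundingBox) -> None:
        self.box = box

    def detect(self, frame: Frame) -> List[Detection]:
        h, w = frame.shape
        return [Detection(frame.index, self.box.clipped(h, w), confidence=1.0)]


_CSV_FIELDS = ["frame_index", "subject_id", "x_min", "y_min", "x_max", "y_max", "confidence"]


def write_detections_csv(detections: Sequence[Detection], path) -> None:
    """Write detections in the interchange CSV schema."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for d in detections:
            w.writerow([
                d.frame_index,
                "" if d.subject_id is None else d.subject_id,
                d.box.x_min, d.box.y_min, d.box.x_max, d.box.y_max,
                d.confidence,
            ])


def read_detections_csv(path) -> List[Detection]:
    """Read detections from the interchange CSV schema."""
    out: List[Detection] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Detection(
                frame_index=int(row["frame_index"]),
                box=BoundingBox(int(row["x_min"]), int(row["y_min"]),
                                int(row["x_max"]), int(row["y_max"])),
                confidence=float(row["confidence"]),
                subject_id=int(row["subject_id"]) if row["subject_id"] != "" else None,
            ))
    return out
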