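"""Seeded synthetic kennel scenarios with exact ground truth.

Real validation footage of sleeping dogs is rarely shareable, so the
pipeline is exercised on rendered scenarios instead: 0-2 "dogs" (textured
ellipses) in a small arena, each following a known sleep/wake schedule.
Awake dogs take a random walk and their texture shimmers (limb motion);
asleep dogs are pixel-static apart from optional brief twitches. The
renderer reproduces the practical nuisances of cheap outdoor CCTV — global
camera shake in wind, lights switching (intensity flicker), and sensor
noise — and emits, alongside the frames, the true bounding boxes, the true
per-frame state sequence, and the true sleep summary for every dog.

Realism is explicitly not a goal: the generator targets the statistical
structure the classifier assumes (pixel motion iff awake), which is what
makes exact recovery testable. Everything is deterministic given the
scenario seed; each dog and each nuisance consumes its own substream, so
switching a nuisance on does not change any dog's trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import yaml

from .annotations import write_observation_log
from .detection import BoundingBox, Detection, write_detections_csv
from .sleep_state import (
    SleepSummary,
    State,
    StateSequence,
    extract_bouts,
    summarize,
)
from .video_io import Frame, FrameMode

__all__ = [
    "DogSpec",
    "NuisanceSpec",
    "Scenario",
    "GroundTruth",
    "simulate",
    "render_scenario",
    "observer_error_model",
    "scenario_from_yaml",
    "scenario_to_yaml",
]

# Day-mode per-channel gains applied to the luminance image; chosen to keep
# BT.601 luminance close to the underlying gray render.
_DAY_GAINS = np.array([1.08, 1.0, 0.85])


@dataclass
class DogSpec:
    """One synthetic dog: geometry, schedule, and motion statistics.

    ``schedule`` is an ordered list of ``(state, duration_s)`` with state
    ``"asleep"`` or ``"awake"``; durations must sum to the scenario
    duration. ``awake_motion_sd`` is the per-frame random-walk step (pixels,
    per axis); ``twitch_prob`` is the per-asleep-frame probability of a
    one-frame positional twitch of ``twitch_amplitude`` pixels sd.
    """

    body_size: int = 24
    start_position: Tuple[float, float] = (40.0, 40.0)  # (x, y) centre
    schedule: List[Tuple[str, float]] = field(default_factory=list)
    awake_motion_sd: float = 2.0
    twitch_prob: float = 0.0
    twitch_amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.body_size < 4:
            raise ValueError("body_size must be >= 4 pixels")
        if not 0.0 <= self.twitch_prob <= 1.0:
            raise ValueError("twitch_prob must be in [0, 1]")
        for state, dur in self.schedule:
            if state not in ("asleep", "awake"):
                raise ValueError(f"schedule state must be asleep/awake, got {state!r}")
            if dur <= 0:
                raise ValueError("schedule: zero- or negative-duration entries not allowed")


@dataclass
class NuisanceSpec:
    """Global recording nuisances applied after compositing."""

    shake_sd: float = 0.0            # px/frame global translation
    flicker_amplitude: float = 0.0   # intensity units
    flicker_period_s: float = 10.0   # seconds
    sensor_noise_sd: float = 0.0     # intensity units

    def __post_init__(self) -> None:
        for name in ("shake_sd", "flicker_amplitude", "flicker_period_s", "sensor_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class Scenario:
    """A full synthetic recording description."""

    duration_s: float
    fps: float = 5.0
    width: int = 160
    height: int = 120
    seed: int = 0
    dogs: List[DogSpec] = field(default_factory=list)
    mode: FrameMode = FrameMode.NIGHT_GRAY
    nuisance: NuisanceSpec = field(default_factory=NuisanceSpec)

    def __post_init__(self) -> None:
        if not 0 <= len(self.dogs) <= 2:
            raise ValueError(f"scenario supports 0-2 dogs, got {len(self.dogs)}")
        n = self.duration_s * self.fps
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s x fps must be an integer frame count")
        for i, dog in enumerate(self.dogs):
            total = sum(d for _, d in dog.schedule)
            if abs(total - self.duration_s) > 1e-9:
                raise ValueError(
                    f"schedule: dog {i} schedule sums to {total} s, "
                    f"expected scenario duration {self.duration_s} s"
                )

    @property
    def n_frames(self) -> int:
        return round(self.duration_s * self.fps)


@dataclass
class GroundTruth:
    """What actually happened in a rendered scenario."""

    boxes_by_frame: Dict[int, List[BoundingBox]]   # one box per dog, dog order
    states_by_frame: Dict[int, List[State]]
    sequences: List[StateSequence]                 # per dog
    summaries: List[SleepSummary]                  # per dog

    def detections(self) -> List[Detection]:
        """Flatten to the detection-CSV schema, subject id = dog index."""
        out: List[Detection] = []
        for fi in sorted(self.boxes_by_frame):
            for dog_idx, box in enumerate(self.boxes_by_frame[fi]):
                out.append(Detection(fi, box, 1.0, subject_id=dog_idx))
        return out


def _schedule_states(dog: DogSpec, n_frames: int, fps: float) -> List[State]:
    states: List[State] = []
    for state, dur in dog.schedule:
        states.extend([State.ASLEEP if state == "asleep" else State.AWAKE]
                      * round(dur * fps))
    if len(states) != n_frames:  # rounding guard
        states = states[:n_frames] + [states[-1]] * (n_frames - len(states))
    return states


def _dog_texture(rng: np.random.Generator, h: int, w: int) -> Tuple[np.ndarray, np.ndarray]:
    """Per-dog random texture tile and elliptical body mask."""
    texture = rng.integers(90, 221, size=(h, w)).astype(np.uint8)
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    mask = ((yy - cy) / (h / 2.0)) ** 2 + ((xx - cx) / (w / 2.0)) ** 2 <= 1.0
    return texture, mask


def simulate(scenario: Scenario) -> Tuple[List[Frame], GroundTruth]:
    """Render a scenario in memory: frames plus exact ground truth."""
    n_frames = scenario.n_frames
    ss = np.random.SeedSequence(scenario.seed)
    streams = ss.spawn(len(scenario.dogs) + 1)
    dog_rngs = [np.random.default_rng(s) for s in streams[:len(scenario.dogs)]]
    nuisance_rng = np.random.default_rng(streams[-1])

    H, W = scenario.height, scenario.width
    background = 60

    # Per-dog static data.
    bodies = []
    for dog, rng in zip(scenario.dogs, dog_rngs):
        bh = dog.body_size
        bw = int(round(dog.body_size * 1.5))  # dogs are longer than tall
        texture, mask = _dog_texture(rng, bh, bw)
        bodies.append((texture, mask, bh, bw))
    positions = [np.array(dog.start_position, dtype=float) for dog in scenario.dogs]
    all_states = [_schedule_states(dog, n_frames, scenario.fps) for dog in scenario.dogs]

    frames: List[Frame] = []
    boxes_by_frame: Dict[int, List[BoundingBox]] = {}
    states_by_frame: Dict[int, List[State]] = {}

    for t in range(n_frames):
        canvas = np.full((H, W), background, dtype=np.float64)

        frame_boxes: List[BoundingBox] = []
        frame_states: List[State] = []
        for d, (dog, rng) in enumerate(zip(scenario.dogs, dog_rngs)):
            state = all_states[d][t]
            offset = np.zeros(2)
            if t > 0:
                if state is State.AWAKE:
                    positions[d] = positions[d] + rng.normal(0.0, dog.awake_motion_sd, 2)
                elif dog.twitch_prob > 0:
                    if rng.random() < dog.twitch_prob:
                        offset = rng.normal(0.0, dog.twitch_amplitude, 2)
            texture, mask, bh, bw = bodies[d]
            # Keep the body fully inside the arena.
            positions[d][0] = np.clip(positions[d][0], bw / 2 + 1, W - bw / 2 - 2)
            positions[d][1] = np.clip(positions[d][1], bh / 2 + 1, H - bh / 2 - 2)
            cx = int(round(positions[d][0] + offset[0]))
            cy = int(round(positions[d][1] + offset[1]))
            cx = int(np.clip(cx, bw // 2 + 1, W - bw // 2 - 2))
            cy = int(np.clip(cy, bh // 2 + 1, H - bh // 2 - 2))

            tex = texture
            if state is State.AWAKE:
                # Limb motion: shimmer the texture by a small random phase.
                sy, sx = rng.integers(-2, 3, size=2)
                tex = np.roll(np.roll(texture, int(sy), axis=0), int(sx), axis=1)

            y0, x0 = cy - bh // 2, cx - bw // 2
            region = canvas[y0:y0 + bh, x0:x0 + bw]
            region[mask] = tex[mask]

            frame_boxes.append(BoundingBox(x0, y0, x0 + bw, y0 + bh))
            frame_states.append(state)

        # Nuisances: global shake, light flicker, sensor noise. Each frame
        # consumes draws in a fixed order so seeds stay comparable.
        nu = scenario.nuisance
        shake = np.round(nuisance_rng.normal(0.0, 1.0, 2) * nu.shake_sd).astype(int)
        if shake[0] != 0 or shake[1] != 0:
            canvas = np.roll(np.roll(canvas, shake[0], axis=0), shake[1], axis=1)
            shifted = []
            for b in frame_boxes:
                shifted.append(BoundingBox(
                    int(np.clip(b.x_min + shake[1], 0, W - 2)),
                    int(np.clip(b.y_min + shake[0], 0, H - 2)),
                    int(np.clip(b.x_max + shake[1], 1, W)),
                    int(np.clip(b.y_max + shake[0], 1, H)),
                ))
            frame_boxes = shifted
        if nu.flicker_amplitude > 0:
            phase = 2.0 * np.pi * t / max(nu.flicker_period_s * scenario.fps, 1e-9)
            canvas = canvas + nu.flicker_amplitude * np.sin(phase)
        noise = nuisance_rng.normal(0.0, 1.0, canvas.shape)
        if nu.sensor_noise_sd > 0:
            canvas = canvas + nu.sensor_noise_sd * noise

        gray = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
        if scenario.mode is FrameMode.DAY_COLOUR:
            pixels = np.clip(np.round(gray[..., None] * _DAY_GAINS), 0, 255).astype(np.uint8)
        else:
            pixels = gray
        frames.append(Frame(t, t / scenario.fps, pixels, scenario.mode))
        boxes_by_frame[t] = frame_boxes
        states_by_frame[t] = frame_states

    sequences = [
        StateSequence(subject_id=d, fps=scenario.fps, states=all_states[d])
        for d in range(len(scenario.dogs))
    ]
    summaries = [summarize(seq) for seq in sequences]
    truth = GroundTruth(boxes_by_frame, states_by_frame, sequences, summaries)
    return frames, truth


def render_scenario(scenario: Scenario, out_dir) -> Tuple[Path, GroundTruth]:
    """Render a scenario to disk: PNG frame directory plus ground truth.

    Writes ``frames/frame_NNNNNN.png``, ``detections.csv`` (the detection
    module's interchange schema), one ``observations_dogN.csv`` event log
    per dog (the annotations dialect), and ``truth.json`` with per-dog
    summaries. Byte-identical across runs for the same scenario.
    """
    out_dir = Path(out_dir)
    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)

    frames, truth = simulate(scenario)
    for f in frames:
        iio.imwrite(frames_dir / f"frame_{f.index:06d}.png", f.pixels)

    write_detections_csv(truth.detections(), out_dir / "detections.csv")
    for d, seq in enumerate(truth.sequences):
        write_observation_log(seq, out_dir / f"observations_dog{d}.csv")

    payload = {
        "fps": scenario.fps,
        "duration_s": scenario.duration_s,
        "n_frames": scenario.n_frames,
        "seed": scenario.seed,
        "mode": scenario.mode.value,
        "summaries": [s.to_dict() for s in truth.summaries],
    }
    (out_dir / "truth.json").write_text(json.dumps(payload, indent=2))
    return frames_dir, truth


def observer_error_model(
    truth: StateSequence,
    lapse_prob: float,
    boundary_jitter_sd: float,
    seed: int,
) -> StateSequence:
    """Simulate an imperfect human observer scoring a known truth.

    Each true bout's boundaries are shifted by independent zero-mean
    normal draws (sd = ``boundary_jitter_sd`` seconds) and each bout is
    independently missed altogether with probability ``lapse_prob``.
    Deterministic per seed; with lapse 0 and jitter 0 the output equals
    the input's asleep/awake pattern.
    """
    if not 0.0 <= lapse_prob <= 1.0:
        raise ValueError("lapse_prob must be in [0, 1]")
    if boundary_jitter_sd < 0:
        raise ValueError("boundary_jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    bouts = extract_bouts(truth)
    n = len(truth)
    states = [State.AWAKE] * n
    duration = truth.duration
    for b in bouts:
        lapse_draw = rng.random()
        j_start, j_end = rng.normal(0.0, 1.0, 2) * boundary_jitter_sd
        if lapse_draw < lapse_prob:
            continue
        start = float(np.clip(b.start + j_start, 0.0, duration))
        end = float(np.clip(b.end + j_end, 0.0, duration))
        a = round(start * truth.fps)
        z = round(end * truth.fps)
        for i in range(max(0, a), min(n, z)):
            states[i] = State.ASLEEP
    return StateSequence(subject_id=truth.subject_id, fps=truth.fps, states=states)


def scenario_from_yaml(path) -> Scenario:
    """Load a Scenario from a YAML description."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        dogs = [
            DogSpec(
                body_size=int(d.get("body_size", 24)),
                start_position=tuple(d.get("start_position", (40.0, 40.0))),
                schedule=[(str(s), float(dur)) for s, dur in d.get("schedule", [])],
                awake_motion_sd=float(d.get("awake_motion_sd", 2.0)),
                twitch_prob=float(d.get("twitch_prob", 0.0)),
                twitch_amplitude=float(d.get("twitch_amplitude", 2.0)),
            )
            for d in raw.get("dogs", [])
        ]
        nu = raw.get("nuisance", {}) or {}
        return Scenario(
            duration_s=float(raw["duration_s"]),
            fps=float(raw.get("fps", 5.0)),
            width=int(raw.get("width", 160)),
            height=int(raw.get("height", 120)),
            seed=int(raw.get("seed", 0)),
            dogs=dogs,
            mode=FrameMode(raw.get("mode", "night_gray")),
            nuisance=NuisanceSpec(
                shake_sd=float(nu.get("shake_sd", 0.0)),
                flicker_amplitude=float(nu.get("flicker_amplitude", 0.0)),
                flicker_period_s=float(nu.get("flicker_period_s", 10.0)),
                sensor_noise_sd=float(nu.get("sensor_noise_sd", 0.0)),
            ),
        )
    except KeyError as exc:
        raise ValueError(f"scenario file {path} missing required field {exc}") from exc


def scenario_to_yaml(scenario: Scenario, path) -> None:
    """Write a Scenario as YAML (inverse of :func:`scenario_from_yaml`)."""
    payload = {
        "duration_s": scenario.duration_s,
        "fps": scenario.fps,
        "width": scenario.width,
        "height": scenario.height,
        "seed": scenario.seed,
        "mode": scenario.mode.value,
        "dogs": [
            {
                "body_size": d.body_size,
                "start_position": list(d.start_position),
                "schedule": [[s, dur] for s, dur in d.schedule],
                "awake_motion_sd": d.awake_motion_sd,
                "twitch_prob": d.twitch_prob,
                "twitch_amplitude": d.twitch_amplitude,
            }
            for d in scenario.dogs
        ],
        "nuisance": {
            "shake_sd": scenario.nuisance.shake_sd,
            "flicker_amplitude": scenario.nuisance.flicker_amplitude,
            "flicker_period_s": scenario.nuisance.flicker_period_s,
            "sensor_noise_sd": scenario.nuisance.sensor_noise_sd,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
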