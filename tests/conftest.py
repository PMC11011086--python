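from __future__ import annotations

import numpy as np
import pytest

from dogsleep.sleep_state import State, StateSequence
from dogsleep.video_io import Frame, FrameMode

_CODE = {"S": State.ASLEEP, "W": State.AWAKE, "U": State.UNKNOWN}


def seq(pattern: str, fps: float = 1.0, subject_id="dog") -> StateSequence:
    """Build a StateSequence from a compact pattern string (S/W/U)."""
    return StateSequence(subject_id=subject_id, fps=fps,
                         states=[_CODE[c] for c in pattern])


def gray_frame(pixels, index: int = 0, fps: float = 1.0) -> Frame:
    pixels = np.asarray(pixels, dtype=np.uint8)
    return Frame(index, index / fps, pixels, FrameMode.NIGHT_GRAY)


def colour_frame(pixels, index: int = 0, fps: float = 1.0) -> Frame:
    pixels = np.asarray(pixels, dtype=np.uint8)
    return Frame(index, index / fps, pixels, FrameMode.DAY_COLOUR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)
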