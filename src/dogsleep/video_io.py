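"""Frame input: video containers or image-sequence directories.

Footage arrives either as a container file (MP4/AVI) or as a directory of
numbered still images (``frame_000001.png`` ...). Both are exposed as a
:class:`FrameStream` yielding :class:`Frame` objects with an index, a
timestamp derived from the frame rate, and a day/night mode flag. Consumer
code never touches the decoding backend.

Cheap CCTV hardware records in two modes: full colour under daylight or
artificial light, and infrared-illuminated grayscale at night. Colour frames
are reduced to luminance with the ITU-R BT.601 weights before any motion
arithmetic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import imageio.v3 as iio
import numpy as np

__all__ = [
    "FrameMode",
    "Frame",
    "FrameStream",
    "open_frame_source",
    "to_grayscale",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}

# ITU-R BT.601 luma weights, the 8-bit video standard.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class FrameMode(enum.Enum):
    """Capture mode of a frame: daylight colour or infrared night vision."""

    DAY_COLOUR = "day_colour"
    NIGHT_GRAY = "night_gray"


@dataclass(frozen=True)
class Frame:
    """One video frame.

    Attributes
    ----------
    index : int
        Zero-based position in the stream.
    timestamp : float
        Seconds from session start; ``index / fps`` for constant-rate streams.
    pixels : numpy.ndarray
        ``(H, W)`` uint8 for grayscale or ``(H, W, 3)`` uint8 RGB.
    mode : FrameMode
        Day-colour or night-gray capture mode.
    """

    index: int
    timestamp: float
    pixels: np.ndarray
    mode: FrameMode

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError(f"frame index must be >= 0, got {self.index}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"frame pixels must be uint8, got {self.pixels.dtype}")
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"frame pixels must be 2-D or 3-D, got {self.pixels.ndim}-D")

    @property
    def shape(self) -> tuple:
        """(height, width) of the frame."""
        return self.pixels.shape[:2]

    @property
    def is_gray(self) -> bool:
        return self.pixels.ndim == 2


@dataclass
class FrameStream:
    """A re-iterable, ordered source of frames with constant frame rate."""

    source: Path
    fps: float
    count: int
    _loader: object = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.count < 0:
            raise ValueError("frame count must be >= 0")

    def __len__(self) -> int:
        return self.count

    def __iter__(self) -> Iterator[Frame]:
        return self._loader()

    @property
    def duration(self) -> float:
        """Session length in seconds."""
        return self.count / self.fps


def _infer_mode(pixels: np.ndarray) -> FrameMode:
    return FrameMode.NIGHT_GRAY if pixels.ndim == 2 else FrameMode.DAY_COLOUR


def _squeeze_gray(pixels: np.ndarray) -> np.ndarray:
    # Single-channel images decoded as (H, W, 1) are treated as grayscale.
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        return pixels[:, :, 0]
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        return pixels[:, :, :3]
    return pixels


def _list_directory_frames(path: Path) -> list[Path]:
    files = sorted(
        p for p in path.iterdir()
        if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS
    )
    if not files:
        raise ValueError(f"no frames: directory {path} contains no image files")
    return files


def open_frame_source(path, fps_override: Optional[float] = None) -> FrameStream:
    """Open a video file or an image-sequence directory as a frame stream.

    Parameters
    ----------
    path : path-like
        A video container readable by imageio, or a directory of image
        files in lexicographic frame order.
    fps_override : float, optional
        Frame rate to use. Mandatory for directories (still images carry
        no timing); overrides container metadata when given for files.

    Returns
    -------
    FrameStream
        Yields frames in order. Iterating twice yields identical frames.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        Empty directory, missing fps for a directory, or frames whose
        dimensions do not match the first frame (the offending frame is
        named in the message).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frame source does not exist: {path}")

    if path.is_dir():
        if fps_override is None:
            raise ValueError(
                "fps_override is required for image-sequence directories "
                "(still images carry no frame-rate metadata)"
            )
        files = _list_directory_frames(path)
        fps = float(fps_override)

        first = _squeeze_gray(np.asarray(iio.imread(files[0])))
        ref_shape = first.shape[:2]

        def loader() -> Iterator[Frame]:
            for i, f in enumerate(files):
                pixels = _squeeze_gray(np.asarray(iio.imread(f)))
                if pixels.shape[:2] != ref_shape:
                    raise ValueError(
                        f"mismatched frame dimensions: frame {i} ({f.name}) is "
                        f"{pixels.shape[:2]}, expected {ref_shape}"
                    )
                pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
                yield Frame(i, i / fps, pixels, _infer_mode(pixels))

        return FrameStream(source=path, fps=fps, count=len(files), _loader=loader)

    # Container file: delegate decoding to imageio.
    if fps_override is not None:
        fps = float(fps_override)
    else:
        try:
            meta = iio.immeta(path)
            fps = float(meta["fps"])
        except Exception as exc:  # pragma: no cover - backend-dependent
            raise ValueError(
                f"could not read fps metadata from {path}; pass fps_override"
            ) from exc

    frames_array = np.asarray(iio.imread(path))
    if frames_array.ndim == 3 and frames_array.shape[-1] in (1, 3, 4):
        frames_array = frames_array[None]
    count = frames_array.shape[0]

    def loader() -> Iterator[Frame]:
        ref_shape = None
        for i in range(count):
            pixels = _squeeze_gray(frames_array[i])
            if ref_shape is None:
                ref_shape = pixels.shape[:2]
            elif pixels.shape[:2] != ref_shape:
                raise ValueError(
                    f"mismatched frame dimensions: frame {i} is "
                    f"{pixels.shape[:2]}, expected {ref_shape}"
                )
            pixels = np.ascontiguousarray(pixels, dtype=np.uint8)
            yield Frame(i, i / fps, pixels, _infer_mode(pixels))

    return FrameStream(source=path, fps=fps, count=count, _loader=loader)


def to_grayscale(frame: Frame) -> Frame:
    """Convert a colour frame to 8-bit luminance; pass grayscale through.

    Luminance is ``round(0.299 R + 0.587 G + 0.114 B)`` clipped to [0, 255]
    (ITU-R BT.601). Idempotent: grayscale input is returned unchanged.
    """
    if frame.is_gray:
        return frame
    if frame.pixels.ndim != 3 or frame.pixels.shape[2] != 3:
        raise ValueError(
            f"expected 1 or 3 channels, got shape {frame.pixels.shape}"
        )
    luma = frame.pixels.astype(np.float64) @ _LUMA_WEIGHTS
    gray = np.clip(np.round(luma), 0, 255).astype(np.uint8)
    return Frame(frame.index, frame.timestamp, gray, frame.mode)


def gray_pixels(frame: Frame) -> np.ndarray:
    """Grayscale pixel array of a frame, converting colour if needed."""
    return to_grayscale(frame).pixels
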