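"""Frame-differencing motion detection inside a subject's bounding box.

A sleeping dog is, to the camera, a static patch of pixels. Movement is
therefore detected by the classical frame-differencing recipe, applied to
the cropped bounding-box content of consecutive frames:

1. convert the crop to grayscale,
2. blur it (suppresses sensor noise and compression artefacts),
3. take the per-pixel absolute difference between consecutive crops,
4. binarize the difference with an intensity threshold,
5. dilate the binary image to fuse fragmented motion pixels,
6. find connected components and measure their areas.

The total area of sufficiently large components, relative to the box area,
decides whether the subject moved in that frame. All numeric parameters are
configuration, bundled in :class:`MotionParams`; the defaults follow the
standard frame-differencing recipe for low-quality CCTV footage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
from scipy import ndimage

from .video_io import Frame, FrameMode, to_grayscale

__all__ = [
    "MotionParams",
    "MotionMeasurement",
    "blur",
    "frame_delta",
    "binarize",
    "dilate",
    "component_areas",
    "measure_motion",
]

# 8-connectivity: diagonal neighbours belong to the same component.
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class MotionParams:
    """Tunable parameters of the six-step motion detector.

    Attributes
    ----------
    blur_kernel : int
        Odd Gaussian kernel width in pixels (1 = no blur). Default 21.
    delta_threshold : int
        Intensity difference (1-255) above which a pixel counts as changed.
        Default 25.
    dilate_kernel : int
        Odd width of the square dilation structuring element. Default 3.
    dilate_iterations : int
        Number of dilation passes (0 = none). Default 2.
    min_component_area : int
        Components smaller than this many pixels are ignored. Default 25.
    min_motion_fraction : float
        Qualifying area, as a fraction of the box area, required to flag
        the frame as moved. Default 0.005 (half a percent of the box).
    """

    blur_kernel: int = 21
    delta_threshold: int = 25
    dilate_kernel: int = 3
    dilate_iterations: int = 2
    min_component_area: int = 25
    min_motion_fraction: float = 0.005

    def __post_init__(self) -> None:
        _check_odd_kernel(self.blur_kernel, "blur_kernel")
        if not 1 <= self.delta_threshold <= 255:
            raise ValueError(f"delta_threshold must be in [1, 255], got {self.delta_threshold}")
        _check_odd_kernel(self.dilate_kernel, "dilate_kernel")
        if self.dilate_iterations < 0:
            raise ValueError("dilate_iterations must be >= 0")
        if self.min_component_area < 1:
            raise ValueError("min_component_area must be >= 1")
        if self.min_motion_fraction < 0:
            raise ValueError("min_motion_fraction must be >= 0")


@dataclass(frozen=True)
class MotionMeasurement:
    """Outcome of the motion detector for one subject in one frame."""

    frame_index: int
    subject_id: int
    qualifying_area: int
    moved: bool


def _check_odd_kernel(kernel: int, name: str) -> None:
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"{name} must be an odd integer >= 1, got {kernel}")


def gaussian_kernel_1d(kernel: int) -> np.ndarray:
    """Discrete normalized Gaussian of width ``kernel``.

    Sigma follows the 8-bit video convention
    ``0.3 * ((kernel - 1)/2 - 1) + 0.8`` so the kernel support matches its
    nominal width.
    """
    _check_odd_kernel(kernel, "kernel")
    if kernel == 1:
        return np.array([1.0])
    sigma = 0.3 * ((kernel - 1) / 2 - 1) + 0.8
    half = (kernel - 1) // 2
    x = np.arange(-half, half + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def blur(img: np.ndarray, kernel: int) -> np.ndarray:
    """Gaussian-blur a grayscale uint8 image (separable, reflect borders).

    ``kernel == 1`` returns the input unchanged. Output is rounded back
    to uint8.
    """
    _check_odd_kernel(kernel, "kernel")
    if kernel == 1:
        return img.copy()
    k1 = gaussian_kernel_1d(kernel)
    out = img.astype(np.float64)
    out = ndimage.correlate1d(out, k1, axis=0, mode="reflect")
    out = ndimage.correlate1d(out, k1, axis=1, mode="reflect")
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def frame_delta(prev: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Per-pixel absolute intensity difference between two grayscale images."""
    if prev.shape != cur.shape:
        raise ValueError(f"shape mismatch: {prev.shape} vs {cur.shape}")
    a = prev.astype(np.int16)
    b = cur.astype(np.int16)
    return np.abs(b - a).astype(np.uint8)


def binarize(delta: np.ndarray, threshold: int) -> np.ndarray:
    """Threshold a delta image: 1 where value > threshold (strict), else 0."""
    if not 1 <= threshold <= 255:
        raise ValueError(f"threshold must be in [1, 255], got {threshold}")
    return (delta > threshold).astype(np.uint8)


def dilate(binary: np.ndarray, kernel: int, iterations: int) -> np.ndarray:
    """Morphological dilation with a square structuring element.

    Applied ``iterations`` times; 0 iterations is the identity. The
    structuring element is truncated at image edges (out-of-bounds
    neighbourhood treated as background).
    """
    _check_odd_kernel(kernel, "kernel")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return binary.copy()
    struct = np.ones((kernel, kernel), dtype=bool)
    out = ndimage.binary_dilation(binary.astype(bool), structure=struct,
                                  iterations=iterations)
    return out.astype(np.uint8)


def component_areas(binary: np.ndarray) -> List[int]:
    """Pixel areas of 8-connected foreground components, descending."""
    labels, n = ndimage.label(binary.astype(bool), structure=_CONN8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    return sorted((int(a) for a in areas), reverse=True)


def _as_gray_array(crop) -> np.ndarray:
    if isinstance(crop, Frame):
        return to_grayscale(crop).pixels
    crop = np.asarray(crop)
    if crop.ndim == 3:
        tmp = Frame(0, 0.0, crop.astype(np.uint8), FrameMode.DAY_COLOUR)
        return to_grayscale(tmp).pixels
    return crop.astype(np.uint8)


def measure_motion(
    prev_crop,
    cur_crop,
    params: MotionParams = MotionParams(),
    frame_index: int = 0,
    subject_id: int = 0,
) -> MotionMeasurement:
    """Run the six-step detector on one pair of equal-shaped crops.

    ``prev_crop``/``cur_crop`` may be :class:`Frame` objects or raw uint8
    arrays (grayscale or RGB). The qualifying area is the summed area of
    all connected components at least ``min_component_area`` pixels large;
    the frame is flagged as moved when that area reaches
    ``min_motion_fraction`` of the crop area.
    """
    prev_g = _as_gray_array(prev_crop)
    cur_g = _as_gray_array(cur_crop)
    if prev_g.shape != cur_g.shape:
        raise ValueError(f"crop shape mismatch: {prev_g.shape} vs {cur_g.shape}")

    pb = blur(prev_g, params.blur_kernel)
    cb = blur(cur_g, params.blur_kernel)
    delta = frame_delta(pb, cb)
    binary = binarize(delta, params.delta_threshold)
    dilated = dilate(binary, params.dilate_kernel, params.dilate_iterations)
    areas = component_areas(dilated)

    qualifying = sum(a for a in areas if a >= params.min_component_area)
    box_area = prev_g.shape[0] * prev_g.shape[1]
    moved = qualifying >= params.min_motion_fraction * box_area
    return MotionMeasurement(frame_index, subject_id, qualifying, moved)
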