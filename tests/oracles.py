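"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the package's code paths: the image pipeline is
evaluated with direct windowed sums and flood fill, and t-test p-values
come straight from the regularized incomplete beta function / numerical
integration of the t density.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate, special


def oracle_grayscale(pixels: np.ndarray) -> np.ndarray:
    if pixels.ndim == 2:
        return pixels.astype(np.uint8)
    out = 0.299 * pixels[..., 0] + 0.587 * pixels[..., 1] + 0.114 * pixels[..., 2]
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def oracle_gaussian_kernel(kernel: int) -> np.ndarray:
    if kernel == 1:
        return np.array([1.0])
    sigma = 0.3 * ((kernel - 1) / 2 - 1) + 0.8
    half = (kernel - 1) // 2
    k = np.array([math.exp(-(i ** 2) / (2 * sigma ** 2)) for i in range(-half, half + 1)])
    return k / k.sum()


def oracle_blur(img: np.ndarray, kernel: int) -> np.ndarray:
    """Direct 2-D windowed convolution with symmetric (reflect) padding."""
    if kernel == 1:
        return img.copy()
    k1 = oracle_gaussian_kernel(kernel)
    k2 = np.outer(k1, k1)
    half = (kernel - 1) // 2
    padded = np.pad(img.astype(np.float64), half, mode="symmetric")
    h, w = img.shape
    out = np.empty((h, w), dtype=np.float64)
    for y in range(h):
        for x in range(w):
            out[y, x] = float(np.sum(padded[y:y + kernel, x:x + kernel] * k2))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def oracle_dilate(binary: np.ndarray, kernel: int, iterations: int) -> np.ndarray:
    out = binary.astype(np.uint8).copy()
    half = (kernel - 1) // 2
    h, w = out.shape
    for _ in range(iterations):
        nxt = np.zeros_like(out)
        for y in range(h):
            for x in range(w):
                y0, y1 = max(0, y - half), min(h, y + half + 1)
                x0, x1 = max(0, x - half), min(w, x + half + 1)
                nxt[y, x] = 1 if out[y0:y1, x0:x1].any() else 0
        out = nxt
    return out


def oracle_component_areas(binary: np.ndarray) -> list:
    h, w = binary.shape
    seen = np.zeros((h, w), dtype=bool)
    areas = []
    for y in range(h):
        for x in range(w):
            if binary[y, x] and not seen[y, x]:
                stack = [(y, x)]
                seen[y, x] = True
                area = 0
                while stack:
                    cy, cx = stack.pop()
                    area += 1
                    for dy in (-1, 0, 1):
                        for dx in (-1, 0, 1):
                            ny, nx = cy + dy, cx + dx
                            if (0 <= ny < h and 0 <= nx < w
                                    and binary[ny, nx] and not seen[ny, nx]):
                                seen[ny, nx] = True
                                stack.append((ny, nx))
                areas.append(area)
    return sorted(areas, reverse=True)


def oracle_measure_motion(prev, cur, blur_kernel=21, delta_threshold=25,
                          dilate_kernel=3, dilate_iterations=2,
                          min_component_area=25, min_motion_fraction=0.005):
    """The six steps, composed straight-line: (qualifying area, moved)."""
    pg = oracle_blur(oracle_grayscale(np.asarray(prev)), blur_kernel)
    cg = oracle_blur(oracle_grayscale(np.asarray(cur)), blur_kernel)
    delta = np.abs(cg.astype(int) - pg.astype(int))
    binary = (delta > delta_threshold).astype(np.uint8)
    dilated = oracle_dilate(binary, dilate_kernel, dilate_iterations)
    areas = oracle_component_areas(dilated)
    qualifying = sum(a for a in areas if a >= min_component_area)
    moved = qualifying >= min_motion_fraction * pg.size
    return qualifying, moved


def oracle_paired_t(x, y):
    """(t, df, p) by direct formula; p via the regularized incomplete beta."""
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    mean = sum(d) / n
    var = sum((v - mean) ** 2 for v in d) / (n - 1)
    t = mean / math.sqrt(var / n)
    df = n - 1
    p = special.betainc(df / 2.0, 0.5, df / (df + t * t))
    return t, df, float(p)


def oracle_t_sf_by_integration(t: float, df: int) -> float:
    """Upper-tail t probability by numerical integration of the density."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))

    def density(u):
        return c * (1 + u * u / df) ** (-(df + 1) / 2)

    val, _ = integrate.quad(density, abs(t), np.inf)
    return val
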