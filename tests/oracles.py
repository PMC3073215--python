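"""Independent brute-force oracles used by the test suite.

These are deliberately naive loop implementations — sliding-window
min/max for grayscale morphology and direct set-based box counting for
the multifractal spectrum — kept free of any code path they are used to
check.
"""

from __future__ import annotations

import numpy as np


def brute_erode(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Sliding-window minimum over the footprint, symmetric padding."""
    r = footprint.shape[0] // 2
    padded = np.pad(image, r, mode="symmetric")
    out = np.empty_like(image, dtype=np.float64)
    fp = footprint.astype(bool)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = window[fp].min()
    return out


def brute_dilate(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Sliding-window maximum over the footprint, symmetric padding."""
    r = footprint.shape[0] // 2
    padded = np.pad(image, r, mode="symmetric")
    out = np.empty_like(image, dtype=np.float64)
    fp = footprint.astype(bool)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            window = padded[i : i + 2 * r + 1, j : j + 2 * r + 1]
            out[i, j] = window[fp].max()
    return out


def brute_opening(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_dilate(brute_erode(image, footprint), footprint)


def brute_closing(image: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    return brute_erode(brute_dilate(image, footprint), footprint)


def brute_window_sum(image: np.ndarray, halfwidth: int) -> np.ndarray:
    """Direct (2k+1)x(2k+1) windowed sums with symmetric padding."""
    k = halfwidth
    padded = np.pad(image, k, mode="symmetric")
    out = np.empty_like(image, dtype=np.float64)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = padded[i : i + 2 * k + 1, j : j + 2 * k + 1].sum()
    return out


def brute_box_counts(
    bin_index: np.ndarray, n_bins: int, box_sizes: list[int]
) -> np.ndarray:
    """For each alpha bin and box size, count occupied grid boxes directly."""
    counts = np.zeros((n_bins, len(box_sizes)), dtype=np.int64)
    rows, cols = bin_index.shape
    for jd, delta in enumerate(box_sizes):
        boxes: list[set] = [set() for _ in range(n_bins)]
        for i in range(rows):
            for j in range(cols):
                boxes[bin_index[i, j]].add((i // delta, j // delta))
        for b in range(n_bins):
            counts[b, jd] = len(boxes[b])
    return counts


def slope_loglog(y: np.ndarray, x: np.ndarray) -> float:
    """Least-squares slope via polyfit (independent of the package's math)."""
    return float(np.polyfit(x, y, 1)[0])
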