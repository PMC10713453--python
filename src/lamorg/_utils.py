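"""Small shared numerics: knee location, moving means, seed fan-out."""

from __future__ import annotations

import zlib

import numpy as np


def kneedle_decreasing(x: np.ndarray, y: np.ndarray) -> int:
    """Locate the knee of a decreasing, convex curve (Kneedle).

    Both axes are min-max normalized; the knee is the point maximizing the
    vertical gap between the normalized curve and the descending diagonal,
    i.e. argmax of (1 - x_n) - y_n. Returns the index into ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("knee location needs at least 3 points")
    if np.any(np.diff(x) <= 0):
        raise ValueError("x must be strictly increasing")
    xn = (x - x.min()) / (x.max() - x.min())
    yr = y.max() - y.min()
    yn = (y - y.min()) / yr if yr > 0 else np.zeros_like(y)
    diff = (1.0 - xn) - yn
    return int(np.argmax(diff))


def moving_mean(values: np.ndarray, window: int, axis: int = -1) -> np.ndarray:
    """Centered moving mean with truncated (shorter) windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.moveaxis(np.asarray(values, dtype=float), axis, -1)
    n = values.shape[-1]
    if window > n:
        raise ValueError(f"window {window} exceeds axis length {n}")
    kernel = np.ones(window)
    flat = values.reshape(-1, n)
    sums = np.apply_along_axis(lambda r: np.convolve(r, kernel, mode="same"), 1, flat)
    counts = np.convolve(np.ones(n), kernel, mode="same")
    out = (sums / counts).reshape(values.shape)
    return np.moveaxis(out, -1, axis)


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from one global seed by stable name hashing."""
    return (int(global_seed) + zlib.crc32(stage.encode("utf-8"))) % (2**31 - 1)


def check_symmetric_zero_diag(D: np.ndarray, name: str = "distance matrix") -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError(f"{name} must have zero diagonal")
    return 0.5 * (D + D.T)
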