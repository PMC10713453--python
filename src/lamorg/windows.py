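"""Laminar window segmentation and orientation (Laminator stage 1).

A laminar window is a rectangle anchored with the midpoint of its short
edge on the tissue contour, spanning the inner-outer axis of the tissue.
Orientation is found by rotating the rectangle about its anchor and
maximizing the distance-transform signal captured under its footprint: the
distance map increases toward the tissue interior, so the argmax rotation
aligns the long axis with the local inward normal.

Coordinate convention: 0-based (row, col), pixel centers at integer
coordinates; angles in radians measured from the +col axis with the row
coordinate as the sine component.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.morphology import binary_dilation, disk

from .profiles import ProfileMatrix


# ---------------------------------------------------------------------------
# mask, contour, distance map

def build_tissue_mask(
    channels: np.ndarray, dilation_radius: int = 5
) -> np.ndarray:
    """Binary tissue mask from structural channels.

    Channels are percentile-scaled to [0, 1] (1st/99th), averaged, Otsu
    thresholded, dilated, hole-filled; the largest connected component is
    kept.
    """
    channels = np.atleast_3d(np.asarray(channels, dtype=float))
    if channels.ndim == 2:
        channels = channels[None]
    scaled = np.zeros_like(channels)
    for c in range(channels.shape[0]):
        p1, p99 = np.percentile(channels[c], [1, 99])
        span = p99 - p1 if p99 > p1 else 1.0
        scaled[c] = np.clip((channels[c] - p1) / span, 0, 1)
    avg = scaled.mean(axis=0)
    if avg.max() == avg.min():
        raise ValueError("structural channels are constant; cannot build a mask")
    binary = avg > threshold_otsu(avg)
    if not binary.any():
        raise ValueError("empty mask after thresholding")
    if dilation_radius > 0:
        binary = binary_dilation(binary, disk(dilation_radius))
    binary = ndimage.binary_fill_holes(binary)
    lab, n = ndimage.label(binary)
    if n > 1:
        sizes = np.bincount(lab.ravel())[1:]
        binary = lab == (1 + np.argmax(sizes))
    return binary


@dataclass
class Contour:
    coords: np.ndarray      # (M, 2) ordered closed polyline of subpixel (row, col)
    section_id: str = ""

    def __len__(self) -> int:
        return self.coords.shape[0]


def extract_contour(mask: np.ndarray, sigma: float = 50.0, section_id: str = "") -> Contour:
    """Smoothed tissue outline: Gaussian-filter the mask, re-threshold (Otsu),
    take the longest marching-squares iso-contour, oriented counter-clockwise
    (positive shoelace area with col as x and row as y)."""
    mask = np.asarray(mask, dtype=float)
    if not mask.any():
        raise ValueError("mask is empty")
    smooth = ndimage.gaussian_filter(mask, sigma) if sigma > 0 else mask
    if smooth.max() > smooth.min():
        level = threshold_otsu(smooth)
        if not (smooth.min() < level < smooth.max()):
            level = 0.5 * (smooth.min() + smooth.max())
    else:
        level = 0.5
    # subpixel marching-squares contour at the threshold level
    contours = measure.find_contours(smooth, level)
    if not contours:
        raise ValueError("no contour found")
    coords = max(contours, key=lambda c: c.shape[0])
    if not np.allclose(coords[0], coords[-1]):
        coords = np.vstack([coords, coords[:1]])
    # signed area (x = col, y = row); flip to make it positive
    x, y = coords[:, 1], coords[:, 0]
    area = 0.5 * np.sum(x[:-1] * y[1:] - x[1:] * y[:-1])
    if area < 0:
        coords = coords[::-1].copy()
    return Contour(coords, section_id)


@dataclass
class DistanceMap:
    values: np.ndarray
    sigma: float


def distance_map(mask: np.ndarray, sigma: float = 25.0) -> DistanceMap:
    """Exact Euclidean distance transform of the mask, Gaussian smoothed."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    dt = ndimage.distance_transform_edt(mask)
    if sigma > 0:
        dt = ndimage.gaussian_filter(dt, sigma)
    return DistanceMap(dt, sigma)


# ---------------------------------------------------------------------------
# windows

@dataclass
class LaminarWindow:
    anchor: tuple[float, float]     # (row, col) on the contour
    angle: float                    # inner-outer axis direction, pointing inward
    width_px: int = 100
    length_px: int = 1000
    valid_fraction: float = float("nan")
    dt_score: float = 0.0
    flags: set = dc_field(default_factory=set)
    contour_index: int = -1
    initial_angle: float = float("nan")


@dataclass
class WindowSet:
    windows: list[LaminarWindow]
    section_id: str = ""
    timepoint: object = None
    pixel_size_um: float = 0.1625
    contour: Contour | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def size_um(self) -> tuple[float, float]:
        """(width, length) of the default window in micrometers."""
        w = self.windows[0] if self.windows else LaminarWindow((0, 0), 0.0)
        return (w.width_px * self.pixel_size_um, w.length_px * self.pixel_size_um)


def _initial_normal(contour: Contour, idx: int, dmap: DistanceMap, half_span: int = 10) -> float:
    """Inward normal estimate from the local tangent (PCA over +-half_span
    contour points), sign disambiguated toward higher distance-map values."""
    coords = contour.coords[:-1]
    n = coords.shape[0]
    nbr = coords[(np.arange(idx - half_span, idx + half_span + 1)) % n]
    centered = nbr - nbr.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    t_row, t_col = vt[0]
    n_row, n_col = -t_col, t_row
    anchor = coords[idx]
    probe = np.array(
        [[anchor[0] + 3 * n_row, anchor[0] - 3 * n_row],
         [anchor[1] + 3 * n_col, anchor[1] - 3 * n_col]]
    )
    vals = ndimage.map_coordinates(dmap.values, probe, order=1, cval=0.0)
    if vals[1] > vals[0]:
        n_row, n_col = -n_row, -n_col
    return float(np.arctan2(n_row, n_col))


def place_windows(
    contour: Contour,
    dmap: DistanceMap,
    stride: int = 100,
    width_px: int = 100,
    length_px: int = 1000,
) -> WindowSet:
    """Anchor one unoriented window on every stride-th contour coordinate,
    initialized to the local inward normal."""
    coords = contour.coords[:-1]
    if stride >= coords.shape[0]:
        raise ValueError(f"stride {stride} >= contour length {coords.shape[0]}")
    windows = []
    for idx in range(0, coords.shape[0], stride):
        angle = _initial_normal(contour, idx, dmap)
        windows.append(
            LaminarWindow(
                anchor=(float(coords[idx, 0]), float(coords[idx, 1])),
                angle=angle,
                width_px=width_px,
                length_px=length_px,
                contour_index=idx,
                initial_angle=angle,
            )
        )
    return WindowSet(windows, section_id=contour.section_id, contour=contour)


def _footprint_coords(
    anchor: tuple[float, float], angle: float, width: int, length: int, step: int = 1
) -> np.ndarray:
    """(2, n) image coordinates of the window footprint sample grid.

    u runs along the inner-outer axis from the anchor (outer edge) inward,
    v across the width, centered on the anchor.
    """
    u = np.arange(0, length, step) + 0.5
    v = np.arange(0, width, step) - (width - 1) / 2.0
    uu, vv = np.meshgrid(u, v, indexing="ij")
    s, c = np.sin(angle), np.cos(angle)
    rows = anchor[0] + uu * s + vv * c
    cols = anchor[1] + uu * c - vv * s
    return np.stack([rows.ravel(), cols.ravel()])


def _dt_scores(
    dmap: DistanceMap,
    anchor: tuple[float, float],
    angles: np.ndarray,
    width: int,
    length: int,
    step: int,
) -> np.ndarray:
    """Sum of bilinearly sampled distance-map values under the footprint,
    for every candidate angle (out-of-image samples contribute 0)."""
    coords = [ _footprint_coords(anchor, a, width, length, step) for a in angles ]
    allc = np.concatenate(coords, axis=1)
    vals = ndimage.map_coordinates(dmap.values, allc, order=1, cval=0.0)
    per = coords[0].shape[1]
    return vals.reshape(len(angles), per).sum(axis=1)


def orient_window(
    window: LaminarWindow,
    dmap: DistanceMap,
    coarse_step_deg: float = 2.0,
    refine_step_deg: float = 0.5,
    search_deg: float = 90.0,
    score_step: int = 2,
    full_circle: bool = False,
) -> LaminarWindow:
    """Rotate the window about its anchor and keep the angle maximizing the
    captured distance-transform signal (coarse scan then local refinement);
    ties resolve to the angle closest to the initial normal."""
    init = window.angle
    if full_circle:
        search_deg = 180.0
    coarse = np.deg2rad(coarse_step_deg)
    refine = np.deg2rad(refine_step_deg)
    search = np.deg2rad(search_deg)

    cand = init + np.arange(-search, search + 1e-9, coarse)
    scores = _dt_scores(dmap, window.anchor, cand, window.width_px, window.length_px, score_step)
    if np.all(scores == 0):
        window.flags.add("out_of_bounds")
        window.dt_score = 0.0
        return window
    best = cand[_argmax_closest(scores, cand, init)]

    cand2 = best + np.arange(-coarse, coarse + 1e-9, refine)
    scores2 = _dt_scores(dmap, window.anchor, cand2, window.width_px, window.length_px, score_step)
    j = _argmax_closest(scores2, cand2, init)
    window.angle = float(cand2[j])
    window.dt_score = float(scores2[j])
    return window


def _argmax_closest(scores: np.ndarray, angles: np.ndarray, init: float) -> int:
    """Index of the max score; among exact ties, the angle nearest ``init``."""
    m = scores.max()
    tied = np.flatnonzero(scores == m)
    return int(tied[np.argmin(np.abs(angles[tied] - init))])


def orient_windows(ws: WindowSet, dmap: DistanceMap, **kwargs) -> WindowSet:
    for w in ws.windows:
        orient_window(w, dmap, **kwargs)
    return ws


# ---------------------------------------------------------------------------
# profile extraction and filtering

def extract_profiles(
    ws: WindowSet,
    channels: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    mtu_labels: np.ndarray | None = None,
    n_mtus: int | None = None,
    mask: np.ndarray | None = None,
) -> ProfileMatrix:
    """Resample every window onto its width x length grid and average the
    transverse (width) dimension at each inner-outer position.

    Intensity channels are sampled bilinearly; MTU label images are sampled
    nearest-neighbor and one-hot encoded per id before averaging, yielding
    per-MTU occupancy profiles in [0, 1].  Samples outside the mask (or the
    image) are missing and excluded from the mean; a position with no valid
    sample is NaN.  Position 0 is the outer (contour) edge.
    """
    if channels is None and mtu_labels is None:
        raise ValueError("need intensity channels and/or an MTU label image")
    names: list[str] = []
    if channels is not None:
        channels = np.asarray(channels, dtype=float)
        names += channel_names or [f"ch{i}" for i in range(channels.shape[0])]
    if mtu_labels is not None:
        mtu_labels = np.asarray(mtu_labels)
        if n_mtus is None:
            n_mtus = int(mtu_labels.max())
        names += [f"mtu{m}" for m in range(1, n_mtus + 1)]

    shape_ref = channels[0].shape if channels is not None else mtu_labels.shape
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != shape_ref:
            raise ValueError("mask shape does not match features")

    profs, metas = [], []
    for wi, w in enumerate(ws.windows):
        L, W = w.length_px, w.width_px
        coords = _footprint_coords(w.anchor, w.angle, W, L, step=1)
        in_image = (
            (coords[0] >= 0) & (coords[0] <= shape_ref[0] - 1)
            & (coords[1] >= 0) & (coords[1] <= shape_ref[1] - 1)
        )
        if mask is not None:
            mvals = ndimage.map_coordinates(
                mask.astype(np.uint8), coords, order=0, cval=0
            ).astype(bool)
            valid = in_image & mvals
        else:
            valid = in_image
        valid2d = valid.reshape(L, W)
        w.valid_fraction = float(valid.mean())

        cols = []
        if channels is not None:
            for c in range(channels.shape[0]):
                vals = ndimage.map_coordinates(channels[c], coords, order=1, cval=0.0)
                vals = vals.reshape(L, W)
                cols.append(_masked_transverse_mean(vals, valid2d))
        if mtu_labels is not None:
            lab = ndimage.map_coordinates(mtu_labels, coords, order=0, cval=0)
            lab = lab.reshape(L, W)
            for m in range(1, n_mtus + 1):
                cols.append(_masked_transverse_mean((lab == m).astype(float), valid2d))
        profs.append(np.column_stack(cols))
        metas.append(
            {
                "window": wi,
                "section": ws.section_id,
                "timepoint": ws.timepoint,
                "anchor_row": w.anchor[0],
                "anchor_col": w.anchor[1],
                "angle": w.angle,
                "valid_fraction": w.valid_fraction,
            }
        )
    import pandas as pd

    return ProfileMatrix(np.stack(profs), pd.DataFrame(metas), names)


def _masked_transverse_mean(vals: np.ndarray, valid: np.ndarray) -> np.ndarray:
    out = np.full(vals.shape[0], np.nan)
    n = valid.sum(axis=1)
    ok = n > 0
    out[ok] = np.where(valid, vals, 0.0).sum(axis=1)[ok] / n[ok]
    return out


def contour_straightness(contour: Contour, idx: int, span: int) -> float:
    """Max perpendicular deviation of the contour span around ``idx`` from its
    chord; small values mean a straight segment."""
    coords = contour.coords[:-1]
    n = coords.shape[0]
    seg = coords[np.arange(idx - span, idx + span + 1) % n]
    chord = seg[-1] - seg[0]
    norm = np.linalg.norm(chord)
    if norm == 0:
        return 0.0
    d = np.abs(np.cross(chord / norm, seg - seg[0]))
    return float(d.max())


def filter_windows(
    ws: WindowSet,
    profiles: ProfileMatrix,
    min_valid: float = 0.99,
    straightness_threshold: float | None = None,
) -> tuple[WindowSet, ProfileMatrix]:
    """Drop low-coverage windows (valid_fraction <= min_valid) and, when a
    threshold is given, windows anchored on straight contour segments."""
    keep, n_low, n_straight = [], 0, 0
    for i, w in enumerate(ws.windows):
        if not (w.valid_fraction > min_valid):
            n_low += 1
            continue
        if straightness_threshold is not None and ws.contour is not None:
            dev = contour_straightness(ws.contour, w.contour_index, w.width_px // 2)
            if dev < straightness_threshold:
                w.flags.add("straight_contour")
                n_straight += 1
                continue
        keep.append(i)
    if not keep:
        raise ValueError(
            f"all {len(ws.windows)} windows removed "
            f"(low coverage: {n_low}, straight contour: {n_straight})"
        )
    kept_ws = WindowSet(
        [ws.windows[i] for i in keep], ws.section_id, ws.timepoint, ws.pixel_size_um, ws.contour
    )
    return kept_ws, profiles.subset(np.asarray(keep))
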