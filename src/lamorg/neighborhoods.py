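"""Nuclei features and radial cell-neighborhood profiling.

A cell's microenvironment is summarized by ring-averaged channel
intensities at 1-px radial steps out to a fixed radius around its nucleus
centroid, with all nucleus pixels masked out so the profile reflects the
surroundings rather than the cell itself.  The radial profiles then reuse
the laminar-profile machinery (normalize, smooth, FFT distances, diffusion,
UMAP + Louvain) to find neighborhood types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import metrics, trajectory
from ._graph import knn_louvain
from .profiles import ProfileMatrix
from .windows import DistanceMap


def nucleus_features(
    label_image: np.ndarray,
    channels: np.ndarray,
    dmap: DistanceMap | np.ndarray | None = None,
    kernel: tuple[int, int] = (100, 100),
) -> pd.DataFrame:
    """Per-nucleus intensity statistics plus two spatial features.

    Intensity stats per channel: bottom 5th / top 5th percentile, median,
    mean and sum over the nucleus's member pixels.  ``radial_distance`` is
    the mean distance-map value under the nucleus; ``local_density`` counts
    nuclei centroids (self included) inside the elliptical kernel centered
    on the centroid (semi-axes kernel/2).
    """
    lab = np.asarray(label_image)
    channels = np.asarray(channels, dtype=float)
    ids = np.unique(lab[lab > 0])
    if ids.size == 0:
        return pd.DataFrame()
    dvals = dmap.values if isinstance(dmap, DistanceMap) else dmap

    rows = []
    centroids = np.zeros((ids.size, 2))
    for i, nid in enumerate(ids):
        rr, cc = np.nonzero(lab == nid)
        centroids[i] = rr.mean(), cc.mean()
        rec: dict = {
            "nucleus": int(nid),
            "centroid_row": float(rr.mean()),
            "centroid_col": float(cc.mean()),
            "area": int(rr.size),
        }
        for c in range(channels.shape[0]):
            px = channels[c, rr, cc]
            rec[f"ch{c}_p5"] = float(np.percentile(px, 5))
            rec[f"ch{c}_p95"] = float(np.percentile(px, 95))
            rec[f"ch{c}_median"] = float(np.median(px))
            rec[f"ch{c}_mean"] = float(px.mean())
            rec[f"ch{c}_sum"] = float(px.sum())
        if dvals is not None:
            rec["radial_distance"] = float(dvals[rr, cc].mean())
        rows.append(rec)

    # elliptical-kernel density, self-inclusive
    sa, sb = kernel[0] / 2.0, kernel[1] / 2.0
    scaled = centroids / np.array([sa, sb])
    tree = cKDTree(scaled)
    # tiny slack keeps boundary centroids inside despite scaling round-off
    counts = np.array([len(tree.query_ball_point(p, 1.0 + 1e-9)) for p in scaled])
    df = pd.DataFrame(rows)
    df["local_density"] = counts
    return df


def _ring_offsets(radius: int) -> dict[int, np.ndarray]:
    """Integer pixel offsets grouped by rounded Euclidean distance 1..radius."""
    span = np.arange(-radius, radius + 1)
    dy, dx = np.meshgrid(span, span, indexing="ij")
    r = np.rint(np.hypot(dy, dx)).astype(int)
    return {
        k: np.column_stack([dy[r == k], dx[r == k]]) for k in range(1, radius + 1)
    }


def radial_profiles(
    nuclei: pd.DataFrame,
    channels: np.ndarray,
    nuclei_labels: np.ndarray,
    radius_px: int = 40,
    exclude: str = "all",
) -> ProfileMatrix:
    """Ring-averaged channel intensities around each nucleus centroid.

    Bin r holds the mean intensity over pixels at rounded Euclidean distance
    r from the centroid, excluding nucleus pixels (``exclude="all"`` masks
    every nucleus, ``"focal"`` only the profiled one) — out-of-image pixels
    are missing (NaN), never zero.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    channels = np.asarray(channels, dtype=float)
    lab = np.asarray(nuclei_labels)
    h, w = lab.shape
    offsets = _ring_offsets(radius_px)

    values = np.full((len(nuclei), radius_px, channels.shape[0]), np.nan)
    for i, rec in enumerate(nuclei.itertuples()):
        r0 = int(round(rec.centroid_row))
        c0 = int(round(rec.centroid_col))
        if not (0 <= r0 < h and 0 <= c0 < w):
            raise ValueError(f"nucleus {rec.nucleus} centroid outside image")
        for rbin, off in offsets.items():
            rr = r0 + off[:, 0]
            cc = c0 + off[:, 1]
            inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            rr, cc = rr[inside], cc[inside]
            if rr.size == 0:
                continue
            if exclude == "all":
                keep = lab[rr, cc] == 0
            else:
                keep = lab[rr, cc] != rec.nucleus
            rr, cc = rr[keep], cc[keep]
            if rr.size:
                values[i, rbin - 1] = channels[:, rr, cc].mean(axis=1)

    meta = pd.DataFrame(
        {
            "window": np.arange(len(nuclei)),
            "nucleus": nuclei["nucleus"].to_numpy(),
            "section": nuclei.get("section", pd.Series([""] * len(nuclei))).to_numpy(),
            "timepoint": nuclei.get("timepoint", pd.Series([0] * len(nuclei))).to_numpy(),
        }
    )
    names = [f"ch{c}" for c in range(channels.shape[0])]
    return ProfileMatrix(values, meta, names)


@dataclass
class NeighborhoodClustering:
    labels: np.ndarray
    embedding: np.ndarray
    pseudotime: np.ndarray | None = None


def neighborhood_clustering(
    rpm: ProfileMatrix,
    mean_window: int = 20,
    factor: int = 2,
    n_components: int = 10,
    k_umap: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> NeighborhoodClustering:
    """Cluster radial neighborhoods via the laminar-profile distance chain:
    normalize -> smooth/downsample -> FFT distances -> mean aggregate ->
    diffusion components -> UMAP -> Louvain."""
    import umap

    if rpm.n_windows < 2:
        raise ValueError("need at least 2 neighborhoods")
    pm = metrics.normalize_profiles(rpm)
    pm = metrics.smooth_downsample(pm, mean_window=mean_window, factor=factor)
    ds = metrics.fft_distance(pm, n_components=min(n_components, pm.n_positions // 2 + 1))
    D = metrics.aggregate_log_distance(ds)
    dr = trajectory.diffusion_from_distance(D, n_dcs=min(10, rpm.n_windows - 2), seed=seed)
    k = min(k_umap, rpm.n_windows - 1)
    reducer = umap.UMAP(n_neighbors=k, n_components=2, random_state=seed)
    emb = reducer.fit_transform(dr.components)
    labels = knn_louvain(emb, k=k, seed=seed, resolution=resolution)
    return NeighborhoodClustering(labels, emb)
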