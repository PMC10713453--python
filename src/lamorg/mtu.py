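"""Pixel-level multiplexed tissue unit (MTU) clustering.

An MTU is a cluster of pixels sharing a multi-channel intensity signature —
an unsupervised pixel-level tissue annotation.  The chain is: harmonize
images by reverse z-scoring, subsample in-mask pixels into a pixel matrix,
train a self-organizing map (30 x 30 grid, Euclidean, best of 10 runs),
metacluster the node medians with a kNN-graph Louvain partition whose
neighbor count is picked at the knee of the (k, n_clusters) curve, and
finally label every pixel by its nearest metacluster centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from ._graph import knn_louvain
from ._utils import kneedle_decreasing


# ---------------------------------------------------------------------------
# normalization

@dataclass
class NormalizationStats:
    """Group-level harmonization statistics.

    ``group_stats`` maps (timepoint, channel) to the pooled (mean, sd) of all
    images in that group; ``channel_percentiles`` maps channel index to the
    global (p1, p99) used for the final 0-1 scaling.
    """

    group_stats: dict[tuple[object, int], tuple[float, float]]
    channel_percentiles: dict[int, tuple[float, float]]
    passthrough: list[tuple[str, int]] = field(default_factory=list)


def reverse_zscore_normalize(
    stacks: dict[str, np.ndarray],
    timepoints: dict[str, object],
    clip: bool = True,
) -> tuple[dict[str, np.ndarray], NormalizationStats]:
    """Harmonize per-section channel stacks while preserving group contrasts.

    Each image (one channel of one section) is z-scored with its own mean/sd,
    then rescaled by the pooled sd and mean of its (timepoint, channel) group
    — "reverse z-scoring".  Finally every channel is min-max scaled so the
    global 1st percentile maps to 0 and the 99th to 1 (clipped to [0, 1]).

    Images with zero variance are passed through unchanged and flagged.
    """
    ids = sorted(stacks)
    if not ids:
        raise ValueError("no sections given")
    n_channels = stacks[ids[0]].shape[0]

    group_stats: dict[tuple[object, int], tuple[float, float]] = {}
    for c in range(n_channels):
        tps = sorted({timepoints[s] for s in ids}, key=str)
        for tp in tps:
            pooled = np.concatenate(
                [stacks[s][c].ravel() for s in ids if timepoints[s] == tp]
            )
            mu, sd = float(pooled.mean()), float(pooled.std())
            if sd == 0.0:
                raise ValueError(f"group (timepoint={tp!r}, channel={c}) has zero variance")
            group_stats[(tp, c)] = (mu, sd)

    passthrough: list[tuple[str, int]] = []
    intermediate: dict[str, np.ndarray] = {}
    for s in ids:
        stack = np.asarray(stacks[s], dtype=float)
        out = np.empty_like(stack)
        for c in range(n_channels):
            img = stack[c]
            mu_i, sd_i = img.mean(), img.std()
            if sd_i == 0.0:
                passthrough.append((s, c))
                out[c] = img
                continue
            gmu, gsd = group_stats[(timepoints[s], c)]
            out[c] = (img - mu_i) / sd_i * gsd + gmu
        intermediate[s] = out

    channel_percentiles: dict[int, tuple[float, float]] = {}
    for c in range(n_channels):
        pooled = np.concatenate([intermediate[s][c].ravel() for s in ids])
        p1, p99 = np.percentile(pooled, [1, 99])
        channel_percentiles[c] = (float(p1), float(p99))

    normalized: dict[str, np.ndarray] = {}
    for s in ids:
        out = np.empty_like(intermediate[s])
        for c in range(n_channels):
            p1, p99 = channel_percentiles[c]
            span = p99 - p1 if p99 > p1 else 1.0
            out[c] = (intermediate[s][c] - p1) / span
        if clip:
            out = np.clip(out, 0.0, 1.0)
        normalized[s] = out

    return normalized, NormalizationStats(group_stats, channel_percentiles, passthrough)


# ---------------------------------------------------------------------------
# pixel matrix

@dataclass
class PixelMatrix:
    values: np.ndarray          # (n_pixels, n_channels), finite
    provenance: pd.DataFrame    # columns: section, row, col
    channel_names: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pixel matrix contains non-finite values")


def subsample_pixels(
    sections: dict[str, tuple[np.ndarray, np.ndarray]],
    factor: int = 1000,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> PixelMatrix:
    """Draw floor(n_in_mask / factor) in-mask pixels per section without
    replacement and stack them row-wise into a pixel matrix."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    rng = np.random.default_rng(seed)
    rows, provs = [], []
    for sid in sorted(sections):
        stack, mask = sections[sid]
        mask = np.asarray(mask, dtype=bool)
        rr, cc = np.nonzero(mask)
        if rr.size == 0:
            raise ValueError(f"section {sid!r} has no in-mask pixels")
        if factor == 1:
            take = np.arange(rr.size)
        else:
            n_take = rr.size // factor
            take = np.sort(rng.choice(rr.size, size=n_take, replace=False))
        rows.append(stack[:, rr[take], cc[take]].T)
        provs.append(pd.DataFrame({"section": sid, "row": rr[take], "col": cc[take]}))
    values = np.concatenate(rows, axis=0)
    names = channel_names or [f"ch{i}" for i in range(values.shape[1])]
    return PixelMatrix(values, pd.concat(provs, ignore_index=True), names)


# ---------------------------------------------------------------------------
# self-organizing map

@dataclass
class SOMCodebook:
    grid_shape: tuple[int, int]
    node_vectors: np.ndarray        # (n_nodes, n_channels)
    node_counts: np.ndarray         # training pixels per node
    quantization_error: float
    seed: int


def _train_som_once(
    X: np.ndarray, grid: tuple[int, int], seed: int, epochs: int = 20
) -> tuple[np.ndarray, float]:
    """One batch-SOM run: Gaussian neighborhood shrinking linearly over epochs."""
    rng = np.random.default_rng(seed)
    n_nodes = grid[0] * grid[1]
    W = X[rng.choice(X.shape[0], size=n_nodes, replace=False)].copy()

    gr, gc = np.divmod(np.arange(n_nodes), grid[1])
    grid_d2 = (gr[:, None] - gr[None, :]) ** 2 + (gc[:, None] - gc[None, :]) ** 2

    sigma0, sigma1 = max(grid) / 2.0, 0.5
    for e in range(epochs):
        sigma = sigma0 + (sigma1 - sigma0) * (e / max(epochs - 1, 1))
        d = cdist(X, W)
        bmu = np.argmin(d, axis=1)
        S = np.zeros_like(W)
        np.add.at(S, bmu, X)
        n = np.bincount(bmu, minlength=n_nodes).astype(float)
        H = np.exp(-grid_d2 / (2.0 * sigma**2))
        numer = H @ S
        denom = H @ n
        upd = denom > 0
        W[upd] = numer[upd] / denom[upd, None]

    d = cdist(X, W)
    qe = float(d[np.arange(X.shape[0]), np.argmin(d, axis=1)].mean())
    return W, qe


def fit_som(
    matrix: PixelMatrix,
    grid: tuple[int, int] = (30, 30),
    runs: int = 10,
    seed: int = 0,
    epochs: int = 20,
) -> SOMCodebook:
    """Train ``runs`` SOMs (seeds seed..seed+runs-1) and keep the codebook
    with the lowest quantization error."""
    X = np.asarray(matrix.values, dtype=float)
    n_nodes = grid[0] * grid[1]
    if X.shape[0] < n_nodes:
        raise ValueError(
            f"{X.shape[0]} pixels < {n_nodes} nodes; use a smaller grid"
        )
    best: tuple[float, np.ndarray, int] | None = None
    for r in range(runs):
        W, qe = _train_som_once(X, grid, seed + r, epochs=epochs)
        if best is None or qe < best[0]:
            best = (qe, W, seed + r)
    qe, W, used_seed = best
    bmu = np.argmin(cdist(X, W), axis=1)
    counts = np.bincount(bmu, minlength=n_nodes)
    return SOMCodebook(grid, W, counts, qe, used_seed)


# ---------------------------------------------------------------------------
# metaclustering

@dataclass
class MTUModel:
    codebook: SOMCodebook
    node_to_mtu: np.ndarray     # (n_nodes,) int, ids from 1
    n_mtus: int
    mtu_centroids: np.ndarray   # (n_mtus, n_channels)
    chosen_k_neighbors: int
    channel_names: list[str]
    k_sweep_clusters: dict[int, int] = field(default_factory=dict)


def metacluster(
    codebook: SOMCodebook,
    training: PixelMatrix,
    k_sweep: list[int] | None = None,
    seed: int = 0,
    resolution: float = 1.0,
) -> MTUModel:
    """Group SOM nodes into MTUs via kNN-graph Louvain on node medians.

    The neighbor count k is swept and the value at the knee of the
    (k, n_clusters) curve — where adding neighbors stops merging clusters —
    is adopted.  Final MTU ids are ordered by descending member pixel count
    and start at 1.
    """
    if k_sweep is None:
        k_sweep = [5, 10, 15, 20, 25, 30, 35, 40]
    if len(k_sweep) < 3:
        raise ValueError("k_sweep must contain at least 3 values (knee undefined)")
    k_sweep = sorted(k_sweep)

    X = np.asarray(training.values, dtype=float)
    W = codebook.node_vectors
    n_nodes = W.shape[0]
    bmu = np.argmin(cdist(X, W), axis=1)

    medians = W.copy()
    for node in np.unique(bmu):
        medians[node] = np.median(X[bmu == node], axis=0)

    sweep_labels: dict[int, np.ndarray] = {}
    n_clusters: list[int] = []
    for k in k_sweep:
        labels = knn_louvain(medians, k=k, seed=seed)
        sweep_labels[k] = labels
        n_clusters.append(int(labels.max()) + 1)

    knee_idx = kneedle_decreasing(np.asarray(k_sweep, float), np.asarray(n_clusters, float))
    chosen_k = int(k_sweep[knee_idx])
    labels = sweep_labels[chosen_k]

    # order ids by member pixel count, descending; ids contiguous from 1
    node_counts = np.bincount(bmu, minlength=n_nodes)
    sizes = np.bincount(labels, weights=node_counts)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty_like(order)
    remap[order] = np.arange(1, order.size + 1)
    node_to_mtu = remap[labels]

    n_mtus = int(node_to_mtu.max())
    centroids = np.vstack(
        [medians[node_to_mtu == m].mean(axis=0) for m in range(1, n_mtus + 1)]
    )
    return MTUModel(
        codebook=codebook,
        node_to_mtu=node_to_mtu.astype(int),
        n_mtus=n_mtus,
        mtu_centroids=centroids,
        chosen_k_neighbors=chosen_k,
        channel_names=list(training.channel_names),
        k_sweep_clusters=dict(zip(k_sweep, n_clusters)),
    )


# ---------------------------------------------------------------------------
# assignment and summaries

@dataclass
class MTULabelImage:
    labels: np.ndarray      # (H, W) int, 0 outside mask
    section_id: str


def assign_pixels(
    stack: np.ndarray, model: MTUModel, mask: np.ndarray, section_id: str = ""
) -> MTULabelImage:
    """Label every in-mask pixel with the nearest MTU centroid (Euclidean);
    ties go to the lowest MTU id; out-of-mask pixels stay 0."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] != model.mtu_centroids.shape[1]:
        raise ValueError(
            f"stack has {stack.shape[0]} channels, model expects "
            f"{model.mtu_centroids.shape[1]}"
        )
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    rr, cc = np.nonzero(mask)
    if rr.size:
        d = cdist(stack[:, rr, cc].T, model.mtu_centroids)
        labels[rr, cc] = np.argmin(d, axis=1) + 1  # argmin takes first == lowest id
    return MTULabelImage(labels, section_id)


def mtu_summary(label: MTULabelImage, channels: np.ndarray) -> pd.DataFrame:
    """Per-MTU mean channel intensity and member pixel count."""
    lab = label.labels
    channels = np.asarray(channels, dtype=float)
    if channels.shape[1:] != lab.shape:
        raise ValueError("channels and label image shapes disagree")
    ids = np.unique(lab[lab > 0])
    rows = []
    for m in ids:
        sel = lab == m
        rows.append(
            {"mtu": int(m), "count": int(sel.sum()),
             **{f"ch{c}": float(channels[c][sel].mean()) for c in range(channels.shape[0])}}
        )
    return pd.DataFrame(rows)
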