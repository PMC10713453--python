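"""Diffusion embedding, pseudotime and cluster graphs over tissue windows
(Laminator stage 3).

The window-by-window distance matrix is turned into a Markov diffusion
operator (Gaussian kernel with local bandwidths, density-normalized), whose
spectrum gives diffusion components; pseudotime is the distance from a root
window in the eigenvalue-rescaled component space.  Windows are clustered
per timepoint on UMAP embeddings of the components, a maturation score
contrasts compromise distances to the extreme pseudotime quantiles, and a
timepoint-constrained kNN cluster graph summarizes the trajectory.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components


from ._graph import knn_louvain
from ._utils import check_symmetric_zero_diag, moving_mean
from .metrics import CompromiseDistance
from .profiles import ProfileMatrix


@dataclass
class DiffusionResult:
    eigenvalues: np.ndarray         # non-trivial spectrum, descending
    components: np.ndarray          # (W, n_dcs) eigenvectors scaled by eigenvalues
    eigenvectors: np.ndarray        # (W, n_dcs) unscaled right eigenvectors
    k_local: int
    alpha: float = 1.0


@dataclass
class PseudotimeResult:
    pt: np.ndarray                  # (W,) in [0, 1]
    root: int
    method: str = "diffusion-distance"


@dataclass
class WindowClustering:
    labels: pd.DataFrame            # columns: window, timepoint, cluster
    embeddings: dict                # timepoint -> (n_tp, 2) UMAP coordinates
    params: dict


@dataclass
class MaturationScores:
    score: np.ndarray               # (W,) in [-1, 1]
    q: float


@dataclass
class ClusterGraph:
    nodes: pd.DataFrame             # columns: node, timepoint, cluster, size
    edges: pd.DataFrame             # columns: a, b, weight
    layout: np.ndarray              # (n_nodes, 2)
    k: int


# ---------------------------------------------------------------------------

def diffusion_from_distance(
    D: np.ndarray, n_dcs: int = 10, k_local: int = 30, seed: int = 0
) -> DiffusionResult:
    """Diffusion components from a precomputed distance matrix.

    Kernel: K[i,j] = exp(-D[i,j]^2 / (sigma_i sigma_j)) with sigma_i the
    distance to the k_local-th neighbor, density-normalized on both sides
    (alpha = 1), then symmetrically normalized and eigendecomposed.  The
    trivial constant eigenvector is dropped; components are right
    eigenvectors scaled by their eigenvalues.
    """
    D = check_symmetric_zero_diag(D, "distance matrix")
    W = D.shape[0]
    if W <= n_dcs + 1:
        n_dcs = W - 2
    if k_local >= W:
        k_local = max(2, W // 4)

    sortd = np.sort(D, axis=1)
    sigma = sortd[:, k_local]
    sigma = np.where(sigma > 0, sigma, sortd[:, -1] + 1e-12)
    K = np.exp(-(D**2) / np.outer(sigma, sigma))

    n_comp, comp_labels = connected_components(K > 0, directed=False)
    if n_comp > 1:
        sizes = np.bincount(comp_labels).tolist()
        raise ValueError(f"kernel graph is disconnected; component sizes {sizes}")

    q = K.sum(axis=1)
    K1 = K / np.outer(q, q)
    d = K1.sum(axis=1)
    A = K1 / np.sqrt(np.outer(d, d))
    evals, evecs = np.linalg.eigh(A)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    # right eigenvectors of the Markov operator
    u = evecs / np.sqrt(d)[:, None]
    u = u / np.linalg.norm(u, axis=0)
    lam = evals[1 : n_dcs + 1]
    vecs = u[:, 1 : n_dcs + 1]
    return DiffusionResult(
        eigenvalues=lam, components=vecs * lam, eigenvectors=vecs, k_local=k_local
    )


def diffusion_pseudotime(
    dr: DiffusionResult,
    root: int | str = "auto",
    timepoints: np.ndarray | None = None,
) -> PseudotimeResult:
    """Pseudotime as Euclidean distance from a root window in the
    lambda/(1-lambda)-rescaled diffusion space, min-max scaled to [0, 1].

    ``root="auto"`` picks the window of the earliest timepoint with the most
    extreme first-diffusion-component value.
    """
    lam = dr.eigenvalues
    if np.any(lam >= 1 - 1e-12):
        raise ValueError("eigenvalue 1 in the non-trivial spectrum (disconnected graph)")
    M = dr.eigenvectors * (lam / (1.0 - lam))

    if root == "auto":
        dc1 = dr.eigenvectors[:, 0]
        if timepoints is not None:
            timepoints = np.asarray(timepoints)
            cand = np.flatnonzero(timepoints == np.min(timepoints))
        else:
            cand = np.arange(M.shape[0])
        root = int(cand[np.argmax(np.abs(dc1[cand]))])
    root = int(root)

    pt = np.linalg.norm(M - M[root], axis=1)
    span = pt.max() - pt.min()
    pt = (pt - pt.min()) / span if span > 0 else np.zeros_like(pt)
    return PseudotimeResult(pt, root)


def cluster_windows_per_timepoint(
    dr: DiffusionResult,
    timepoints: np.ndarray,
    k_umap: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    n_dcs: int = 10,
) -> WindowClustering:
    """Per timepoint: UMAP on that subset's first diffusion components, then
    Louvain on the kNN graph of the 2-D embedding."""
    import umap

    timepoints = np.asarray(timepoints)
    comps = dr.components[:, :n_dcs]
    rows, embeddings = [], {}
    for tp in sorted(pd.unique(timepoints), key=str):
        idx = np.flatnonzero(timepoints == tp)
        if idx.size < k_umap + 1:
            warnings.warn(f"timepoint {tp!r}: only {idx.size} windows; single cluster")
            labels = np.zeros(idx.size, dtype=int)
            emb = np.zeros((idx.size, 2))
        else:
            reducer = umap.UMAP(n_neighbors=k_umap, n_components=2, random_state=seed)
            emb = reducer.fit_transform(comps[idx])
            labels = knn_louvain(emb, k=k_umap, seed=seed, resolution=resolution)
        embeddings[tp] = emb
        for w, lab in zip(idx, labels):
            rows.append({"window": int(w), "timepoint": tp, "cluster": int(lab)})
    df = pd.DataFrame(rows).sort_values("window").reset_index(drop=True)
    return WindowClustering(
        df, embeddings, {"k_umap": k_umap, "resolution": resolution, "seed": seed}
    )


def maturation_score(
    cd: CompromiseDistance | np.ndarray,
    pt: PseudotimeResult | np.ndarray,
    q: float = 0.05,
    end_set: np.ndarray | None = None,
) -> MaturationScores:
    """Difference of mean compromise distances to the earliest vs latest
    pseudotime quantile sets, min-max scaled to [-1, 1].

    ``end_set`` may override the latest-quantile set (e.g. reference windows
    from a mature tissue)."""
    D = cd.D_plus if isinstance(cd, CompromiseDistance) else np.asarray(cd, float)
    ptv = pt.pt if isinstance(pt, PseudotimeResult) else np.asarray(pt, float)
    lo, hi = np.quantile(ptv, q), np.quantile(ptv, 1 - q)
    start = np.flatnonzero(ptv <= lo)
    end = end_set if end_set is not None else np.flatnonzero(ptv >= hi)
    raw = D[:, start].mean(axis=1) - D[:, end].mean(axis=1)
    span = raw.max() - raw.min()
    if span == 0:
        warnings.warn("all windows equidistant; maturation scores set to 0")
        return MaturationScores(np.zeros_like(raw), q)
    score = 2.0 * (raw - raw.min()) / span - 1.0
    return MaturationScores(score, q)


def build_cluster_graph(
    clustering: WindowClustering,
    timepoint_order: list,
    D_plus: np.ndarray | CompromiseDistance,
    k: int = 4,
    seed: int = 0,
) -> ClusterGraph:
    """Timepoint-constrained kNN graph over window clusters.

    Edges are only allowed between clusters of the same or adjacent
    timepoints; the edge weight is the mean compromise distance between the
    member windows, and each node keeps its k lightest allowed edges
    (union-symmetrized).  Layout is force-directed with attraction
    proportional to 1/weight.
    """
    import igraph as ig

    D = D_plus.D_plus if isinstance(D_plus, CompromiseDistance) else np.asarray(D_plus)
    df = clustering.labels
    tp_rank = {tp: i for i, tp in enumerate(timepoint_order)}

    node_keys = sorted(
        {(r.timepoint, r.cluster) for r in df.itertuples()},
        key=lambda x: (tp_rank[x[0]], x[1]),
    )
    if len(node_keys) < 2:
        raise ValueError("need at least 2 clusters to build a graph")
    members = {
        key: df.loc[(df.timepoint == key[0]) & (df.cluster == key[1]), "window"].to_numpy()
        for key in node_keys
    }
    n = len(node_keys)
    weights = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            if abs(tp_rank[node_keys[i][0]] - tp_rank[node_keys[j][0]]) > 1:
                continue
            mi, mj = members[node_keys[i]], members[node_keys[j]]
            weights[i, j] = weights[j, i] = float(D[np.ix_(mi, mj)].mean())

    edge_set = set()
    for i in range(n):
        allowed = np.flatnonzero(np.isfinite(weights[i]))
        keep = allowed[np.argsort(weights[i, allowed], kind="stable")[:k]]
        for j in keep:
            edge_set.add((min(i, j), max(i, j)))
    edges = sorted(edge_set)

    for a, b in edges:  # hard adjacency assertion
        assert abs(tp_rank[node_keys[a][0]] - tp_rank[node_keys[b][0]]) <= 1

    nodes = pd.DataFrame(
        [
            {"node": i, "timepoint": key[0], "cluster": key[1], "size": len(members[key])}
            for i, key in enumerate(node_keys)
        ]
    )
    edf = pd.DataFrame(
        [{"a": a, "b": b, "weight": weights[a, b]} for a, b in edges]
    )
    g = ig.Graph(n=n, edges=edges, directed=False)
    random.seed(seed)
    if edges:
        attraction = [1.0 / w if w > 0 else 1.0 for w in edf.weight]
        layout = np.asarray(g.layout_fruchterman_reingold(weights=attraction).coords)
    else:
        layout = np.zeros((n, 2))
    return ClusterGraph(nodes, edf, layout, k)


def render_trajectory_heatmap(
    pm: ProfileMatrix,
    pt: PseudotimeResult | np.ndarray,
    feature: int = 0,
    low_q: float = 0.01,
    high_q: float = 0.05,
    smooth_pt: int = 15,
) -> np.ndarray:
    """(positions, windows) display matrix: windows sorted by pseudotime,
    values clip-scaled between the feature's lower ``low_q`` and upper
    ``high_q`` quantiles, mean-filtered along the pseudotime axis."""
    if high_q <= low_q:
        raise ValueError("high_q must exceed low_q")
    ptv = pt.pt if isinstance(pt, PseudotimeResult) else np.asarray(pt, float)
    order = np.argsort(ptv, kind="stable")
    mat = pm.values[order, :, feature].T  # (positions, windows)
    lo = np.nanquantile(mat, low_q)
    hi = np.nanquantile(mat, 1 - high_q)
    span = hi - lo if hi > lo else 1.0
    mat = np.clip((mat - lo) / span, 0.0, 1.0)
    if mat.shape[1] >= smooth_pt:
        mat = moving_mean(mat, smooth_pt, axis=1)
    return mat


def average_trajectory_profile(
    pm: ProfileMatrix, pt: PseudotimeResult | np.ndarray, smooth_avg: int = 25
) -> np.ndarray:
    """(features, windows) position-averaged profiles ordered by pseudotime,
    mean-filtered along the pseudotime axis."""
    ptv = pt.pt if isinstance(pt, PseudotimeResult) else np.asarray(pt, float)
    order = np.argsort(ptv, kind="stable")
    mat = np.nanmean(pm.values[order], axis=1).T  # (features, windows)
    if mat.shape[1] >= smooth_avg:
        mat = moving_mean(mat, smooth_avg, axis=1)
    return mat
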