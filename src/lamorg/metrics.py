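"""Profile distances and the DISTATIS compromise (Laminator stage 2).

Window profiles are harmonized (reverse z-scoring per section/timepoint
group), smoothed and downsampled, then compared per feature by the
Euclidean distance between their first Fourier coefficients.  The
per-feature distance matrices are fused into a single compromise distance
by DISTATIS: each matrix is double-centered into a cross-product matrix,
eigenvalue-normalized, weighted by the first eigenvector of their RV
coefficient matrix, summed, and back-transformed to a distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._utils import check_symmetric_zero_diag, moving_mean
from .profiles import ProfileMatrix


@dataclass
class FeatureDistanceSet:
    matrices: np.ndarray        # (n_features, W, W), symmetric, zero diagonal
    feature_names: list[str]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != m.shape[2]:
            raise ValueError("matrices must be (features, W, W)")
        self.matrices = m

    @property
    def n_items(self) -> int:
        return self.matrices.shape[1]


@dataclass
class CompromiseDistance:
    D_plus: np.ndarray          # (W, W) compromise distance
    alpha: np.ndarray           # per-feature weights, sum 1
    rv_matrix: np.ndarray       # feature x feature RV coefficients
    feature_names: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------

def normalize_profiles(
    pm: ProfileMatrix, group_keys: tuple[str, ...] = ("section", "timepoint")
) -> ProfileMatrix:
    """Reverse z-score profiles per feature within (section, timepoint)
    groups, then min-max scale each feature to [0, 1] across all windows.

    Each window's profile is z-scored with its own mean/sd and rescaled by
    the pooled sd/mean of its group, harmonizing windows while preserving
    group-level contrasts.  Constant windows pass through flagged; a feature
    constant across all windows is set to 0.5.
    """
    out = pm.copy()
    vals = out.values
    groups = out.meta.groupby(list(group_keys), dropna=False, sort=False).indices
    flagged_windows: list[tuple[object, int]] = []
    constant_features: list[str] = []

    for f in range(pm.n_features):
        for gkey, idx in groups.items():
            idx = np.asarray(idx)
            block = vals[idx, :, f]
            if idx.size < 2:
                out.flags.setdefault("small_groups", []).append((gkey, pm.feature_names[f]))
                continue
            gmu = float(np.nanmean(block))
            gsd = float(np.nanstd(block))
            for i in idx:
                prof = vals[i, :, f]
                mu, sd = np.nanmean(prof), np.nanstd(prof)
                if sd == 0 or not np.isfinite(sd):
                    flagged_windows.append((gkey, int(i)))
                    continue
                vals[i, :, f] = (prof - mu) / sd * gsd + gmu
        fv = vals[:, :, f]
        lo, hi = np.nanmin(fv), np.nanmax(fv)
        if hi > lo:
            vals[:, :, f] = (fv - lo) / (hi - lo)
        else:
            vals[:, :, f] = 0.5
            constant_features.append(pm.feature_names[f])
    if flagged_windows:
        out.flags["constant_windows"] = flagged_windows
    if constant_features:
        out.flags["constant_features"] = constant_features
    return out


def smooth_downsample(pm: ProfileMatrix, mean_window: int = 20, factor: int = 2) -> ProfileMatrix:
    """Centered moving-mean filter along the position axis (edge-truncated
    windows), then keep every factor-th position.  Missing positions are
    imputed from the nearest valid position first, so the output is complete.
    """
    if mean_window > pm.n_positions:
        raise ValueError(
            f"mean_window {mean_window} exceeds profile length {pm.n_positions}"
        )
    out = pm.copy()
    vals = out.values
    # nearest-valid imputation along positions
    for i in range(vals.shape[0]):
        for f in range(vals.shape[2]):
            prof = vals[i, :, f]
            bad = ~np.isfinite(prof)
            if bad.any():
                if bad.all():
                    prof[:] = 0.0
                else:
                    pos = np.arange(prof.size)
                    prof[bad] = np.interp(pos[bad], pos[~bad], prof[~bad])
    smoothed = moving_mean(vals, mean_window, axis=1)
    out.values = smoothed[:, ::factor, :]
    return out


def fft_distance(
    pm: ProfileMatrix, n_components: int = 10, magnitude_only: bool = False
) -> FeatureDistanceSet:
    """Per-feature pairwise Euclidean distances between the first
    ``n_components`` Fourier coefficients of the profiles (DC included).

    Complex coefficients are compared jointly in real and imaginary parts by
    default; ``magnitude_only`` compares their moduli instead.
    """
    vals = pm.values
    if not np.all(np.isfinite(vals)):
        raise ValueError("profiles contain missing values; smooth/impute first")
    n_avail = vals.shape[1] // 2 + 1
    if n_components > n_avail:
        raise ValueError(f"n_components {n_components} > available {n_avail}")
    mats = np.empty((pm.n_features, pm.n_windows, pm.n_windows))
    for f in range(pm.n_features):
        F = np.fft.rfft(vals[:, :, f], axis=1)[:, :n_components]
        if magnitude_only:
            feats = np.abs(F)
        else:
            feats = np.column_stack([F.real, F.imag])
        mats[f] = squareform(pdist(feats))
    return FeatureDistanceSet(mats, list(pm.feature_names))


# ---------------------------------------------------------------------------
# DISTATIS

def _double_center(D: np.ndarray) -> np.ndarray:
    """Cross-product matrix S = -1/2 C D^2 C with uniform masses."""
    W = D.shape[0]
    C = np.eye(W) - np.ones((W, W)) / W
    return -0.5 * C @ (D**2) @ C


def _rv(S1: np.ndarray, S2: np.ndarray) -> float:
    num = np.sum(S1 * S2)
    den = np.sqrt(np.sum(S1 * S1) * np.sum(S2 * S2))
    return float(num / den) if den > 0 else 0.0


def distatis(ds: FeatureDistanceSet) -> CompromiseDistance:
    """Fuse per-feature distance matrices into a compromise distance.

    Steps: double-center squared distances to cross-products, normalize each
    by its leading eigenvalue, weight by the first eigenvector of the RV
    coefficient matrix (rescaled to sum 1), sum, and back-transform the
    compromise cross-product to a distance matrix.
    """
    K = ds.matrices.shape[0]
    if K < 2:
        raise ValueError("DISTATIS needs at least 2 feature distance matrices")
    W = ds.n_items
    S_tilde = np.empty((K, W, W))
    for f in range(K):
        D = check_symmetric_zero_diag(ds.matrices[f], f"distance matrix {f}")
        S = _double_center(D)
        ev = np.linalg.eigvalsh(S)[-1]
        S_tilde[f] = S / ev if ev > 0 else S

    R = np.empty((K, K))
    for i in range(K):
        for j in range(i, K):
            R[i, j] = R[j, i] = _rv(S_tilde[i], S_tilde[j])

    evals, evecs = np.linalg.eigh(R)
    v = evecs[:, -1]
    if v.sum() < 0:
        v = -v
    alpha = v / v.sum()

    S_plus = np.tensordot(alpha, S_tilde, axes=1)
    diag = np.diag(S_plus)
    D2 = diag[:, None] + diag[None, :] - 2.0 * S_plus
    if (D2 < -1e-10).any():
        warnings.warn("negative squared compromise distances clamped to 0")
    D_plus = np.sqrt(np.clip(D2, 0.0, None))
    np.fill_diagonal(D_plus, 0.0)
    return CompromiseDistance(D_plus, alpha, R, list(ds.feature_names))


def aggregate_log_distance(ds: FeatureDistanceSet, how: str = "mean") -> np.ndarray:
    """log10(D + 1)-transformed distances aggregated across features."""
    logs = np.log10(ds.matrices + 1.0)
    if how == "mean":
        return logs.mean(axis=0)
    if how == "sum":
        return logs.sum(axis=0)
    raise ValueError("how must be 'mean' or 'sum'")
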