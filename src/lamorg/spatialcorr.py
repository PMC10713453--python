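"""Section-level spatial correlation of nuclei-resolved features.

Every per-nucleus numeric feature is rendered into a smooth 200 x 200
density grid by a feature-weighted bivariate normal kernel density
estimate; an occupancy mask (thresholded unweighted nuclei density)
restricts comparisons to tissue-occupied grid cells, on which Pearson
correlations against a target feature are computed and averaged across
sections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class DensityGrid:
    grid: np.ndarray                    # (G, G) nonnegative density
    extent: tuple[float, float, float, float]   # (row_min, row_max, col_min, col_max)
    bandwidths: tuple[float, float]
    feature: str = ""
    section_id: str = ""


def _normal_reference_bandwidth(x: np.ndarray) -> float:
    """Silverman's normal-reference rule: 1.06 min(sd, IQR/1.34) n^(-1/5)."""
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 1.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(sd, 1.0)
    return float(1.06 * spread * n ** (-1 / 5))


def feature_density(
    centroids: np.ndarray,
    weights: np.ndarray | None = None,
    grid_size: int = 200,
    extent: tuple[float, float, float, float] | None = None,
    bandwidths: tuple[float, float] | None = None,
    feature: str = "",
    section_id: str = "",
) -> DensityGrid:
    """Feature-weighted 2-D KDE with an axis-aligned bivariate normal kernel.

    Each centroid contributes a Gaussian scaled by its (nonnegative) feature
    value; negative weights are shifted up to zero and the shift recorded on
    the result.  Bandwidths default to the per-axis normal-reference rule on
    the point coordinates.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] < 5:
        raise ValueError("need at least 5 nuclei for a density estimate")
    if weights is None:
        weights = np.ones(centroids.shape[0])
    weights = np.asarray(weights, dtype=float)
    shift = 0.0
    if weights.min() < 0:
        shift = -float(weights.min())
        weights = weights + shift
    total = weights.sum()
    if total <= 0:
        raise ValueError("zero total weight")

    if extent is None:
        extent = (
            centroids[:, 0].min(), centroids[:, 0].max(),
            centroids[:, 1].min(), centroids[:, 1].max(),
        )
    if bandwidths is None:
        bandwidths = (
            _normal_reference_bandwidth(centroids[:, 0]),
            _normal_reference_bandwidth(centroids[:, 1]),
        )
    hr, hc = bandwidths
    gr = np.linspace(extent[0], extent[1], grid_size)
    gc = np.linspace(extent[2], extent[3], grid_size)

    # separable Gaussian kernels: grid = Kr @ diag(w) @ Kc.T
    Kr = np.exp(-0.5 * ((gr[:, None] - centroids[None, :, 0]) / hr) ** 2) / (
        hr * np.sqrt(2 * np.pi)
    )
    Kc = np.exp(-0.5 * ((gc[:, None] - centroids[None, :, 1]) / hc) ** 2) / (
        hc * np.sqrt(2 * np.pi)
    )
    grid = (Kr * weights[None, :]) @ Kc.T
    dg = DensityGrid(grid, extent, (float(hr), float(hc)), feature, section_id)
    dg.weight_shift = shift
    return dg


def occupancy_mask(
    centroids: np.ndarray,
    grid_size: int = 200,
    extent: tuple[float, float, float, float] | None = None,
    threshold: float = 0.05,
) -> np.ndarray:
    """Binary tissue-occupancy grid: unweighted nuclei-position KDE rescaled
    to max 1 and thresholded."""
    dg = feature_density(centroids, None, grid_size=grid_size, extent=extent)
    scaled = dg.grid / dg.grid.max()
    return scaled > threshold


def spatial_correlation(
    target: DensityGrid | np.ndarray,
    other: DensityGrid | np.ndarray,
    mask: np.ndarray,
) -> float:
    """Pearson correlation of two density grids over masked cells; NaN when
    either grid is constant under the mask."""
    a = target.grid if isinstance(target, DensityGrid) else np.asarray(target)
    b = other.grid if isinstance(other, DensityGrid) else np.asarray(other)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError("grids and mask must share shape")
    if mask.sum() < 10:
        raise ValueError("fewer than 10 masked grid cells")
    x, y = a[mask], b[mask]
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class SpatialCorrelationTable:
    per_section: pd.DataFrame   # columns: feature, section, r
    mean_r: pd.Series           # feature -> mean r across sections
    top_positive: list[str]
    top_negative: list[str]


def rank_correlates(
    target_feature: str,
    sections: dict[str, tuple[np.ndarray, pd.DataFrame]],
    grid_size: int = 200,
    threshold: float = 0.05,
    top_n: int = 115,
) -> SpatialCorrelationTable:
    """Rank features by mean masked spatial correlation with a target.

    ``sections`` maps section id to (centroids, feature table); every numeric
    column of the table is a candidate feature.  Sections missing the target
    or a feature are skipped for that feature.
    """
    rows = []
    for sid, (centroids, feats) in sorted(sections.items()):
        if target_feature not in feats:
            continue
        mask = occupancy_mask(centroids, grid_size=grid_size, threshold=threshold)
        tgt = feature_density(
            centroids, feats[target_feature].to_numpy(), grid_size=grid_size,
            feature=target_feature, section_id=sid,
        )
        tgrid = tgt.grid * mask
        for col in feats.columns:
            if not np.issubdtype(feats[col].dtype, np.number):
                continue
            dg = feature_density(
                centroids, feats[col].to_numpy(), grid_size=grid_size,
                feature=col, section_id=sid,
            )
            r = spatial_correlation(tgrid, dg.grid * mask, mask)
            rows.append({"feature": col, "section": sid, "r": r})
    per_section = pd.DataFrame(rows)
    if per_section.empty:
        raise ValueError(f"target feature {target_feature!r} found in no section")
    mean_r = per_section.groupby("feature")["r"].mean().sort_values(ascending=False)
    top_positive = mean_r.head(top_n).index.tolist()
    top_negative = mean_r.tail(top_n).index[::-1].tolist()
    return SpatialCorrelationTable(per_section, mean_r, top_positive, top_negative)
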