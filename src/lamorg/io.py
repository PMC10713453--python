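"""Manifests, run configuration, section reading and portable outputs.

Images are TIFF (multi-page stacks for channels, integer label TIFFs for
nuclei/MTU labels), tables are UTF-8 delimited text with a JSON sidecar
declaring the column schema, arrays are ``.npz`` archives with a JSON
sidecar naming the axes, and the fitted MTU model is a single ``.npz``
archive.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .mtu import MTUModel, SOMCodebook


@dataclass
class RunConfig:
    """Every tunable of the pipeline, with the defaults used throughout."""

    seed: int = 0
    pixel_size_um: float = 0.1625
    # mask / contour / distance map
    mask_dilation_radius: int = 5
    contour_sigma: float = 50.0
    dmap_sigma: float = 25.0
    # windows
    stride: int = 100
    window_width_px: int = 100
    window_length_px: int = 1000
    orient_coarse_step_deg: float = 2.0
    orient_refine_step_deg: float = 0.5
    orient_search_deg: float = 90.0
    min_valid_fraction: float = 0.99
    straightness_threshold: float | None = None
    # MTU
    som_grid: tuple[int, int] = (30, 30)
    som_runs: int = 10
    subsample_factor: int = 1000
    k_sweep: tuple[int, ...] = (5, 10, 15, 20, 25, 30, 35, 40)
    # metrics
    profile_mean_window: int = 20
    downsample_factor: int = 2
    fft_components: int = 10
    aggregate: str = "mean"
    # trajectory
    n_dcs: int = 10
    k_local: int = 30
    k_umap: int = 15
    louvain_resolution: float = 1.0
    graph_k: int = 4
    maturation_q: float = 0.05
    heatmap_smooth_pt: int = 15
    heatmap_smooth_avg: int = 25
    # neighborhoods / spatial correlation
    radial_extension_px: int = 40
    density_kernel: tuple[int, int] = (100, 100)
    kde_grid: int = 200
    occupancy_threshold: float = 0.05
    top_n_correlates: int = 115

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("som_grid", "k_sweep", "density_kernel"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


MANIFEST_COLUMNS = [
    "section_id", "sample_id", "timepoint_label", "timepoint", "pixel_size_um",
    "channels_path", "mask_path", "nuclei_path", "mtu_path", "channel_names",
]


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a tab-delimited section manifest."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"section_id": str, "sample_id": str})
    missing = [c for c in ("section_id", "timepoint", "pixel_size_um", "channels_path", "mask_path") if c not in df]
    if missing:
        raise ValueError(f"manifest missing columns: {missing}")
    if df.section_id.duplicated().any():
        raise ValueError("manifest has duplicate section ids")
    if (df.pixel_size_um <= 0).any():
        raise ValueError("pixel_size_um must be > 0")
    base = path.parent
    for col in ("channels_path", "mask_path", "nuclei_path", "mtu_path"):
        if col not in df:
            continue
        for p in df[col].dropna():
            if not (base / p).exists() and not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


@dataclass
class ImageSection:
    section_id: str
    channels: np.ndarray            # (C, H, W) float
    mask: np.ndarray                # (H, W) bool
    timepoint: object = 0
    pixel_size_um: float = 0.1625
    channel_names: list[str] = field(default_factory=list)
    nuclei_labels: np.ndarray | None = None
    mtu_labels: np.ndarray | None = None


def _resolve(base: Path, p: str) -> Path:
    q = Path(p)
    return q if q.exists() else base / p


def read_section(row: pd.Series, base: str | Path = ".") -> ImageSection:
    """Load one manifest row into an in-memory section."""
    base = Path(base)
    try:
        channels = tifffile.imread(_resolve(base, row.channels_path)).astype(float)
    except Exception as exc:
        raise IOError(f"cannot read channel stack {row.channels_path}: {exc}") from exc
    if channels.ndim == 2:
        channels = channels[None]
    mask = tifffile.imread(_resolve(base, row.mask_path)).astype(bool)
    if mask.shape != channels.shape[1:]:
        raise ValueError(
            f"section {row.section_id}: mask shape {mask.shape} does not match "
            f"channels {channels.shape[1:]}"
        )
    names = []
    if "channel_names" in row and isinstance(row.channel_names, str):
        names = row.channel_names.split(",")
        if len(names) != channels.shape[0]:
            raise ValueError(f"section {row.section_id}: channel name count mismatch")
    sec = ImageSection(
        section_id=str(row.section_id),
        channels=channels,
        mask=mask,
        timepoint=row.timepoint,
        pixel_size_um=float(row.pixel_size_um),
        channel_names=names,
    )
    for attr, col in (("nuclei_labels", "nuclei_path"), ("mtu_labels", "mtu_path")):
        if col in row and isinstance(row[col], str) and row[col]:
            lab = tifffile.imread(_resolve(base, row[col]))
            if lab.shape != mask.shape:
                raise ValueError(f"section {row.section_id}: {col} shape mismatch")
            setattr(sec, attr, lab.astype(np.int32))
    return sec


# ---------------------------------------------------------------------------
# writers

def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Delimited table plus a JSON sidecar declaring the column schema."""
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    schema = {c: str(df[c].dtype) for c in df.columns}
    path.with_suffix(path.suffix + ".schema.json").write_text(json.dumps(schema, indent=1))


def write_arrays(path: str | Path, axes: dict[str, list[str]], **arrays: np.ndarray) -> None:
    """npz archive plus a JSON sidecar naming each array's axes."""
    path = Path(path)
    np.savez_compressed(path, **arrays)
    meta = {name: axes.get(name, []) for name in arrays}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def write_label_tiff(path: str | Path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label value exceeds 16-bit range")
    tifffile.imwrite(path, labels.astype(np.uint16))


def save_mtu_model(path: str | Path, model: MTUModel) -> None:
    np.savez_compressed(
        path,
        grid_shape=np.asarray(model.codebook.grid_shape),
        node_vectors=model.codebook.node_vectors,
        node_counts=model.codebook.node_counts,
        quantization_error=np.asarray(model.codebook.quantization_error),
        som_seed=np.asarray(model.codebook.seed),
        node_to_mtu=model.node_to_mtu,
        mtu_centroids=model.mtu_centroids,
        chosen_k_neighbors=np.asarray(model.chosen_k_neighbors),
        channel_names=np.asarray(model.channel_names),
    )


def load_mtu_model(path: str | Path) -> MTUModel:
    with np.load(path, allow_pickle=False) as z:
        codebook = SOMCodebook(
            grid_shape=tuple(int(x) for x in z["grid_shape"]),
            node_vectors=z["node_vectors"],
            node_counts=z["node_counts"],
            quantization_error=float(z["quantization_error"]),
            seed=int(z["som_seed"]),
        )
        return MTUModel(
            codebook=codebook,
            node_to_mtu=z["node_to_mtu"],
            n_mtus=int(z["node_to_mtu"].max()),
            mtu_centroids=z["mtu_centroids"],
            chosen_k_neighbors=int(z["chosen_k_neighbors"]),
            channel_names=[str(s) for s in z["channel_names"]],
        )
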