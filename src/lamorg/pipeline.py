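"""End-to-end pipeline: sections -> MTUs -> laminar windows -> distances ->
trajectory, with every numeric output reproducible from one global seed."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics, mtu, trajectory, windows
from ._utils import stage_seed
from .io import (
    ImageSection,
    RunConfig,
    load_mtu_model,
    read_manifest,
    read_section,
    save_mtu_model,
    write_arrays,
    write_table,
)

log = logging.getLogger("lamorg")


def run_pipeline(
    manifest: str | Path | pd.DataFrame | list[ImageSection],
    config: RunConfig,
    outdir: str | Path,
) -> Path:
    """Run all stages on the manifest's sections and persist every result.

    Writes the window table, profile arrays, per-feature and compromise
    distances, pseudotime/maturation tables, the cluster-graph edge list,
    the echoed config and a log of stage seeds and timings.  Re-running with
    identical inputs and seed reproduces the numeric outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    runlog: dict = {"seed": config.seed, "stages": {}}

    if isinstance(manifest, list):
        sections = manifest
    else:
        df = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
        base = Path(manifest).parent if isinstance(manifest, (str, Path)) else Path(".")
        sections = [read_section(row, base) for _, row in df.iterrows()]
    if not sections:
        raise ValueError("no sections to process")

    # --- stage: normalization -------------------------------------------
    t0 = time.time()
    stacks = {s.section_id: s.channels for s in sections}
    tps = {s.section_id: s.timepoint for s in sections}
    try:
        normalized, _stats = mtu.reverse_zscore_normalize(stacks, tps)
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc
    for s in sections:
        s.channels = normalized[s.section_id]
    runlog["stages"]["normalize"] = {"seconds": time.time() - t0}

    # --- stage: MTU model ------------------------------------------------
    t0 = time.time()
    model_path = outdir / "mtu_model.npz"
    seed_mtu = stage_seed(config.seed, "mtu")
    if model_path.exists():
        model = load_mtu_model(model_path)
        runlog["stages"]["mtu_fit"] = {"reused": True}
    else:
        try:
            pix = mtu.subsample_pixels(
                {s.section_id: (s.channels, s.mask) for s in sections},
                factor=config.subsample_factor,
                seed=seed_mtu,
            )
            codebook = mtu.fit_som(
                pix, grid=config.som_grid, runs=config.som_runs, seed=seed_mtu
            )
            model = mtu.metacluster(codebook, pix, list(config.k_sweep), seed=seed_mtu)
        except Exception as exc:
            raise RuntimeError(f"stage 'mtu_fit' failed: {exc}") from exc
        save_mtu_model(model_path, model)
        runlog["stages"]["mtu_fit"] = {
            "reused": False, "seed": seed_mtu, "n_mtus": model.n_mtus,
            "chosen_k": model.chosen_k_neighbors, "seconds": time.time() - t0,
        }
        log.info("fitted MTU model: %d MTUs at k=%d", model.n_mtus, model.chosen_k_neighbors)

    for s in sections:
        if s.mtu_labels is None:
            s.mtu_labels = mtu.assign_pixels(
                s.channels, model, s.mask, s.section_id
            ).labels

    # --- stage: windows ---------------------------------------------------
    t0 = time.time()
    all_pms, all_ws = [], []
    for s in sections:
        try:
            contour = windows.extract_contour(s.mask, config.contour_sigma, s.section_id)
            dmap = windows.distance_map(s.mask, config.dmap_sigma)
            ws = windows.place_windows(
                contour, dmap, config.stride,
                config.window_width_px, config.window_length_px,
            )
            ws.timepoint = s.timepoint
            ws.pixel_size_um = s.pixel_size_um
            windows.orient_windows(
                ws, dmap,
                coarse_step_deg=config.orient_coarse_step_deg,
                refine_step_deg=config.orient_refine_step_deg,
                search_deg=config.orient_search_deg,
            )
            pm = windows.extract_profiles(
                ws, channels=s.channels, channel_names=s.channel_names or None,
                mtu_labels=s.mtu_labels, n_mtus=model.n_mtus, mask=s.mask,
            )
            ws, pm = windows.filter_windows(
                ws, pm, config.min_valid_fraction, config.straightness_threshold
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'windows' failed on {s.section_id}: {exc}") from exc
        all_ws.append(ws)
        all_pms.append(pm)
    pm = _concat_profiles(all_pms)
    write_table(pm.meta, outdir / "windows.tsv")
    runlog["stages"]["windows"] = {
        "seconds": time.time() - t0, "n_windows": pm.n_windows,
    }

    # --- stage: distances -------------------------------------------------
    t0 = time.time()
    try:
        pmn = metrics.normalize_profiles(pm)
        pms = metrics.smooth_downsample(
            pmn, config.profile_mean_window, config.downsample_factor
        )
        ds = metrics.fft_distance(pms, config.fft_components)
        cd = metrics.distatis(ds)
        D_agg = metrics.aggregate_log_distance(ds, config.aggregate)
    except Exception as exc:
        raise RuntimeError(f"stage 'distances' failed: {exc}") from exc
    write_arrays(
        outdir / "distances.npz",
        axes={
            "profiles": ["window", "position", "feature"],
            "feature_distances": ["feature", "window", "window"],
            "compromise": ["window", "window"],
            "aggregated": ["window", "window"],
            "alpha": ["feature"],
        },
        profiles=pms.values,
        feature_distances=ds.matrices,
        compromise=cd.D_plus,
        aggregated=D_agg,
        alpha=cd.alpha,
    )
    runlog["stages"]["distances"] = {"seconds": time.time() - t0}

    # --- stage: trajectory ------------------------------------------------
    t0 = time.time()
    seed_tr = stage_seed(config.seed, "trajectory")
    tp = pm.meta["timepoint"].to_numpy()
    try:
        dr = trajectory.diffusion_from_distance(
            D_agg, n_dcs=config.n_dcs, k_local=config.k_local, seed=seed_tr
        )
        pt = trajectory.diffusion_pseudotime(dr, root="auto", timepoints=tp)
        clustering = trajectory.cluster_windows_per_timepoint(
            dr, tp, k_umap=config.k_umap,
            resolution=config.louvain_resolution, seed=seed_tr,
        )
        scores = trajectory.maturation_score(cd, pt, q=config.maturation_q)
        graph = trajectory.build_cluster_graph(
            clustering, sorted(pd.unique(tp)), cd, k=config.graph_k, seed=seed_tr
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'trajectory' failed: {exc}") from exc

    table = pm.meta.copy()
    table["pseudotime"] = pt.pt
    table["maturation_score"] = scores.score
    table = table.merge(
        clustering.labels[["window", "cluster"]].rename(columns={"window": "_w"}),
        left_index=True, right_on="_w", how="left",
    ).drop(columns="_w")
    for i in range(dr.components.shape[1]):
        table[f"dc{i + 1}"] = dr.components[:, i]
    write_table(table, outdir / "pseudotime.tsv")
    write_table(graph.nodes, outdir / "cluster_graph_nodes.tsv")
    edges = graph.edges.copy()
    write_table(edges, outdir / "cluster_graph_edges.tsv")
    np.savetxt(outdir / "cluster_graph_layout.tsv", graph.layout, delimiter="\t")
    runlog["stages"]["trajectory"] = {
        "seconds": time.time() - t0, "seed": seed_tr, "root": pt.root,
    }

    (outdir / "run_log.json").write_text(json.dumps(runlog, indent=1))
    return outdir


def _concat_profiles(pms: list) -> "metrics.ProfileMatrix":
    from .profiles import ProfileMatrix

    names = pms[0].feature_names
    for p in pms[1:]:
        if p.feature_names != names:
            raise ValueError("sections produced differing feature sets")
    values = np.concatenate([p.values for p in pms], axis=0)
    meta = pd.concat([p.meta for p in pms], ignore_index=True)
    meta["window"] = np.arange(len(meta))
    return ProfileMatrix(values, meta, list(names))
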