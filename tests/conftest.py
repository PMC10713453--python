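"""Shared fixtures: phantom sections and the laminar-window analysis chain.

Heavy fixtures are session-scoped so the trajectory chain is computed once
and shared between the module tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from lamorg import metrics, mtu, trajectory
from lamorg import windows as W
from lamorg.phantom import (
    PhantomSpec,
    default_timecourse_specs,
    four_class_spec,
    make_phantom_section,
    make_phantom_timecourse,
)
from lamorg.pipeline import _concat_profiles


@pytest.fixture(scope="session")
def small_section():
    """A 256 px wobbled-ellipse section with moderate noise."""
    return make_phantom_section(
        PhantomSpec(image_size=(256, 256), seed=7, n_nuclei=40)
    )


@pytest.fixture(scope="session")
def four_class_section():
    """Four well-separated pixel classes (plateau depth bands)."""
    return make_phantom_section(four_class_spec(seed=3))


@pytest.fixture(scope="session")
def mtu_model(four_class_section):
    """SOM + metaclustering fitted on the four-class section."""
    sec = four_class_section
    pix = mtu.subsample_pixels({"s0": (sec.channels, sec.mask)}, factor=10, seed=3)
    codebook = mtu.fit_som(pix, grid=(10, 10), runs=10, seed=3)
    model = mtu.metacluster(codebook, pix, [5, 10, 15, 20, 25, 30, 35, 40], seed=3)
    return pix, codebook, model


def run_laminator_chain(sections, width_px=50, length_px=200, n_windows=60,
                        contour_sigma=5.0, dmap_sigma=5.0, min_valid=0.5):
    """Windows -> profiles -> distances for a list of phantom sections."""
    pms = []
    for sec in sections:
        contour = W.extract_contour(sec.mask, sigma=contour_sigma)
        dmap = W.distance_map(sec.mask, sigma=dmap_sigma)
        stride = max(1, len(contour) // n_windows)
        ws = W.place_windows(contour, dmap, stride=stride,
                             width_px=width_px, length_px=length_px)
        ws.timepoint = sec.timepoint if sec.timepoint is not None else 0
        W.orient_windows(ws, dmap)
        pm = W.extract_profiles(ws, channels=sec.channels, mask=sec.mask)
        ws, pm = W.filter_windows(ws, pm, min_valid=min_valid)
        pms.append(pm)
    return _concat_profiles(pms)


@pytest.fixture(scope="session")
def timecourse_chain():
    """Full Laminator run on the 5-timepoint phantom series.

    Returns (profiles, feature distances, compromise, aggregated distance,
    diffusion result, pseudotime, maturation scores, timepoints).
    """
    specs = default_timecourse_specs(5, image_size=(256, 256), seed=10)
    sections = make_phantom_timecourse(specs)
    pm = run_laminator_chain(sections)
    pmn = metrics.normalize_profiles(pm)
    pms = metrics.smooth_downsample(pmn, 20, 2)
    ds = metrics.fft_distance(pms, 10)
    cd = metrics.distatis(ds)
    D = metrics.aggregate_log_distance(ds)
    tp = pm.meta["timepoint"].to_numpy()
    dr = trajectory.diffusion_from_distance(D, n_dcs=10, k_local=30)
    pt = trajectory.diffusion_pseudotime(dr, "auto", timepoints=tp)
    sc = trajectory.maturation_score(cd, pt, q=0.05)
    return {
        "pm": pm, "pm_smooth": pms, "ds": ds, "cd": cd, "D": D,
        "dr": dr, "pt": pt, "scores": sc, "tp": tp,
    }
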