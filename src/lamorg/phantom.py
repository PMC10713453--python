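"""Synthetic organoid-section phantoms with known ground truth.

A phantom section is a wobbled ellipse of "tissue" whose multi-channel
intensities are exact functions of normalized depth (Euclidean distance to
the tissue boundary, scaled to [0, 1]).  Layers are Gaussian bumps on that
depth axis whose per-channel amplitudes interpolate linearly between a
t = 0 and a t = 1 state, so a single scalar ``maturation_t`` moves the
section from unstructured to laminated.  Every downstream stage (pixel
clustering, window orientation, profile trajectories, radial neighborhoods)
can therefore be tested against closed forms: the analytic boundary normal,
the analytic depth profile, the generating pixel class and the planted
nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class LayerDef:
    """One Gaussian layer on the normalized depth axis.

    ``center_frac``/``width_frac`` are the bump mean and sd in units of
    normalized depth (0 = boundary, 1 = deepest point).  ``amp_t0`` and
    ``amp_t1`` give the per-channel amplitude at maturation 0 and 1; the
    amplitude at maturation t is their linear interpolation.

    ``class_id`` groups layers into one ground-truth pixel class (several
    narrow sublayers sharing a signature form a plateau band); it defaults
    to the layer's own 1-based index.
    """

    center_frac: float
    width_frac: float
    amp_t0: tuple[float, ...]
    amp_t1: tuple[float, ...]
    class_id: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.center_frac <= 1) or not (0 < self.width_frac <= 1):
            raise ValueError("layer center/width fractions must be in (0, 1]")
        if len(self.amp_t0) != len(self.amp_t1):
            raise ValueError("amp_t0 and amp_t1 must have equal channel counts")
        if min(self.amp_t0) < 0 or min(self.amp_t1) < 0:
            raise ValueError("layer amplitudes must be >= 0")

    def amplitude(self, t: float) -> np.ndarray:
        return (1.0 - t) * np.asarray(self.amp_t0) + t * np.asarray(self.amp_t1)


@dataclass(frozen=True)
class PhantomSpec:
    image_size: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.1625
    n_channels: int = 4
    maturation_t: float = 0.5
    layer_defs: tuple[LayerDef, ...] = ()
    center: tuple[float, float] | None = None
    radii: tuple[float, float] | None = None
    wobble_amp: float = 0.08
    wobble_freq: int = 5
    n_nuclei: int = 150
    nucleus_radius: float = 4.0
    noise_sd: float = 0.05
    poisson_like: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 128 or w < 128:
            raise ValueError("image_size must be at least 128 x 128")
        if not self.layer_defs:
            object.__setattr__(self, "layer_defs", _default_layers(self.n_channels))
        for ld in self.layer_defs:
            if len(ld.amp_t0) != self.n_channels:
                raise ValueError("layer amplitude length must equal n_channels")
        if not (0.0 <= self.maturation_t <= 1.0):
            raise ValueError("maturation_t must lie in [0, 1]")
        if self.center is None:
            object.__setattr__(self, "center", ((h - 1) / 2.0, (w - 1) / 2.0))
        if self.radii is None:
            base = 0.40 * min(h, w)
            object.__setattr__(self, "radii", (base, 0.85 * base))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _default_layers(n_channels: int) -> tuple[LayerDef, ...]:
    """Four equispaced layers; uniform at t = 0, channel-specific at t = 1."""
    centers = (0.2, 0.4, 0.6, 0.8)
    layers = []
    for i, mu in enumerate(centers):
        amp0 = tuple(0.5 for _ in range(n_channels))
        amp1 = tuple(1.0 if c == i % n_channels else 0.1 for c in range(n_channels))
        layers.append(LayerDef(mu, 0.08, amp0, amp1))
    return tuple(layers)


@dataclass
class PhantomSection:
    channels: np.ndarray            # (C, H, W) noisy intensities, >= 0
    clean_channels: np.ndarray      # (C, H, W) noise-free field
    mask: np.ndarray                # (H, W) bool
    pixel_class: np.ndarray         # (H, W) int, 0 outside mask
    depth: np.ndarray               # (H, W) normalized depth in [0, 1]
    nuclei_centroids: np.ndarray    # (N, 2) float (row, col)
    nuclei_labels: np.ndarray       # (H, W) int
    maturation_t: float
    contour_truth: np.ndarray       # (M, 2) closed polyline (row, col)
    spec: PhantomSpec
    timepoint: int | None = None

    def inward_normal(self, point: Sequence[float]) -> float:
        return ground_truth_orientation(self, point)


def _radius_fn(spec: PhantomSpec, theta: np.ndarray) -> np.ndarray:
    return 1.0 + spec.wobble_amp * np.sin(spec.wobble_freq * theta)


def layer_intensity(spec: PhantomSpec, depth: np.ndarray, t: float | None = None) -> np.ndarray:
    """Closed-form noise-free channel intensities at the given depths.

    Returns an array of shape ``depth.shape + (n_channels,)``.
    """
    t = spec.maturation_t if t is None else t
    depth = np.asarray(depth, dtype=float)
    out = np.zeros(depth.shape + (spec.n_channels,))
    for ld in spec.layer_defs:
        bump = np.exp(-((depth - ld.center_frac) ** 2) / (2.0 * ld.width_frac**2))
        out += bump[..., None] * ld.amplitude(t)
    return out


def layer_contrast(spec: PhantomSpec, t: float | None = None, n_depth: int = 512) -> float:
    """Mean over channels of (max - min) of the noise-free radial profile.

    Lamination redistributes intensity between channels along depth, so the
    contrast must be measured per channel; the channel-summed profile is
    blind to it when total amplitude is conserved.
    """
    d = np.linspace(0.0, 1.0, n_depth)
    prof = layer_intensity(spec, d, t=t)  # (n_depth, C)
    return float((prof.max(axis=0) - prof.min(axis=0)).mean())


def make_phantom_section(spec: PhantomSpec) -> PhantomSection:
    """Generate one synthetic section; bit-deterministic for a given seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    cr, cc = spec.center
    a, b = spec.radii

    rows = np.arange(h)[:, None] - cr
    cols = np.arange(w)[None, :] - cc
    u = rows / a
    v = cols / b
    r = np.hypot(u, v)
    theta = np.arctan2(u, v)
    mask = r <= _radius_fn(spec, theta)

    if not mask.any():
        raise ValueError("phantom mask is empty; check radii/center")

    dist_px = ndimage.distance_transform_edt(mask)
    max_depth = dist_px.max()
    depth = dist_px / max_depth

    # noise-free field and generating pixel class
    clean = np.zeros((spec.n_channels, h, w))
    contrib = np.zeros((len(spec.layer_defs), h, w))
    class_ids = np.array(
        [ld.class_id if ld.class_id is not None else li + 1
         for li, ld in enumerate(spec.layer_defs)]
    )
    for li, ld in enumerate(spec.layer_defs):
        bump = np.exp(-((depth - ld.center_frac) ** 2) / (2.0 * ld.width_frac**2))
        amp = ld.amplitude(spec.maturation_t)
        clean += amp[:, None, None] * bump[None]
        contrib[li] = bump * amp.sum()
    clean *= mask[None]
    pixel_class = np.where(mask, class_ids[np.argmax(contrib, axis=0)], 0).astype(np.int32)

    channels = clean.copy()
    if spec.poisson_like:
        scale = 50.0
        channels = rng.poisson(np.maximum(channels, 0.0) * scale) / scale
    if spec.noise_sd > 0:
        channels = channels + rng.normal(0.0, spec.noise_sd, channels.shape)
    channels = np.clip(channels, 0.0, None) * mask[None]

    centroids, nuc_labels = _place_nuclei(spec, mask, dist_px, rng)

    th = np.linspace(0.0, 2.0 * np.pi, 4097)
    R = _radius_fn(spec, th)
    contour = np.column_stack([cr + a * R * np.sin(th), cc + b * R * np.cos(th)])

    return PhantomSection(
        channels=channels,
        clean_channels=clean,
        mask=mask,
        pixel_class=pixel_class,
        depth=depth,
        nuclei_centroids=centroids,
        nuclei_labels=nuc_labels,
        maturation_t=spec.maturation_t,
        contour_truth=contour,
        spec=spec,
    )


def _place_nuclei(
    spec: PhantomSpec, mask: np.ndarray, dist_px: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping disk nuclei fully inside the mask."""
    h, w = mask.shape
    rad = spec.nucleus_radius
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 10_000
    while len(centers) < spec.n_nuclei:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} nuclei in {attempts} attempts; "
                "mask too small for the requested count/radius"
            )
        attempts += 1
        rr = rng.uniform(0, h - 1)
        cc_ = rng.uniform(0, w - 1)
        if dist_px[int(round(rr)), int(round(cc_))] < rad + 1:
            continue
        if any((rr - r0) ** 2 + (cc_ - c0) ** 2 < (2 * rad + 1) ** 2 for r0, c0 in centers):
            continue
        centers.append((rr, cc_))
    centroids = np.array(centers) if centers else np.zeros((0, 2))

    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (r0, c0) in enumerate(centers, start=1):
        disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2
        labels[disk] = i
    return centroids, labels


def make_phantom_timecourse(specs: Sequence[PhantomSpec]) -> list[PhantomSection]:
    """Generate an ordered developmental series of sections.

    All specs must share layer definitions and carry strictly increasing
    ``maturation_t``; the returned sections are tagged with ordinal
    timepoints 0..n-1.
    """
    specs = list(specs)
    if not specs:
        raise ValueError("need at least one spec")
    ts = [s.maturation_t for s in specs]
    if any(t1 <= t0 for t0, t1 in zip(ts, ts[1:])):
        raise ValueError("maturation_t must be strictly increasing across specs")
    if any(s.layer_defs != specs[0].layer_defs for s in specs):
        raise ValueError("timecourse specs must share layer_defs")
    sections = []
    for i, s in enumerate(specs):
        sec = make_phantom_section(s)
        sec.timepoint = i
        sections.append(sec)
    return sections


def default_timecourse_specs(
    n_timepoints: int = 5,
    image_size: tuple[int, int] = (256, 256),
    n_channels: int = 4,
    seed: int = 0,
    noise_sd: float = 0.05,
    n_nuclei: int = 60,
) -> list[PhantomSpec]:
    """The standard phantom developmental series used throughout the tests:
    uniform layer amplitudes at t = 0 maturing into distinct laminae at t = 1.
    """
    ts = np.linspace(0.0, 1.0, n_timepoints)
    return [
        PhantomSpec(
            image_size=image_size,
            n_channels=n_channels,
            maturation_t=float(t),
            seed=seed + i,
            noise_sd=noise_sd,
            n_nuclei=n_nuclei,
        )
        for i, t in enumerate(ts)
    ]


def four_class_spec(
    image_size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.05,
    seed: int = 0,
    n_nuclei: int = 20,
) -> PhantomSpec:
    """A section with four well-separated pixel classes of near-equal area.

    Depth is split into four bands holding equal pixel mass on a disk
    (band boundaries at 1 - sqrt(1 - q)); each band is tiled by three
    narrow sublayers sharing a one-hot channel signature, so signatures
    form plateaus with thin transitions — class separation is 1.0, i.e.
    8x the default noise sd or more.
    """
    bounds = [0.0, 0.134, 0.293, 0.5, 1.0]
    layers = []
    for ci in range(4):
        lo, hi = bounds[ci], bounds[ci + 1]
        span = hi - lo
        sub_sigma = span / 6.0
        amp1 = tuple(1.0 if c == ci else 0.0 for c in range(4))
        amp0 = tuple(0.5 for _ in range(4))
        for frac in (1.0 / 6.0, 0.5, 5.0 / 6.0):
            layers.append(
                LayerDef(lo + frac * span, sub_sigma, amp0, amp1, class_id=ci + 1)
            )
    return PhantomSpec(
        image_size=image_size,
        n_channels=4,
        maturation_t=1.0,
        layer_defs=tuple(layers),
        noise_sd=noise_sd,
        n_nuclei=n_nuclei,
        seed=seed,
    )


def ground_truth_orientation(section: PhantomSection, anchor: Sequence[float]) -> float:
    """Analytic inward-normal angle of the generating shape at the contour
    point nearest to ``anchor`` (radians, measured from the +col axis).

    Raises if the anchor lies more than 5 px from the true contour.
    """
    anchor = np.asarray(anchor, dtype=float)
    contour = section.contour_truth
    d2 = ((contour - anchor) ** 2).sum(axis=1)
    i = int(np.argmin(d2))
    if d2[i] > 25.0:
        raise ValueError(f"anchor is {np.sqrt(d2[i]):.1f} px from the contour (> 5 px)")

    spec = section.spec
    cr, cc = spec.center
    a, b = spec.radii
    # recover the parameter of the nearest contour vertex
    th = np.linspace(0.0, 2.0 * np.pi, contour.shape[0])[i]
    wamp, f = spec.wobble_amp, spec.wobble_freq
    R = 1.0 + wamp * np.sin(f * th)
    dR = wamp * f * np.cos(f * th)
    # tangent of p(th) = center + (a R sin th, b R cos th)
    t_row = a * (dR * np.sin(th) + R * np.cos(th))
    t_col = b * (dR * np.cos(th) - R * np.sin(th))
    n_row, n_col = -t_col, t_row
    p = contour[i]
    if n_row * (cr - p[0]) + n_col * (cc - p[1]) < 0:
        n_row, n_col = -n_row, -n_col
    return float(np.arctan2(n_row, n_col))
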