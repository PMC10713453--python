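# lamorg

Spatial phenotyping of laminated tissue sections from multiplexed
immunofluorescence (4i) imaging — built for retinal organoids and other
tissues that organize into concentric layers between an outer boundary and
an inner core.

Highly multiplexed imaging of organoid sections produces dozens of aligned
protein channels per section, but turning those images into quantitative
statements about *laminar organization* — which layers exist, how they
mature over developmental time, and how individual cells' microenvironments
differ — requires dedicated machinery. `lamorg` provides that machinery as
a tested library plus CLI:

- **MTUs (multiplexed tissue units)** — unsupervised pixel-level tissue
  annotation. Images are harmonized by *reverse z-scoring* (z-score each
  image, rescale with the pooled timepoint/channel mean and s.d., then map
  the global 1st/99th percentiles to 0/1), subsampled pixels train a
  self-organizing map (30 × 30 grid, Euclidean distance, best of 10 runs by
  quantization error), SOM node medians are metaclustered by Louvain
  community detection on a kNN graph with the neighbor count *k* chosen at
  the knee of the (k, #clusters) curve, and every pixel is labeled by its
  nearest metacluster centroid.
- **Laminar windows** — rectangles (default 100 × 1000 px = 16.25 × 162.5 μm
  at 0.1625 μm/px) anchored with the midpoint of their short edge on every
  100th coordinate of the smoothed tissue contour and oriented along the
  inner–outer axis by rotating each window about its anchor to maximize the
  Euclidean-distance-transform signal captured under its footprint.
- **Profile distances** — window profiles (transverse means at each
  inner–outer position, for protein channels and one-hot MTU occupancies)
  are reverse z-scored per section/timepoint, smoothed (1D mean filter,
  window 20), downsampled (×2), and compared per feature by the Euclidean
  distance between their first 10 Fourier coefficients
  D_f(i,j) = ‖F_i,0..9 − F_j,0..9‖. Per-feature distance matrices are fused
  by **DISTATIS**: double-center D_f² into cross-products S_f, normalize by
  the leading eigenvalue, weight by the first eigenvector α of the RV
  coefficient matrix, and back-transform the compromise S₊ = Σ_f α_f S̃_f
  into the compromise distance D₊.
- **Trajectories** — a diffusion map over the log₁₀(x+1)-transformed,
  feature-aggregated distance matrix gives diffusion components; pseudotime
  is the distance from a root window in λ/(1−λ)-rescaled diffusion space;
  windows are clustered per timepoint (UMAP + Louvain); the **maturation
  score** contrasts mean compromise distances to the lower vs upper 5%
  pseudotime quantile sets, scaled to [−1, 1]; a timepoint-constrained kNN
  (k = 4) cluster graph summarizes the trajectory.
- **Radial neighborhoods** — per-nucleus intensity statistics plus ring
  profiles (mean signal at 1-px radial steps out to 40 px = 6.5 μm, all
  nucleus pixels masked out), fed through the same distance/diffusion/
  clustering chain to find microenvironment types.
- **Spatial correlation** — any per-nucleus feature is rendered into a
  200 × 200 grid by a feature-weighted bivariate normal KDE; an occupancy
  mask (thresholded nuclei-position density, cutoff 0.05) restricts Pearson
  correlations against a target feature, averaged across sections.
- **Phantoms** — a synthetic section generator (wobbled-ellipse tissue,
  Gaussian depth layers whose amplitudes interpolate with a maturation
  parameter t, planted non-overlapping nuclei) supplies analytic ground
  truth — boundary normals, depth profiles, pixel classes — for every
  stage. No external data are needed to test or demo the package.

## Worked example

Reconstructing lamination dynamics on a synthetic developmental series of
five sections whose maturation parameter t runs from 0 (unlayered) to 1
(fully laminated):

```python
import numpy as np
from scipy.stats import spearmanr

from lamorg import metrics, trajectory, windows as W
from lamorg.phantom import default_timecourse_specs, make_phantom_timecourse
from lamorg.pipeline import _concat_profiles

sections = make_phantom_timecourse(
    default_timecourse_specs(5, image_size=(256, 256), seed=10)
)

pms = []
for sec in sections:
    contour = W.extract_contour(sec.mask, sigma=5)
    dmap = W.distance_map(sec.mask, sigma=5)
    ws = W.place_windows(contour, dmap, stride=len(contour) // 60,
                         width_px=50, length_px=200)
    ws.timepoint = sec.timepoint
    W.orient_windows(ws, dmap)
    pm = W.extract_profiles(ws, channels=sec.channels, mask=sec.mask)
    ws, pm = W.filter_windows(ws, pm, min_valid=0.5)
    pms.append(pm)
pm = _concat_profiles(pms)

pm = metrics.smooth_downsample(metrics.normalize_profiles(pm), 20, 2)
ds = metrics.fft_distance(pm, n_components=10)
cd = metrics.distatis(ds)
D = metrics.aggregate_log_distance(ds)

tp = pm.meta["timepoint"].to_numpy()
dr = trajectory.diffusion_from_distance(D, n_dcs=10, k_local=30)
pt = trajectory.diffusion_pseudotime(dr, "auto", timepoints=tp)
score = trajectory.maturation_score(cd, pt, q=0.05)

print(f"windows analysed:        {pm.n_windows}")
print(f"DISTATIS feature weights: {np.round(cd.alpha, 3)}")
print(f"Spearman(pseudotime, t):  {spearmanr(pt.pt, tp).statistic:.3f}")
print(f"Spearman(maturation, t):  {spearmanr(score.score, tp).statistic:.3f}")
```

Output:

```
windows analysed:        305
DISTATIS feature weights: [0.248 0.254 0.248 0.249]
Spearman(pseudotime, t):  0.952
Spearman(maturation, t):  0.944
```

305 laminar windows (61 per section) are placed and oriented; the four
channels contribute near-equal DISTATIS weights (the phantom gives each
channel its own layer); and both the diffusion pseudotime and the
maturation score recover the generative maturation order with Spearman
ρ ≈ 0.95 — windows from later sections are correctly placed later along
the reconstructed laminar trajectory.

## Command line

```bash
lamorg phantom --out demo --seed 1 --t 0.8 --size 512      # synthetic section
lamorg mtu-fit --manifest demo/manifest.tsv --out model.npz --seed 1
lamorg mtu-assign --manifest demo/manifest.tsv --model model.npz --out demo
lamorg run-all --manifest demo/manifest.tsv --out results_dir --seed 1
```

All subcommands (`phantom`, `mtu-fit`, `mtu-assign`, `windows`, `profiles`,
`distances`, `trajectory`, `neighborhoods`, `spatialcorr`, `run-all`) share
`--config` (YAML with every tunable), `--seed`, `--out` and `--log-level`;
the config is echoed verbatim into every output directory and one global
seed fans out deterministically to per-stage seeds.

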