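# Methods

## Scope and data model

`lamorg` quantifies laminar tissue organization in multi-channel 2D
sections. The atomic input is an `ImageSection`: a float channel stack, a
binary tissue mask, per-image metadata (timepoint, pixel size, channel
names) and optional nuclei / MTU label images. All analyses assume a
single, closed tissue boundary with intensity structure organized along
the inner–outer axis (the direction of increasing distance from the
boundary). The default pixel size of 0.1625 μm/px makes the default
window (100 × 1000 px) measure 16.25 × 162.5 μm and the neighborhood
radius (40 px) measure 6.5 μm; all geometry is configured in pixels with
the μm equivalence derived from the manifest's pixel size.

## Image harmonization (reverse z-scoring)

Multi-section experiments carry per-image intensity offsets that must be
removed without erasing group-level biology. Each image (one channel of
one section) is z-scored with its own mean and s.d. and then rescaled with
the pooled s.d. and mean of its (timepoint, channel) group. Windows of one
group therefore share first and second moments while between-group
contrasts survive. Finally each channel is min–max scaled so the global
1st percentile maps to 0 and the 99th to 1 (clipped). Constant images pass
through unchanged and are flagged; a group with zero pooled variance is an
error naming the group. The same contract is applied per-feature to
laminar-window profiles with (section, timepoint) groups.

## MTU clustering

Training pixels are drawn from in-mask positions only, ⌊n/factor⌋ per
section without replacement (default factor 1000). The SOM is a batch
algorithm on a rectangular grid: nodes initialized from data rows,
Gaussian neighborhood whose width decays linearly from max(grid)/2 to 0.5
over 20 epochs, batch updates weighted by the neighborhood kernel. Ten
runs with consecutive seeds are trained and the codebook with the lowest
quantization error (mean distance to best-matching node) is kept.

Metaclustering computes per-node median channel intensities (empty nodes
keep their codebook vector), builds a Euclidean kNN graph over the node
medians for each k in a sweep (default {5,…,40}), runs Louvain community
detection (resolution 1.0, unweighted edges; Jaccard weighting available),
and picks k at the knee of the decreasing (k, #clusters) curve using the
Kneedle construction (max of (1−x_n)−y_n on normalized axes; implemented
in `lamorg._utils`, validated against a hand-worked curve). MTU ids are
ordered by descending member-pixel count starting at 1; pixel assignment
is nearest-centroid with ties to the lowest id.

**Grid size vs data volume.** The 30 × 30 default grid (900 nodes) suits
full-scale experiments with millions of training pixels. At desk scale
(a 256² phantom yields ~3k training pixels) 900 nodes leave ~3 pixels per
node, node medians degenerate to noise and the metaclustering oversplits;
the test-bed therefore uses a 10 × 10 grid, keeping ≥ 25 pixels per node.
As a rule of thumb the node count should stay ≥ 10× below the training
pixel count.

## Laminar windows

The contour is the longest marching-squares iso-contour of the
Gaussian-smoothed mask (σ = 50 at full scale) at its Otsu level,
orientation-normalized counter-clockwise; the distance map is the exact
Euclidean distance transform smoothed with σ = 25. Windows anchor the
midpoint of their outer short edge on every stride-th contour coordinate
(stride 100 at full scale). The initial axis is the inward normal
estimated by PCA over ±10 contour points, sign-disambiguated toward
higher distance-map values. Orientation then maximizes the sum of
bilinearly sampled distance-map values under the footprint over the
initial normal ± 90° in 2° steps, refined at 0.5° (full-circle search
available); exact score ties resolve to the angle nearest the initial
normal, and an all-zero score flags the window `out_of_bounds`.

Profiles average the transverse (width) dimension at each of the
length-px inner–outer positions — position 0 is the outer edge. Intensity
channels sample bilinearly, label images nearest-neighbor with one-hot
encoding per MTU id before averaging (per-MTU occupancy profiles in
[0, 1] that sum to 1 where fully in-mask). Out-of-mask samples are
missing, not zero; a position with no valid sample is NaN. Windows with
valid fraction ≤ 0.99 are dropped (strict inequality); an optional
straightness filter drops windows whose contour span deviates from its
chord by less than a threshold (default off — it targets crop-boundary
artifacts of specific acquisitions).

**Window locality matters.** Orientation recovers the analytic inward
normal to ≈ 1–2° median error when the window length is small relative to
the boundary-wobble wavelength; windows longer than the local curvature
scale align with the global medial axis instead (observed ≥ 5° median on
the same phantom). Desk-scale runs use 24 × 80 px windows on 512²
phantoms for orientation checks and 50 × 200 px on 256² sections for
trajectory runs, with a coverage threshold of 0.5 because 200-px windows
necessarily cross the whole phantom; both are geometry-scaled stand-ins
for the full-scale 100 × 1000 px window.

## Profile distances and DISTATIS

Profiles are normalized (above), smoothed with a centered 20-position
moving mean (edge-truncated windows) and downsampled ×2; missing
positions are first imputed by linear interpolation from the nearest
valid positions. Per feature, the real-input FFT of each profile is
truncated to its first 10 complex coefficients *including the DC term*,
and window pairs are compared by the Euclidean distance over real and
imaginary parts jointly (magnitude-only comparison is a flag; the
complex default follows the Fourier-distance convention for time series).

DISTATIS fuses per-feature distances: square and double-center with
uniform masses (S_f = −½ C D_f² C), normalize by the leading eigenvalue,
compute the RV coefficient matrix, weight by its first eigenvector (sign
fixed nonnegative, rescaled to sum 1) and back-transform the compromise
cross-product into a distance. Negative squared distances from numerical
round-off clamp to zero with a warning. The across-feature aggregate used
for diffusion is the mean of log₁₀(D_f + 1); the mean (rather than the
sum) keeps the scale comparable across runs with different feature
counts without changing the diffusion geometry.

## Diffusion, pseudotime and trajectory summaries

The diffusion kernel is Gaussian with local bandwidths,
K_ij = exp(−D_ij²/(σ_i σ_j)) with σ_i the distance to the k_local-th
neighbor (default 30, automatically reduced to W/4 when W ≤ k_local),
density-normalized on both sides (α = 1), symmetrically normalized and
eigendecomposed; the trivial eigenvector is dropped and components are
right eigenvectors scaled by their eigenvalues. A kernel with exact-zero
disconnected blocks is an error listing component sizes. Pseudotime is
the Euclidean distance from a root window in λ/(1−λ)-rescaled diffusion
space, min–max scaled to [0, 1] — a single-branch ordering appropriate
for laminar maturation; the root defaults to the earliest-timepoint
window with the most extreme first component, with explicit override.

Per-timepoint clustering runs UMAP (2D, n_neighbors = k_umap = 15, fixed
seed) on the subset's first 10 components, then Louvain on the embedding's
kNN graph; subsets smaller than k_umap + 1 become a single flagged
cluster. The maturation score is raw_i = mean D₊[i, start] − mean
D₊[i, end] with start/end the ≤ q and ≥ 1−q pseudotime quantile sets
(q = 0.05), min–max scaled to [−1, 1]; an explicit end set (e.g. windows
from mature reference tissue) may replace the upper quantile. The cluster
graph allows edges only between clusters of the same or adjacent
timepoints, weights them by mean inter-cluster compromise distance, keeps
each node's k = 4 lightest edges (union-symmetrized, adjacency asserted
on every construction) and lays the graph out force-directed with
attraction ∝ 1/weight.

## Radial neighborhoods

Per-nucleus features: bottom/top 5th percentile, median, mean and sum per
channel over member pixels; mean distance-map value (`radial_distance`);
and nuclei count within a filled ellipse of semi-axes 50 × 50 px centered
on the centroid, self-inclusive (a 1e−9 radius slack absorbs scaling
round-off at exact boundaries). Ring profiles take, for r = 1…40, the
mean channel intensity over pixels at *rounded* Euclidean distance r from
the rounded centroid — rounding keeps ring widths unbiased — excluding
pixels of any nucleus (focal-only exclusion is a flag) and recording
out-of-image pixels as missing, never zero. Neighborhood clustering
reuses the laminar chain (normalize → smooth/downsample → FFT distances →
mean aggregate → diffusion → UMAP → Louvain).

## Spatial correlation

Feature densities are weighted KDEs with an axis-aligned bivariate normal
kernel: each centroid contributes a Gaussian scaled by its nonnegative
feature value (negative features are shifted up to zero and the shift
recorded) — kernel-weight scaling, not point replication, so the grid is
exact and testable against a double loop. Bandwidths follow the
normal-reference rule h = 1.06·min(s, IQR/1.34)·n^(−1/5) per axis, used
directly as the kernel s.d. The occupancy mask is the unweighted
nuclei-position KDE rescaled to max 1 and thresholded at 0.05 (the max-1
normalization is a package choice; a probability-density normalization
would only rescale the threshold). Pearson correlations are computed over
masked grid cells of mask-multiplied densities; a grid constant under the
mask yields a missing value. Feature rankings average r per feature
across sections and report the top-n positive and negative correlates.

## The phantom generator

The phantom emulates a laminated organoid section: a wobbled ellipse
(polar radius × (1 + a·sin(fθ)), default a = 0.08, f = 5 — the wobble
prevents degenerate circular symmetry in orientation tests), channel
intensities that are exact functions of normalized depth (EDT of the mask
scaled to [0, 1]) as sums of Gaussian layers whose per-channel amplitudes
interpolate linearly between a t = 0 and a t = 1 state, additive Gaussian
noise (default s.d. 0.05), and non-overlapping disk nuclei placed by
rejection sampling (≤ 10,000 attempts). Everything is bit-deterministic
per seed. Ground truth exposed: the analytic contour and inward normal,
the noise-free field and closed-form depth profile, the generating pixel
class (argmax layer contribution; layers may share a `class_id` so that
several narrow sublayers tile one plateau band — used to build genuinely
well-separated pixel classes), nuclei centroids and the maturation
parameter.

Standard test conditions, chosen once: the developmental series is five
256² sections with t = 0, 0.25, …, 1 (uniform amplitudes maturing into
four one-hot laminae), ~60 windows of 50 × 200 px per section; the
four-class section tiles depth into four equal-pixel-mass bands (band
boundaries 1 − √(1−q) on a disk) of three sublayers each, giving class
separation 1.0 = 20× the noise s.d.

What the phantom does *not* emulate: point-spread blur, illumination
gradients, multi-cycle registration error, irregular nucleus shapes,
open-cup or multi-lobed tissue geometry, or biologically realistic
channel correlations. Passing phantom tests therefore demonstrates
correctness of the geometry and numerics under the stated generative
model, not robustness to acquisition artifacts.

## Numerical and design notes

- Coordinates are 0-based (row, col) with pixel centers on integers;
  angles are radians from the +col axis with the row coordinate as the
  sine component.
- Louvain uses igraph's multilevel algorithm; python-igraph draws from
  Python's `random` module, so partitions are seeded by seeding that
  module. One global seed fans out to stages via CRC32 of the stage name.
- The knee locator requires ≥ 3 sweep points and a strictly increasing
  x axis; flat curves resolve to the first index.
- `fft_distance` is *not* shift-invariant (complex coefficients carry
  phase); scaling a profile by c scales its distance to the zero profile
  by c.
- Distance-map sampling outside the image contributes 0 to orientation
  scores; profile samples outside mask or image are missing.
- Tables are written as UTF-8 TSV with a JSON schema sidecar; arrays as
  compressed `.npz` with a JSON sidecar naming each axis; the MTU model
  is one `.npz` archive; label images are 16-bit TIFF.

## Problem sizes

The test suite and acceptance script run entirely on phantoms: 256²–512²
sections, ≤ 305 windows, ≤ 5600 training pixels, 36 nuclei in the
neighborhood scenes, 50-point KDE oracles. The full suite completes in
about a minute on one CPU; `scripts/acceptance.py` in about half a
minute. These sizes are the package's standard desk-scale conditions;
every parameter that differs from the full-scale defaults (SOM grid,
window dimensions, smoothing σ, coverage threshold) is stated above with
its rationale.

## Known limitations

- Single closed contour per section; open-cup geometries are out of scope.
- Pseudotime is single-branch by construction; branching trajectories
  need a different method.
- The 99%-coverage window filter assumes windows fit inside the tissue at
  full scale; strongly concave tissues will drop many windows.
- UMAP + Louvain clustering is seed-stable but not perturbation-stable
  for very small window counts; subsets below k_umap + 1 windows are
  deliberately collapsed to one cluster.
- DISTATIS weights assume features are positively related (RV ≥ 0); a
  feature anti-correlated with all others would receive a near-zero
  weight rather than a negative one.
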