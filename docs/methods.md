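# Methods

## The measurement problem

A two-channel 3D time course of a growing root is, per replicate, `N`
pairs of stacks taken every `dt` hours: a fluorescence channel in which
cells expressing a cell-cycle reporter appear as bright blobs for a few
hours each, and a brightfield channel showing the whole organ. The
package extracts, per time stamp, how many reporter regions are visible,
how long each persists, and where each sits relative to the root tip and
longitudinal axis; filters and averages these signals into per-condition
profiles; compares conditions with a normalized sum-of-squares
dissimilarity; and measures root growth from inter-frame registration.

Time is interval-indexed: frames `n = 0 .. N−1`, `time_h(n) = n·dt`.
A 24-h course at 20-min sampling has `N = 72`. Voxels are ordered
`(z, y, x)` with per-axis physical resolution in µm; the default
geometry is 3.33 µm axial and 0.23 µm lateral — a 14-fold anisotropy
that every distance computation in the package carries explicitly.

## Segmentation

A per-frame threshold (absolute value, or Otsu's rule when no value is
known; the resolved number is always reported) selects candidate
voxels. A marker-controlled watershed on the negated intensity splits
touching regions: seeds are local maxima of the Euclidean distance
transform of the mask, computed with physical spacing and lightly
smoothed (default 1 µm) — the raw transform of a discrete mask is
piecewise constant and its plateaus would seed one blob many times.
Maxima closer than `min_seed_separation_um` (default 5 µm) merge.
Regions below `min_roi_volume_voxels` (default 8) are discarded as hot
pixels; survivors are relabelled contiguously in raster order. ROI
centroids are intensity-weighted and reported in µm.

Numerical notes: the threshold is inclusive (`≥`); connectivity is
26-neighbour; an empty mask yields zero labels; Otsu on a constant
image raises a degenerate-input error rather than guessing.

## Root coordinate system

Root tissue is textured in brightfield while the medium is smooth, so a
per-voxel feature — gradient magnitude with physical spacing, Gaussian
smoothed over 2 µm — separates the two classes. k-means with k = 2 and
a fixed seed assigns each voxel; the cluster with the higher mean
gradient energy is the root. The mask is reduced to its largest
26-connected component and holes are filled. On phantoms this recovers
the true cylinder with intersection-over-union ≈ 0.84; the residual is
a thin dilation halo from the smoothing scale at the root boundary.

The longitudinal axis is the first principal component of the mask
voxel coordinates in µm, anchored at their centroid. Eigenvector sign
is canonicalized (largest-magnitude component positive) so the two axis
ends are stable across frames; a `tip_side` flag then picks which end
is the tip — the extremal mask voxel by projection, ties broken by
smallest `(z, y, x)`. ROI localization uses the straight-line µm
distance to the tip point and the perpendicular distance to the axis
line. Straight-line (rather than arclength along a midline) tip
distance was chosen for determinism on noisy masks; for the nearly
straight meristematic region imaged in such experiments the two agree
closely. Degenerate masks (empty, single voxel) raise instead of
returning an arbitrary axis.

## Tracking and growth

The root moves essentially rigidly between consecutive frames, so one
translation per interval serves two purposes. It is estimated by the
phase-correlation peak of the brightfield pair (integer voxels by
default; subvoxel refinement available). Its per-axis µm conversion —
each axis scaled by its own resolution before the Euclidean norm — is
the growth magnitude `g(n)`; using a single scalar conversion factor
would misstate distances given the 14-fold axial/lateral anisotropy.
Cumulative growth is the prefix sum `G(n)`, `G(0) = 0`, non-decreasing
by construction. Optionally `g` is low-pass filtered with the metrics
filter before accumulation.

Linking is greedy one-to-one nearest-centroid in µm after shifting
frame-`t` centroids by the registration displacement, gated at
`max_link_distance_um` (default 10 µm), ties broken by lower label
pair. Greedy was chosen over optimal assignment for determinism and
speed; tests validate it against a brute-force minimal-cost assignment
on small instances, where the two coincide whenever objects are
separated by more than the localization error — the regime the linker
is designed for. Chains of links become tracks; every ROI belongs to
exactly one track. Persistency is observed member count × `dt` hours;
tracks alive at the first or last frame are kept and counted from their
observed extent (appearances at `n = 0` and endings at `n = N−1`
included).

## The ten metrics, filtering, averaging

For each frame `n`, over the visible ROIs: X1/X2/X3 are the mean,
population standard deviation and sum of the persistencies of their
tracks (so X3 = X1·X4 identically); X4 is the count; X5/X6 count tracks
first/last seen at `n`; X7/X8 and X9/X10 are mean/SD of tip and center
distances. Frames with no ROI carry 0 for the counts and NaN for means
and spreads; a single ROI gives spread 0. Population (divide-by-count)
SD was chosen so that the one-ROI case is well defined.

The low-pass filter is a 10-tap boxcar of weight 1/10 spanning taps
`k = −4 .. 5`; the output at `n` is therefore the mean of samples
`n−5 .. n+4`. At the edges, and across missing samples, the window
truncates and renormalizes (a moving-average semantic) rather than
zero-padding, which would drag boundary values toward zero. DC gain is
exactly 1 and outputs stay within the observed signal range. Filtered
replicate panels are averaged entrywise per condition, ignoring missing
entries cell-wise; entries missing in every replicate stay missing.

## Condition comparison

Profiles are stacked to 10 × N, each metric divided by its maximum over
all conditions and frames (the diagonal normalization matrix), so no
metric outweighs another; a metric identically zero everywhere is left
at zero with a warning. The dissimilarity at frame `n` is the mean
squared difference of the ten normalized metrics — 0 for identical
profiles, 1 when every metric differs by its full range — and the total
SST is the sum over the N frames, not the mean; anyone comparing SST
magnitudes across experiments of different lengths should divide by N
themselves. A metric missing in either profile at a frame contributes 0
while the divisor stays 10 (pairwise-complete policy).

## The phantom generator

`roottrack.synthetic` renders what the pipeline consumes, with exact
ground truth:

* **Root**: a cylinder of radius 8 µm with a hemispherical tip,
  entering the grid at y = 0, axis along y; brightfield shows it as a
  base intensity plus a frozen speckle texture that translates with the
  programmed per-interval drift (integer voxels, default 1 lateral
  voxel ≈ 0.23 µm per 20 min), so registration sees a pure translation.
* **Events**: Gaussian blobs isotropic in µm (σ = 2.5 µm, peak 100 over
  background 10), each with an onset frame and a lifetime drawn from a
  shifted Poisson with mean 9 frames (3 h at 20-min sampling, the
  nominal duration of a mitosis-reporter occurrence). Events ride on
  the root's drift. Concurrent events (lifetimes dilated by one frame)
  are kept ≥ 12 µm apart — beyond the 10 µm linking gate — so the
  programmed tracks are the unique correct answer; the generator raises
  if a random layout cannot satisfy this, rather than silently
  degrading the truth.
* **Noise**: additive Gaussian (σ = 2) in both channels. The default
  SNR is high enough that a fixed global threshold separates blobs;
  thresholding behaviour itself is exercised by segmentation tests, not
  by the scene.

All randomness flows from one seeded generator: identical (config,
seed) gives bit-identical stacks.

What the phantom does **not** emulate: optical PSF and light-sheet
stripe artifacts, photobleaching, intensity fluctuation within an
event's lifetime, cell walls and tissue context, root bending, and
elongation-zone deformation (growth is rigid translation). Passing
tests therefore demonstrate that the algorithms are correct under their
stated model — rigid growth, separated blob-like signals — not that
segmentation or clustering thresholds transfer to any particular
microscope; those remain per-experiment configuration.

## Problem sizes and reproducibility

Tests and the acceptance script use 24-frame, 12-event phantoms on a
16 × 512 × 96 grid (about 0.8 Mvoxel per channel per frame) — large
enough for several concurrent events and a realistic tip trajectory
while keeping a full pipeline run under a minute per replicate; the
comparison experiment uses three replicates per condition, matching the
replication level typical of such imaging studies. The stressed
("prolonged") phantom condition uses fewer, longer-lived events (7
events, mean 14 frames vs 12 events, mean 9), the phantom analogue of
prolonged reporter persistence with fewer initiations. All scripts
derive every random stream from a single `--seed`.

## Known limitations

* Tracking has no division handling: a splitting region ends one track
  and starts another.
* Registration is translation-only; rotation or bending of the root
  between frames degrades both growth estimates and drift correction.
* Tip distance is point-to-point, not along the root midline.
* The watershed relief is the raw intensity; very noisy data may
  benefit from pre-smoothing, which the pipeline does not do.
* Otsu thresholding assumes some signal is present in the frame; on
  signal-free frames an absolute threshold must be configured.
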