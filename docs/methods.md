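# Methods

This note documents the models, conventions and numerical choices behind
`vesselseg`, in the spirit of a methods section: what each stage assumes,
which defaults matter, and what the synthetic tests do and do not show.

## Volume model and blocking

A volume is a (z, y, x)-indexed scalar array with voxel-size metadata,
stored on disk as one 2D TIFF per z-slice in filename order (LZW
compression optional on write).  Coordinates are 0-based and block extents
half-open.  Blocking uses per-axis origins 0, s, 2s, … with stride
s = B − O (block edge B, overlap O; defaults 192 and 32).  A final block
that would overrun is clamped to `dim − B`, gaining extra overlap; an axis
shorter than B gets a single zero-padded block whose padding is trimmed
before fusion so it can never contribute foreground.  Fusion is a voxelwise
OR of all covering blocks, which is commutative and associative, so the
fused result is independent of block processing order, and — for any
pointwise predictor — blockwise predict-then-fuse equals whole-volume
prediction exactly.  Binary masks are written as uint8 {0, 255}.

Integer-factor resampling is block-mean pooling for images and cell
majority for masks, with exact ties resolved to foreground (a tie means
half the cell is vessel; dropping it would bias thin structures away).
Trailing voxels that do not fill a whole cell are dropped.

## Segmentation network

The network addresses the two appearance regimes of wall-labeled
vasculature by *image* multi-resolution rather than feature
multi-resolution: scale k receives the input average-pooled by 2^k
(k = 0, 1, 2 in the reference three-scale configuration), so large-vessel
context (where lumens shrink and close) and capillary detail are learned in
separate branches before fusion.  Each branch is
Conv(1→W) → BottleConv(W) → LinkConv(W) → BottleConv(W), then k stride-2
transposed convolutions return the output to full resolution.  Branch
outputs are concatenated, reweighted by CBAM (channel attention: shared
two-layer MLP over global-max and global-average channel vectors, reduction
6; spatial attention: 7³ convolution over the channelwise max and mean
maps), and reduced by Conv(ΣW→24) → Conv(24→1) → sigmoid.

Submodules:

* `BottleConv(W)` — 1³ squeeze to W/r, 3³ convolution, 1³ expand, additive
  identity skip, ReLU after each stage (r = 2 by default);
* `LinkConv(W)` — average-pool /2, Conv(W→eW), Conv(eW→eW), transposed-conv
  back to full size, concatenation with the un-pooled input, Conv(2W→W)
  (e = 2 by default).

Ablation toggles replace LinkConv/BottleConv by an equal-width plain 3³
convolution and CBAM by the identity.

Channel widths are not uniquely determined by the architecture's published
description; the reference family (8, 12, 16) with expansion 2, bottleneck
ratio 2, CBAM reduction 6 and head width 24 gives **146 662** trainable
scalars (0.15 M at two significant figures, 0.89 % of a 16.42 M 3D U-Net),
verified in tests against a closed-form per-layer sum.  Upsampling inside
LinkConv and between scales uses stride-2 kernel-2 transposed convolutions;
convolutions use zero-padded "same" shape; inputs must be divisible by
2^n_scales (branch pooling plus the LinkConv pool).

All tensors are float32 (C, D, H, W) single-sample arrays on a small
reverse-mode autodiff engine (`_autodiff.py`).  Convolutions run as
shift-and-matmul (27 channel-mixing BLAS calls for a 3³ kernel); the
training path builds one im2col matrix per convolution so both directions
are single matmuls; the 7³ attention convolution switches to FFT
convolution at inference on large blocks.  Gradients are verified against
numerical differentiation in the test suite.

Initialization is seeded He-normal; the output convolution's bias starts at
−3 so the initial prediction matches the background-dominated voxel prior
(vessels are a few percent of the volume) instead of wasting early epochs
collapsing toward it.

### Training protocol

Adam (β = 0.9/0.999), per-voxel binary cross-entropy on logits, learning
rate 0.001 · 0.98^⌊epoch/10⌋.  Augmentation is random cropping, random
permutation of the three spatial axes (voxels are isotropic), and random
multiplicative brightness in [0.7, 1.3].  Training patches are 24³ crops —
large enough to contain a 20 µm-diameter vessel with context, small enough
for CPU throughput — drawn twice per block per epoch; half the crops are
centered on a randomly chosen vessel voxel so the sparse foreground class
is sampled adequately under plain (unweighted) BCE.  Inputs are normalized
per block by min–max to [0, 1] with an epsilon guard for constant blocks.
Validation Dice is computed at the pipeline operating point (threshold 0.5
plus morphological post-processing), and the best-validation weights are
returned.  Everything is driven by explicit seeds; two runs with the same
seed produce identical logs.

## Post-processing

Plane-wise hole filling applies 2D filling (background 4-connectivity, the
dual of 8-connected foreground) to every slice of the x–y, x–z and y–z
families in turn, and repeats the triple once — six passes.  The plane-wise
form matters: the lumen of a tube whose open ends reach the volume border
is 3D-connected to the outside and a single 3D fill leaves it open, but
every interior cross-section is a closed annulus and fills in 2D.  Two
triples suffice for tubular and shell geometry (verified as a fixed point
on such masks); pathological dense-noise masks may not converge in two
triples, which is irrelevant to the vessel use case.  Component removal
labels 26-connected components and deletes those strictly below `min_size`
(default 100 voxels; a component of exactly the threshold survives).  The
composition is fill-then-remove: filling can promote a thin wall fragment
above the size threshold, and the reverse order destroys it first — the
test suite contains a constructed annulus where the two orders differ.

## Metrics

Standard voxel-overlap definitions; both-empty pairs score 1.0 and
empty-vs-nonempty 0.0.  clDice uses the same 3D thinning as the morphometry
module: topology precision |skel(P) ∩ T|/|skel(P)|, topology sensitivity
|skel(T) ∩ P|/|skel(T)|, harmonic mean.  Hausdorff distance is the
symmetric maximum of nearest-surface-voxel Euclidean distances computed via
distance transforms of the two surface sets, in voxel units by default,
with an optional percentile variant (HD95); it raises on empty masks, and
no physical-unit target is implied.

## Skeletonization and morphometry

Skeletons come from 3D medial-axis thinning (Lee's method via
scikit-image).  One repair is applied: that implementation can erase small
even-width objects outright (a 2×2×L bar has no center plane), so any mask
component left without skeleton voxels is re-represented by its deepest
voxel (maximal distance transform), restoring the one-skeleton-component-
per-mask-component contract.  Nodes are skeleton voxels; edges connect
26-neighbors, after pruning diagonal shortcut edges for which a common
neighbor provides a strictly shorter two-step path — this restores degree 2
on straight (including diagonal) runs without disconnecting anything.
Radii are the mask's Euclidean distance transform at each node, scaled to
µm.  Total length is the sum of Euclidean edge lengths; length accuracy is
within ~5 % for axis-aligned tubes and ~10 % for 45° oblique ones.  A
bifurcation is a *branch point*: a connected cluster of degree ≥ 3 nodes
(thinning leaves 2–3 adjacent high-degree voxels at a single anatomical
junction).  Densities divide by region volume (voxel count × voxel volume,
in mm³).  Radius histograms use 1 µm bins per node.  Connectivity domains
are connected components of the skeleton graph, labeled largest-first.
SWC export writes the standard 7 columns with type code 7, µm coordinates
in (x, y, z) order, one root per domain; since SWC is tree-structured, each
graph cycle is broken at its lowest-radius edge (maximum spanning forest
over min-endpoint-radius weights) and the break count is recorded in a
header comment.

## Pipeline and parallelism

`segment_volume` chains reading → optional resampling → blocking (with a
plain-text coordinate record) → per-block prediction → OR-fusion →
post-processing → LZW TIFF output, and writes a JSON manifest recording the
configuration actually used, stage timings, and component counts before and
after removal.  Parallelism is a map over independent work items merged in
fixed index order.  Two deliberate choices keep the output bit-identical
for any worker count:

* post-processing runs once on the fused whole volume, not per worker
  section — the x–z and y–z fill passes are global along z, so no finite
  section halo can guarantee identical lumen filling for cavities spanning
  a section boundary;
* worker threads overlap file I/O (slice reading, block-cache writing)
  while the numerical prediction of each block is serialized under a lock.
  This also sidesteps an observed platform effect where concurrent BLAS
  calls leave the linear-algebra library returning slightly different
  results for the remainder of the process, which would silently break
  seeded reproducibility.

An optional block cache directory makes runs restartable: each predicted
block is written atomically (temp file + rename), so cached files are
content-complete or absent, and a rerun reuses them without recomputation.

## Synthetic phantoms

The generator emulates the appearance properties of a wall-labeled vessel
channel at 1 µm isotropic resolution: vessels at or above 6 µm radius
render as an annular wall (2 µm thick) at high intensity with the lumen at
background level; thinner vessels render solid at a lower intensity;
ground truth is always the filled tube.  Geometry is a seeded random walk
with Gaussian direction perturbation (tortuosity 0.25 rad/step), step 3 µm,
probabilistic symmetric bifurcation (both daughters scaled by 0.8, floored
at the minimum radius), reflection off the volume walls, and root radius
drawn from the upper half of the spec's radius range.  Corruption adds
isolated fluorescent specks (rejection-sampled clear of the vessel mask so
component-removal tests have unambiguous answers), a Gaussian PSF blur
(σ = 0.7 µm), a constant background offset and Gaussian noise, then clips
to the integer dtype.

Dataset assembly crops blocks from freshly generated volumes and keeps a
configurable fraction of background-only blocks (default 47/179 ≈ 0.26,
the fraction such training sets typically retain); the 70/15/15 split is
disjoint, exhaustive, and seed-reproducible.

`hdfmost_like_specs` defines the study conditions used by the desk-scale
learning tests: two capillary-field recipes (radii 2–4 µm, branching walks)
cycled with a mixed recipe containing penetrating vessels up to 10 µm
radius (20 µm diameter — the scale at which a segmentation network can
plausibly infer the lumen from wall context).  This mix gives a few percent
vessel volume fraction, matching the capillary-dominated character of real
vessel-channel blocks.  Known departures from real data: vascular length
density is a few-fold higher than real hippocampal tissue (more signal per
training block; none of the tests depend on density matching); the PSF is
isotropic with no stripe or vignetting artifacts; intensities and SNR are
plausible stand-ins, not calibrated to any instrument; rare trunk vessels
wider than 20 µm diameter are not emulated — consistent with the known
limitation that very large broken-wall lumens defeat automatic filling.
Passing the phantom tests therefore demonstrates the pipeline's mechanics
(blocking, fusion, filling, topology, densities) and desk-scale
learnability, not segmentation accuracy on any particular microscope's
data.

## Desk-scale problem sizes

The test suite trains the width-halved configuration (4, 6, 8 channels,
37 713 parameters) on 60 phantom blocks of 64³ voxels for 30 epochs — about
six minutes on one CPU core — reaching held-out Dice ≈ 0.96 and
clDice ≈ 0.98 with post-processing; the three-scale vs one-scale ablation
comparison and a 256³ worker-invariance segmentation run at similar scale.
The reference-width network is used where only architecture matters
(parameter accounting, shape contracts).  These sizes are the package's
own test design: large enough to exercise every code path and the learning
dynamics, small enough to run routinely.

## Known limitations

* Training is single-sample (no batching) and CPU-bound; the engine is
  written for clarity and testability, not throughput on large clusters.
* Lumens of very large vessels with broken walls are not recoverable by
  the plane-wise fill and would need manual correction.
* Non-integer resampling factors, anisotropic PSFs, and chunked
  hierarchical storage (HDF5/zarr) are out of scope.
* The MPI deployment of the worker-pool contract is not included; the
  serial and thread backends implement the same deterministic semantics.
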