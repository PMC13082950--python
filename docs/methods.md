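# Methods

`gatan` implements a topology-aware 3D vascular segmentation pipeline — a
variable-window attention network with graph-based multi-scale aggregation,
trained with a structural objective that supervises segment existence and
connectivity on top of voxel-wise cross-entropy — together with the synthetic
vascular phantoms needed to exercise it end to end on a CPU.

## The segmentation model

**Backbone.** A strided 3³ convolutional stem halves the input resolution and
feeds a hierarchy of transformer stages (default two). Each block splits its
channels into four equal groups sharing one QKV projection:

* group 0 attends inside local **cubic windows** (default 4³) — compact
  volumetric context;
* groups 1–3 attend inside **stripe windows** bounded in two axes (default
  thickness 4) and spanning the full height, width or depth axis — long-range
  context oriented along each principal direction, which suits elongated
  vessels.

Adjacent blocks alternate regular and shifted partitioning: in the shifted
block every window is cyclically displaced by half its size along each bounded
axis, and an additive mask (−10⁹ pre-softmax) forbids attention between tokens
that originated in different pre-shift windows. The four group outputs are
concatenated, fused by a shared linear projection, added residually, and
followed by a pre-norm feed-forward residual. The number of tokens along an
unbounded stripe axis is capped (default 128); the config validator rejects
stage resolutions above the cap.

**EMA refinement** (optional per config). Coordinate attention pools the
feature along each axis pair to per-axis channel descriptors, mixes them
through a shared bottleneck (1×1×1 channel maps) and emits per-axis sigmoid
gates; a parallel 3³ convolution branch widens the local receptive field.
Global-average statistics of both branches are summed and applied as a
channel-wise sigmoid reweighting of the input. The block is therefore a pure
gating operation: outputs shrink the input by factors in (0, 1).

**MSGA** (optional per config). Each encoder level is passed through a
*grapher*: every voxel-node links to its `graph_k` (default 9, desk configs 4)
nearest neighbors **in feature space**, the message is the element-wise
maximum of neighbor-minus-center differences ("max-relative" aggregation), and
a linear update plus residual closes the block. Neighbor selection is
detached from the gradient. Each decoder skip then receives its own grapher
output concatenated with every deeper grapher output (1×1×1 channel
alignment, nearest-neighbor resize), refined by a 3³ convolution and added
residually to the plain skip. With the flag off the decoder consumes the
plain skips, bit-identically.

**Decoder and heads.** Symmetric nearest-×2 upsampling with 3³ merge
convolutions; a parallel full-resolution 3³ convolution on the raw input is
concatenated before the final refinement so the head can recover 1-voxel
detail that the strided stem discards (without it the desk-scale model
plateaus around Dice 0.88 on a clean tube phantom). The voxel head is a 1×1×1
convolution to C classes. Existence logits are **pooled from the class logit
maps**, not a separate branch: global average per foreground class
(multi-class task) or averages over a 2×2×2 grid of subvolumes (binary task).

## The training objective

`L_total = α·L_pixel + λ₁·L_exist + λ₂·L_conn`, defaults α = 1, λ₁ = 0.7,
λ₂ = 4.

* **L_pixel** — softmax cross-entropy. The restricted form that averages over
  non-background voxels only is the `pixel_loss` default; the trainer lifts
  the restriction because in isolation it has a degenerate optimum (predict
  every voxel foreground). For the 13-class task the trainer additionally
  weights voxels by inverse square-root batch class frequency (full inverse
  weighting makes background false positives nearly free) and upweights
  label-boundary voxels (default ×5) — thin communicating segments occupy
  well under 1% of the voxels each and their contested junction voxels are
  otherwise unlearnable in a short run. An all-background patch contributes
  0 with a warning rather than aborting.
* **L_exist** — mean sigmoid binary cross-entropy over per-class existence
  cells (multi-class; labels derived from the patch ground truth) or
  per-subvolume occupancy cells (binary, 2×2×2 grid).
* **L_conn**, multi-class — for class pairs (a,b), the penalty
  ‖max(0, Pa⊙Pb − Dilate(Pa⊙Pb, K))‖₁ on softmax probability maps, batch-mean.
  With any structuring element containing the origin, grayscale dilation
  dominates its input, so the penalty over the *anatomically valid* pair set
  is identically zero (this is kept as a regression-tested property). The
  default mode therefore evaluates the penalty over the **complement** of the
  valid set — the implausible pairings — which is the only reading under
  which the term penalizes anything; the literal mode is retained. K defaults
  to the full 3³ element; dilation uses zero (background) padding.
* **L_conn**, binary — soft clDice: `1 − 2·Tprec·Tsens/(Tprec+Tsens)` with
  Tprec = |S(P)∩G|/|S(P)|, Tsens = |S(G)∩P|/|S(G)|, soft intersection =
  product, |·| = sum, ε = 10⁻⁶ in every denominator. S(·) is differentiable
  soft skeletonization: iterated soft erosion (minimum of directional 3-wide
  min-pools) and opening, accumulating the residue; default 10 iterations at
  phantom scale. Borders use +∞ fill for min-pools (no erosion from the
  volume boundary); a 1-voxel line embedded in background is returned
  unchanged.

Two further trainer choices matter in practice. The optimized objective adds
an **auxiliary macro soft-Dice term** (weight 2 by default) to the weighted
sum above: cross-entropy alone barely moves the overlap of ~50-voxel
segments, and the CE+Dice compound is the standard remedy; the three
published terms are still computed and logged separately, and the logged
total is the optimized objective. And because left/right arterial classes
are not separable from local appearance (the network is otherwise
translation-equivariant), the input carries **global coordinate channels**
— normalized patch-in-volume coordinates plus Fourier harmonics (default 4
per axis), with higher-frequency harmonics (default 8) concatenated directly
to the 1×1×1 head so region carving is nearly linear. The head itself is
initialized near zero: with Kaiming initialization the initial logits are
confidently wrong (std ≈ 8) and the resulting early gradient spike inflates
Adam's second-moment estimates enough to stall the whole run.

## Evaluation metrics

Binary: Dice, precision, hard-skeleton clDice (3D thinning via
`skimage.morphology.skeletonize` — distinct from the soft training operator)
and average symmetric surface distance in mm (surface = foreground voxels
with a background 6-neighbor, array borders counting as background; mean of
the two directed mean nearest-surface distances, via Euclidean distance
transforms). Conventions: both-empty Dice/clDice = 1; empty-prediction
precision = 1 iff the reference is also empty; ASD with an empty mask is
reported as missing, never 0. Multi-class: per-class Dice
2TP/(2TP+FP+FN) macro-averaged over the 13 foreground classes; a class absent
from both prediction and reference scores 1 by default (correctly predicting
absence is success; `absent_policy="exclude"` drops it from the mean
instead). Probabilities are thresholded at 0.5 (binary) or argmax
(multi-class) before metrics.

## Synthetic phantoms

The generators emulate the *statistical* failure modes the method targets,
not physically accurate OCTA/MRA signal formation:

* **Trees** — binary-branching tubes with per-level radius taper
  `r_child = r_parent · (1 − (1−taper)·U(0.8, 1.2))` (clipped to ≤ 1 so taper
  is monotone; exactly 1 when `taper = 1`). Rasterization labels a voxel with
  a class iff its center lies within the edge radius (crisp labels, no
  partial volume; overlaps resolve to the smaller class index; the tube
  radius of an edge is its parent-node radius).
* **OCTA-like volumes** — several trees in one binary label volume; intensity
  adds a depth-layered background banding (a stand-in for plexus layering —
  real Retina3D layer structure and voxel spacing are not public);
  corruption = multiplicative log-normal speckle plus slice-wise flow
  dropouts (runs of attenuated cross-sections along the first axis). Labels
  are never corrupted.
* **Circle of Willis** — 13-class stylized geometry (BA, PCA-L/R, MCA-L/R,
  ICA-L/R, Pcomm-L/R, Acomm, ACA-L/R, 3rd-A2) built from jittered polylines;
  default 64³ (tests use 48³), isotropic 0.6 mm spacing. The *base* circle
  carries 12 segments; `extra_3rd_a2` adds the accessory A2 segment, and the
  `missing_*` variants delete the named communicating artery entirely, so the
  existence vector of `missing_acomm` is 0 at Acomm (and at 3rd-A2, which
  only the extra variant contains). The canonical adjacency list ships as an
  editable constant; a phantom's adjacency is that list restricted to its
  present classes. MRA corruption = smooth multiplicative bias field
  (normalized to spatial mean 1) plus additive Gaussian noise.

Every generator is a pure function of its parameters and seed; existence
vectors are validated against labels on construction. Passing tests on these
phantoms demonstrates mechanical and topological correctness of the pipeline,
not clinical performance on real OCTA/MRA data.

## Training harness and problem sizes

The numerical core is an in-package reverse-mode autodiff engine over numpy
(float32), with a dedicated conv3d primitive; Adam is the optimizer.
Determinism: all initialization and sampling flow from `numpy` Generators
seeded by the config seed, so runs are bit-reproducible on CPU.

Desk-scale defaults used throughout the tests: two stages of 8/16 channels,
32³ patches, `graph_k = 4`, batch 1, Adam with cosine-decayed lr (2×10⁻³
binary, 5×10⁻³ multi-class; the published constant initial rate of 0.01 is
the full-protocol default). Training patches are sampled centered on
foreground, with the center class drawn uniformly among present classes in
the multi-class task so rare thin segments are seen as often as trunks. The
`overfit_smoke` run trains ≤ 300 steps to memorize a single noise-free
phantom (binary 32³ tube phantom; 48³ missing-Acomm CoW phantom sampled as
32³ patches) and evaluates on that same phantom via Gaussian-blended
sliding-window inference, stopping early once the score clears its bar with
margin. The published-scale protocol
(96×120×120 patches, lr 0.01, batch 2, 1000 epochs) validates and constructs,
but running it is outside this package's envelope: the grapher's exhaustive
feature-space k-NN is quadratic in the voxel count of a stage, which is the
known scalability limit of the implementation.

Variant-stratified splitting allocates each stratum 6:2:2 (largest shares
first, remainders to train first); membership depends only on the id set and
seed, not input order. Patch sampling guarantees a configurable fraction of
foreground-containing patches by centering on random foreground voxels;
undersized volumes are symmetrically zero-padded.

## Known limitations

* The grapher k-NN is exhaustive (O(N²) per stage); full-resolution clinical
  volumes require subsampled or approximate neighbor search not implemented
  here.
* Phantom realism is deliberately minimal — no hemodynamics, no scanner point
  spread, no inter-subject anatomy beyond the modeled CoW variants.
* The existence head is pooled from voxel logits; a dedicated branch could
  decouple detection from segmentation but is not part of this design.
* Soft skeletonization erodes nothing across the volume border (+∞ fill);
  structures touching the border keep their boundary voxels.
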