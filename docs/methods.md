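# Methods

`grapedet` implements a single-class (extensible to multi-class) one-stage
detector for grape bunches in unstructured orchard imagery, in the YOLO v4
family with three additions: parameter-free SimAM attention after every
backbone stage, a weighted path-aggregation neck with fast-normalized fusion
weights, and a focal-modulated composite loss.  This note records the model,
the numerical choices, and what the synthetic test bed does and does not
establish.

## Detector

**Backbone (SAM-CSPDarkNet).** A stem convolution (3x3, 32 ch) followed by
five cross-stage-partial stages with residual-block repeats (1, 2, 8, 8, 4).
Each stage downsamples by 2 with a stride-2 3x3 convolution, splits channels
into a transformed branch (1x1 -> n x residual blocks -> 1x1) and a bypass
branch, concatenates and merges with a 1x1 convolution, then applies SimAM.
Backbone convolutions use Conv + BatchNorm + Mish (`x * tanh(softplus(x))`,
with an overflow-guarded softplus).  For a 608x608 input the exported
pyramid levels are P3 76x76x256, P4 38x38x512, P5 19x19x1024.  The stage
table that motivated this layout labels its middle stage without the
attention suffix while the architecture diagram attaches attention to all
five stages; we follow the diagram (attention after every stage) and expose
a per-stage mask (`attention_stages`) for the literal-table variant.

**SimAM.** For each channel with mean `mu` and population variance `s2`
(computed over all M pixels of that channel, per sample — no leave-one-out
correction, no cross-batch mixing), the minimal energy of a pixel with
activation `t` is

    e*(t) = 4 (s2 + lam) / ((t - mu)^2 + 2 s2 + 2 lam),      lam = 1e-4,

and the refined feature is `sigmoid(1/e*) * x`.  A constant channel forces
`e* = 2` everywhere regardless of `lam`; pixels deviating more from the
channel mean receive strictly larger weights.  The block has no learnable
parameters, which the tests assert via parameter-count parity.

**Neck.** P5 passes through three 1x1/3x3 convolutions, SPP (identity plus
same-padded max pools with kernels 5/9/13, implemented as compositions of
3x3 stride-1 pools, which are exactly equivalent under -inf padding), and
three more convolutions.  The path-aggregation module runs top-down
(upsample, fuse, five-convolution block) and bottom-up.  Fusion nodes carry
one learnable scalar per input edge, initialized to 1, normalized as
`w_i = relu(r_i) / (sum_j relu(r_j) + eps)` with `eps = 1e-4`; the weight
vector is therefore non-negative and sums to 1 up to `eps / sum`.  The
bottom-up mid-scale node is the three-input jump connection
`P4_out = ConvGroup(w0 P4'' + w1 Down(P3_out) + w2 P4)`, with ConvGroup a
3x3 followed by a 1x1 standard convolution; the coarse level is
`P5_out = ConvGroup(concat(Down(P4_out), P5))`.  The fusion module runs
once (not repeated).  Neck and head convolutions use LeakyReLU (slope 0.1).
The exact channel widths inside the five-convolution blocks are the YOLO v4
convention (alternating 1x1/3x3 halving and restoring channels).

**Heads.** One per scale: a 3x3 channel-doubling convolution and a linear
1x1 projection to `3 * (5 + C)` channels (tx, ty, tw, th, objectness, C
class logits per anchor).  The projection weights are initialized small
(He init scaled by 0.08, zero bias) so that initial decoded boxes sit at
their anchors; without this the box regression starts half-saturated and a
short optimization can strand size offsets (see "Decoding").

**Decoding.** Center `(sigmoid(t_xy) + cell) * stride`; size
`anchor * exp(4 tanh(t_wh / 4))`.  The smooth bound on the log-size offset
(range e^-4 … e^4 times the anchor) keeps `exp` finite while preserving a
non-zero gradient everywhere — a hard clamp zeroes the gradient beyond the
bound and permanently strands any offset that drifts past it.  Training and
inference use the same parameterization.

## Loss

Total loss over the three scales s, divided by batch size:

    L = sum_s [ lambda_conf L_fl(l_conf) + lambda_cls L_fl(l_cls) + lambda_loc l_loc ]
        / batch_size,        lambda_* = 1.

* **Confidence**: binary cross-entropy of objectness over object and
  no-object cells, focal-modulated: `-alpha (1-p)^gamma ln p` for positives,
  `-(1-alpha) p^gamma ln(1-p)` for negatives, defaults `alpha = 0.75`,
  `gamma = 2`.  Natural logarithm; probabilities clamped to
  [1e-7, 1 - 1e-7].
* **Classification**: focal BCE over object cells with symmetric label
  smoothing, positive target `1 - eps/2 = 0.9975`, negative `eps/2`
  (`eps = 0.005`).  The symmetric form is used because with a single class
  the `y(1-eps) + eps/K` form degenerates to a no-op.
* **Location**: CIoU over object cells,
  `1 - IoU + rho^2/c^2 + alpha nu`, with `rho` the center distance, `c` the
  enclosing-box diagonal, `nu = (4/pi^2)(arctan(w_gt/h_gt) - arctan(w/h))^2`
  and `alpha = nu / ((1 - IoU) + nu)` treated as a constant in the backward
  pass (the standard CIoU convention).  No focal modulation on CIoU.

**Target assignment.** Each ground-truth box is assigned to the anchor of
highest shape IoU (boxes corner-anchored) at the grid cell containing its
center, on that anchor's scale.  Anchors with shape IoU above 0.5 to some
ground truth that are not the best match are excluded from the no-object
mask (static ignore region, threshold configurable via
`LossConfig.ignore_iou`).  This static approximation of the dynamic
predicted-IoU ignore rule is cheap and adequate for dataset-scale training;
on severely data-limited overfit runs the permanently unsupervised cells can
drift to high confidence, which is why the ignore threshold is configurable.

## Training recipe

Two stages: stage 1 freezes all backbone parameters (epochs 30, batch 8,
initial LR 1e-3), stage 2 fine-tunes everything (epochs 10, batch 2, initial
LR 1e-4).  The schedule presupposes a pretrained backbone checkpoint
(`fit(backbone_checkpoint=...)`); without one the model starts from seeded
random initialization, which is what the tests use.  Cosine annealing per
stage, restarting at the stage boundary, from LR0 to 0.01 LR0.  Images are
letterboxed to the network input and the content randomly shrunk by a factor
uniform in [0.7, 0.9] inside the canvas.  The optimizer is Adam (the recipe
source names none; SGD is available by configuration).  An optional 4-image
mosaic composite is implemented but off by default.  Training is fully
seeded and bit-reproducible.

## Anchors

K-means on ground-truth (w, h) pairs with distance `1 - IoU` between
corner-anchored boxes (the standard choice for YOLO anchor clustering, and
the one consistent with reporting an IoU-style accuracy); squared Euclidean
on (w, h) is available behind `metric="euclidean"`.  Centers update as
per-cluster means; empty clusters reseed from the worst-fitted box; best of
10 seeded restarts by total distance.  Note the mean is the exact minimizer
only for squared Euclidean distance, so the per-step monotonicity assertion
is enforced on that metric; under `1 - IoU` the mean update is a heuristic
and small per-step increases can occur.  The quality score is the mean over
boxes of the best IoU to any anchor.  Nine anchors are grouped three per
scale by ascending area (ties broken by width): smallest to the stride-8
head, largest to stride-32.

## Evaluation

Greedy VOC-protocol matching per image: detections in descending score claim
the unmatched ground truth of highest IoU when that IoU >= 0.5 (threshold
configurable); duplicates are false positives.  Precision, recall and F1
follow the usual definitions with an explicit zero-division policy.  AP is
the area under the precision-recall curve with all-point interpolation
(`p_interp(r) = max precision at recall >= r`), which integrates the step
curve exactly; the 11-point variant is behind a flag.  Multi-class AP
averages unweighted over classes.

## Synthetic scenes

The fixture generator renders schematic orchard images: a leafy cluttered
background, grape bunches as clusters of overlapping shaded ellipses with
stems and specular highlights, leaf-shaped occluders covering a requested
fraction of each bunch's pixel mask (measured coverage is recorded, so tests
can assert occlusion within +-5%), and three illumination modes (front
light, backlight with a sky gradient, low light).  Ground-truth boxes span
the full bunch extent including occluded parts, mirroring how whole clusters
are annotated in field datasets.  Rendering is a pure function of the scene
spec.  These scenes exercise geometry, bookkeeping and the training loop;
they do not establish detection accuracy on real orchard imagery — colors,
textures and scale statistics are far simpler than field data.

## Problem sizes used by the test suite and acceptance script

The architecture contract is checked at the published full size
(608x608, width 1.0, repeats (1, 2, 8, 8, 4); 61.4 M parameters, a few
seconds per CPU forward).  Training behavior is exercised on a reduced
configuration chosen for CPU-scale runs: 128x128 input, width multiplier
0.25, one residual block per stage (~3 M parameters).  The overfit smoke
test trains this tiny model for 200 steps (Adam, LR 1e-3, cosine annealing,
batch of both images) on two single-bunch synthetic scenes, with the nine
anchors clustered from the planted box sizes jittered by factors
0.7–1.3; it then requires the loss to fall below 20% of its initial value
and every planted bunch to be re-detected at IoU >= 0.5.  The smoke run
detects at a 0.25 confidence threshold rather than the library default of
0.5: with the focal positive term's (1-p)^2 damping, 200 steps from random
initialization localize boxes exactly but leave objectness only partially
calibrated (observed final positive confidences 0.5–0.9), and the recovery
criterion scores recall of planted boxes, which additional low-score
detections cannot inflate.  Observed behavior: the loss ratio settles
around 2% and recovery is exact.

## Known limitations

* The numerical backend is a purpose-built numpy autodiff engine; it is
  exact (finite-difference-checked) but not fast.  Full-dataset training at
  608x608 is out of reach on a CPU; the package targets correctness,
  ablations-in-miniature and pipeline tooling, with the architecture
  faithful at full size.
* Pretrained backbone weights are accepted but not shipped; headline
  field-data accuracies therefore cannot be reproduced here.
* The static ignore region approximates the dynamic predicted-box rule.
* BatchNorm statistics keep updating during the frozen stage (parameters are
  frozen, running statistics are not) — the usual convention.
* The VOC writer emits integer coordinates (round half-up); the reader
  accepts 0- and 1-based files verbatim, since box-level IoU tests are
  insensitive to one pixel.
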