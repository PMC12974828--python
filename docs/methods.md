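# Methods

`dermprune` implements a parameter-efficiency workflow for CNN classifiers
of dermoscopy-style RGB images: activation-sparsity-guided layer
truncation with retraining, the Avg-TopK pooling operator, SMOTE class
rebalancing with exact strategy arithmetic, and an augmentation/training
harness.  This note records the models, the defaults and the design
choices, and what the desk-scale experiments do and do not show.

## Model representation and execution

Models are explicit layer DAGs (`ModelGraph`): typed nodes (input, conv2d,
separable_conv2d, batch_norm, relu_activation, max/avg_topk/global
pooling, add_merge, dense, softmax, flatten, dropout) stored in a fixed
topological order and serialized losslessly to JSON.  All surgery —
truncation, head reattachment, pooling replacement — operates on this
representation.

Execution is a compact NumPy engine (`engine.py`): vectorized forward and
backward passes for every node kind plus He-normal initialization and
Adam.  Convolutions use `sliding_window_view` + `einsum`; the separable
convolution is a per-channel k×k depthwise filter followed by a 1×1
pointwise projection, counted as `k²·C_in + C_in·C_out` parameters (no
bias before batch norm; batch norm counts 4C including running
statistics).  Batch norm uses batch statistics during training (running
momentum 0.99, ε=1e-3) and running statistics at inference, so inference
is fully deterministic.  The engine targets desk-scale models on one CPU,
not GPU throughput.

### Backbone

`build_xception` produces a separable-convolution backbone with entry
flow (two stem convolutions, then three downsampling residual blocks of
128/256/728 channels), a configurable middle flow (residual blocks of
three 728-channel separable convolutions), an exit flow (728/1024
downsampling residual block, then 1536/2048 separable convolutions) and a
global-average-pool + dense + softmax head.  A width multiplier rescales
every channel count.

The arrangement is post-activation (conv → BN → ReLU, and a ReLU after
every residual add).  The ReLU that closes block N carries the
conventional `blockN_sepconvM_act` name, so published cut-point names such
as `block12_sepconv3_act` address valid block boundaries.  This differs
from the Keras pre-activation naming, where those names sit strictly
inside residual branches; the post-activation choice makes every published
cut name a well-defined truncation frontier.  The full-scale backbone
(width 1.0, 8 middle blocks) has 20,875,823 parameters with the 7-class
head — the published total for this architecture family is ~20.9 M, with
an unspecified head, so only relative parameter structure is asserted.

The **micro preset** (width 0.125, 2 middle blocks, 32 px input,
192,118 parameters) is used for every experiment in the test suite; full
forward/backward passes of the full-scale model are out of desk-scale
budgets and nothing in the algorithms depends on absolute width.

## Avg-TopK pooling

For a pooling window holding values Y₁ ≥ Y₂ ≥ … the operator returns
(1/K)·Σᵢ≤K Yᵢ — the mean of the K largest values.  K=1 reproduces max
pooling; K = window² reproduces average pooling.  On the worked window
[[1,5,2],[3,8,6],[4,7,0]] with K=3 the output is (8+7+6)/3 = 7 (max
pooling would give 8, full averaging 4).

Decisions the operator needed that its definition leaves open:

* **Ties** at the K-th value are broken by row-major scan order (a stable
  argsort), making forward and backward deterministic.
* **Padding**: "valid" by default; under "same" padding, padded cells are
  excluded from the ranking and K is clamped to the number of real cells.
* **Backward**: each selected position receives `upstream/K`; unselected
  positions receive zero; overlapping windows accumulate additively.  Off
  ties this is the exact gradient of the forward formula, verified against
  central finite differences to 1e-5 relative error.
* `replace_max_pooling(graph, K)` swaps every max_pool node for
  avg_topk_pool with identical window/stride/padding, K defaulting to 3 —
  the published replacement setting.  Global average pooling in the head
  is not touched.

## Sparsity-guided truncation

Layer importance is read from activation sparsity on a validation batch
(default B=16): S(l) = (1/B) Σ_b #zeros(a_{l,b})/size(a_{l,b}).  Only
post-ReLU outputs are profiled (ReLU emits exact zeros, so the default
zero tolerance is 0.0; it is configurable for other activations).  The
network is truncated at the maximal-sparsity layer — the induced subgraph
on that layer's ancestors, with ties going to the earliest layer (the more
aggressive cut) — a fresh global-average-pool + dense + softmax head is
attached, and the reduced architecture is retrained **from scratch**
(full re-initialization; an inherit-weights mode exists but is off by
default, since the procedure is defined as retraining the reduced
architecture anew).

On a DAG, "remove everything after layer k" needs a validity notion: a
cut is rejected (`InvalidCutError`, with the nearest valid cuts listed)
when some discarded add-merge has the cut inside one but not all of its
branches — i.e. the cut splits an unmerged residual branch.  Block
boundaries always pass.  Automatic cut selection further restricts
candidates to separable-block boundary activations: the stem activations
are excluded (cutting there leaves no separable backbone) and so is the
terminal backbone activation (truncating there is the identity).  The full
profile over every ReLU is still computed and emitted; the restriction
applies only to the automated argmax.  With copied weights a truncated
model reproduces the full model's activation at the cut exactly (the same
operations run on the same inputs), which the tests assert at 1e-6.

Truncating the full-scale backbone at `block12_sepconv3_act` removes
32.6% of its parameters — asserted as a 30–40% band rather than an exact
figure because the published totals include an undocumented head.

## Class rebalancing

`target_counts` implements four strategies on per-class counts: *minority*
(only the single smallest class is raised to the largest count),
*not-minority* (every class except the smallest raised), *not-majority*
(every class except the largest raised), and *k× multiplier* (every
non-largest class set to min(k·count, largest count)).  A tie for the
smallest class changes the result and raises an error unless a tie-break
index is supplied; ties for the largest never change the outcome.  Note
the published strategy table contains three cells inconsistent with its
own stated multipliers (mel at 2× and 4×, bkl at 3×); the implementation
follows the arithmetic.

SMOTE synthesis: for each class below target, base samples cycle through
a seeded shuffle; a neighbour is drawn uniformly from the base's k=5
nearest same-class neighbours (Euclidean distance on flattened features,
self excluded, distance ties broken by ascending index, k clamped to
class size − 1); λ ~ U(0,1); the synthetic sample is the elementwise
convex combination x_i + λ(x_nn − x_i).  Originals pass through
bit-for-bit and synthetic items are provenance-tagged.  Both pixel-space
(images as 0–255 tensors) and deep-feature-space inputs are supported —
the container is agnostic — with pixel space as the pipeline default,
since the interpolation equations are stated on 128×128×3 images.
Resampling applies to training splits only; the test split is never
touched.

## Augmentation and training

The augmentation recipe: rescale 1/255, rotation up to ±10°, width/height
shifts up to ±20%, shear up to ±0.2, independent horizontal and vertical
flips, out-of-frame pixels filled by nearest-neighbour (edge) replication,
outputs clipped to [0,1].  `balance_with_augmentation` fills each class's
deficit with augmented copies of seeded-randomly drawn parents
(provenance `augmented`), stored back in the 0–255 domain so the training
set stays homogeneous.  Augmentation is applied as a static balancing
stage rather than per-batch regeneration; test images receive rescale
only.

Training protocol defaults: Adam at 1e-3, sparse categorical
cross-entropy on integer labels, batch size 16, up to 50 epochs, 20%
validation split, early stopping after 10 epochs without validation-loss
improvement with best-weights restoration, learning rate ×0.1 after a
3-epoch plateau.  Softmax and cross-entropy are differentiated jointly for
stability.  The train/test split is a seeded uniform 80/20 split without
stratification (published per-class training counts deviate from exact
80% per class, the signature of a global split).

Metrics are support-weighted precision/recall/F1 plus accuracy and the
confusion matrix, reported as percentages to two decimals.  Weighted
averaging was chosen because weighted recall equals accuracy
algebraically, matching reports in which the two nearly coincide; macro
averaging can be obtained by calling scikit-learn directly on the stored
predictions.

## Synthetic data generator

Each image is a skin-toned background with one elliptical lesion whose
colour offset, eccentricity, border roughness and internal texture
frequency are drawn from class-conditional distributions, plus pixel
noise; `difficulty` scales the class separation (larger = easier).  The
default class table mirrors the seven-class dermoscopy distribution
(6705/1113/1099/514/327/142/115; 10,015 images).  Generation is bitwise
deterministic per seed.

The generator's contract is statistical: classes separable by a fixed
simple classifier, monotonically less so as `difficulty` shrinks, with
exact controllable imbalance.  It does **not** emulate dermatological
appearance, acquisition artefacts (hairs, rulers, vignetting),
intra-class heterogeneity or label noise — so passing tests demonstrate
the correctness and direction-of-effect of the pipeline machinery, not
clinical performance on real dermoscopy archives.

## Desk-scale study conditions

The end-to-end checks run on a 701-image draw with the published
imbalance proportions (counts scaled by 0.07, minimum 8 per class) at
32 px with the micro backbone and equal 4-epoch training budgets, over
three seeds.  Under these conditions the pruned-retrained model's
accuracy stays within 5 points below the unpruned baseline (median over
seeds; in the pilot it was ~7 points *above*), and the
resampled+augmented Avg-TopK run's weighted F1 is at least the
no-resampling run's (median over seeds) — the qualitative direction of
the published ablation.  Absolute published metrics (e.g. 91.52%
accuracy) are not reproducible here: they require the real 10,015-image
archive, the full-width backbone and long training.

## Pipeline and reproducibility

`run_pipeline` fixes the stage order Pruning → SMOTE → Augmentation
(pruning first because it fixes the architecture), with optional pooling
replacement before the final training; stages can be skipped but not
reordered.  Every stochastic stage derives its seed as
SHA-256(global_seed, stage name) mod 2³¹, so runs are reproducible from a
single seed, and each stage writes its artifact (graph JSON, profile CSV,
manifests with provenance, history CSV, metrics JSON) plus the fully
resolved configuration.

## Known limitations

* The engine is CPU/NumPy; full-scale training is out of scope by design.
* No weight-magnitude, filter or channel pruning; no search over multiple
  cut points beyond reporting the profile.
* ADASYN and other SMOTE variants are not implemented.
* The 2-D warp used for augmentation applies shear/rotation about the
  image centre with bilinear interpolation; it is not a re-implementation
  of any specific framework's generator and matches it only in the
  transformation ranges.
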