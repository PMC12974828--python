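# dermprune

Parameter-efficient CNN classifiers for dermoscopy-style skin-lesion
images: **activation-sparsity-guided layer pruning** with retraining, the
**Avg-TopK pooling** operator, **SMOTE** class rebalancing with exact
strategy arithmetic, and an augmentation/training harness — all on an
explicit layer-DAG model representation executed by a compact NumPy
engine, with a seeded synthetic data generator so the whole pipeline runs
with no external image archive.

It is aimed at researchers studying model-compression and
class-imbalance interventions for skin-lesion classification (the
seven-class dermoscopy setting: nv, mel, bkl, bcc, akiec, vasc, df) who
need the individual interventions as reusable, deterministic, testable
library operations.

## The methods

**Sparsity pruning.** After training, a validation batch of B images is
pushed through the network and each ReLU layer l gets a sparsity score

    S(l) = (1/B) · Σ_b  #zeros(a_{l,b}) / size(a_{l,b}),

the batch-averaged fraction of exactly-zero activations.  High sparsity is
read as low importance: the network is truncated at the maximal-sparsity
layer (keeping that layer and all of its ancestors), a fresh
global-average-pool + dense + softmax head is attached, and the reduced
architecture is retrained from scratch.  Truncating the full-scale
backbone at `block12_sepconv3_act` removes ≈33% of its parameters.

**Avg-TopK pooling.** Each pooling window returns the mean of its K
largest values, (1/K)·Σᵢ≤K Yᵢ with Y₁ ≥ Y₂ ≥ …, interpolating between max
pooling (K=1) and average pooling (K=window²).  `replace_max_pooling`
swaps every max-pool node for Avg-TopK (default K=3) without touching any
other layer.

**Imbalance strategies.** Per-class target counts under *minority* /
*not-minority* / *not-majority* / *k× multiplier* semantics, then SMOTE:
synthetic samples x_new = x_i + λ·(x_nn − x_i) with λ ~ U(0,1) and x_nn
one of the k=5 nearest same-class neighbours — applied per pixel per
channel in pixel space, or to deep feature vectors.  Augmentation
(rotation ≤10°, shifts ≤20%, shear ≤0.2, flips, nearest-neighbour fill)
can then equalize class counts.  Training uses Adam 1e-3, batch 16, ≤50
epochs, early stopping (patience 10) and reduce-on-plateau (×0.1,
patience 3), with support-weighted metrics.

## Worked example

```python
import dermprune.engine as engine
from dermprune import (SyntheticSpec, generate_dataset, build_xception, topk_mean,
                       target_counts, ImbalanceStrategy, SparsityConfig, TrainConfig,
                       split_train_test, train)
from dermprune.graph import MICRO
from dermprune.pruning import prune_and_retrain
from dermprune.training import predict_labels, compute_metrics

print(topk_mean([1, 5, 2, 3, 8, 6, 4, 7, 0], K=3))
print(target_counts((5331, 908, 872, 420, 272, 114, 95),
                    ImbalanceStrategy("multiplier", 2)).tolist())

counts = (469, 78, 77, 36, 23, 10, 8)   # the published imbalance, scaled down
ds = generate_dataset(SyntheticSpec(class_counts=counts, image_size=32, seed=1))
train_set, test_set = split_train_test(ds, 0.8, seed=1)

graph = build_xception(MICRO)            # width 0.125, 2 middle blocks, 32 px
cfg = TrainConfig(max_epochs=4, seed=1)
weights = engine.init_weights(graph, seed=1)
weights, _ = train(graph, weights, train_set, cfg)
base = compute_metrics(test_set.labels,
                       predict_labels(graph, weights, test_set.features), 7)
print("baseline:", base.accuracy, base.f1)

trained, result, _ = prune_and_retrain(graph, weights, train_set, SparsityConfig(), cfg)
print("cut:", result.cut_layer_id, result.parameters_before, "->", result.parameters_after)
pruned = compute_metrics(test_set.labels,
                         predict_labels(result.pruned_graph, trained, test_set.features), 7)
print("pruned:", pruned.accuracy, pruned.f1)
```

prints

```
7.0
[5331, 1816, 1744, 840, 544, 228, 190]
baseline: 57.45 50.36
cut: block8_sepconv1_act 192118 -> 139766
pruned: 64.54 50.63
```

Reading the numbers: the 3×3 window `[1,5,2,3,8,6,4,7,0]` pools to
(8+7+6)/3 = 7 with K=3 (max pooling would give 8, plain averaging 4); the
2× strategy doubles every non-majority class's training count, capped at
the majority's 5331; on a 701-image synthetic draw the profiler picks the
deep boundary `block8_sepconv1_act`, the cut removes 27% of the micro
model's 192,118 parameters, and the retrained pruned model's test accuracy
(64.54%) stays on par with the unpruned baseline (57.45%) at an equal
4-epoch budget — the qualitative behaviour the pruning strategy is
designed for.  (Numbers are percentages; accuracy equals support-weighted
recall.)

## Command line

```bash
dermprune generate data/ --image-size 32 --scale 0.07 --seed 1
dermprune split data/ splits/ --train-fraction 0.8 --seed 1
dermprune resample-cmd splits/train resampled/ --strategy 2x --seed 1
dermprune pipeline --seed 1 --output-dir runs/demo   # full stage sequence
```

`pipeline` executes generate/load → split → baseline train → sparsity
profile → prune → retrain → SMOTE (train split only) → augmentation
balancing → Avg-TopK replacement → final train → evaluation, writing one
artifact per stage (graph JSON, profile CSV, provenance manifests,
history CSV, metrics JSON) plus the resolved configuration; every stage's
seed derives deterministically from the global `--seed`.

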