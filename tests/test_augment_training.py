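"""Augmentation recipe, balancing, split, training loop and metrics."""

import numpy as np
import pytest

import dermprune.engine as E
from dermprune.augment import AugmentConfig, balance_with_augmentation, sample_augmentation
from dermprune.data import LabeledImageSet
from dermprune.graph import LayerNode, ModelGraph
from dermprune.training import TrainConfig, compute_metrics, split_train_test, train


class _ZeroDraws:
    """Stub RNG: all uniforms 0 (no geometry), random() forces flips."""

    def __init__(self, flip=True):
        self._flip = 0.0 if flip else 1.0

    def uniform(self, lo, hi):
        return 0.0

    def random(self):
        return self._flip


def _dataset(counts, size=12, seed=0):
    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for cls, c in enumerate(counts):
        base = np.zeros((c, size, size, 3))
        base[..., cls % 3] = 200.0
        feats.append(base + rng.normal(0, 10, base.shape))
        labels += [cls] * c
    return LabeledImageSet(np.clip(np.concatenate(feats), 0, 255),
                           np.array(labels), [str(i) for i in range(len(counts))])


class TestSplit:
    def test_sizes_follow_floor_arithmetic(self):
        ds = _dataset((10,))
        tr, te = split_train_test(ds, 0.8, seed=0)
        assert (len(tr), len(te)) == (8, 2)

    def test_same_seed_identical_membership(self):
        ds = _dataset((12, 8))
        a1, b1 = split_train_test(ds, 0.8, seed=3)
        a2, b2 = split_train_test(ds, 0.8, seed=3)
        np.testing.assert_array_equal(a1.features, a2.features)
        np.testing.assert_array_equal(b1.labels, b2.labels)

    def test_ham_sized_split_gives_printed_train_total(self):
        ds = LabeledImageSet(np.zeros((10015, 1)), np.zeros(10015, dtype=int), ["x"])
        tr, te = split_train_test(ds, 0.8, seed=1)
        assert len(tr) == 8012 and len(te) == 2003

    def test_split_is_disjoint_and_exhaustive(self):
        ds = _dataset((9, 7))
        ds.features[:, 0, 0, 0] = np.arange(16)  # unique marker per item
        tr, te = split_train_test(ds, 0.75, seed=2)
        markers = np.concatenate([tr.features[:, 0, 0, 0], te.features[:, 0, 0, 0]])
        assert sorted(markers.tolist()) == list(range(16))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_dataset((4,)), 1.0, seed=0)


class TestAugmentation:
    def test_identity_draw_is_exact_rescale(self):
        img = np.random.default_rng(1).integers(0, 256, (10, 10, 3)).astype(float)
        out = sample_augmentation(img, AugmentConfig(rotation_max_deg=0, width_shift_frac=0,
                                                     height_shift_frac=0, shear_range=0,
                                                     horizontal_flip=False, vertical_flip=False),
                                  _ZeroDraws())
        np.testing.assert_array_equal(out, img * (1.0 / 255.0))  # bit-exact: no warp ran
        np.testing.assert_allclose(out, img / 255.0, rtol=0, atol=1e-15)

    def test_output_range_contract(self, rng):
        img = rng.integers(0, 256, (16, 16, 3)).astype(float)
        for _ in range(10):
            out = sample_augmentation(img, AugmentConfig(), rng)
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_flip_only_draw_matches_array_reversal(self):
        img = np.random.default_rng(2).integers(0, 256, (8, 8, 3)).astype(float)
        cfg = AugmentConfig(rotation_max_deg=0, width_shift_frac=0, height_shift_frac=0,
                            shear_range=0)
        out = sample_augmentation(img, cfg, _ZeroDraws(flip=True))
        np.testing.assert_allclose(out, (img / 255.0)[::-1, ::-1], rtol=0, atol=1e-15)


class TestBalanceWithAugmentation:
    def test_deficit_filled_with_augmented_copies(self):
        ds = _dataset((10, 4))
        out = balance_with_augmentation(ds, [10, 10], seed=0)
        assert list(out.class_counts()) == [10, 10]
        aug = out.provenance == "augmented"
        assert aug.sum() == 6
        assert all(out.labels[aug] == 1)

    def test_targets_equal_counts_is_noop(self):
        ds = _dataset((5, 5))
        out = balance_with_augmentation(ds, [5, 5], seed=0)
        assert len(out) == 10 and not np.any(out.provenance == "augmented")

    def test_balanced_ratio_within_tolerance(self):
        ds = _dataset((19, 7, 5))
        counts = ds.class_counts()
        out = balance_with_augmentation(ds, np.full_like(counts, counts.max()), seed=1)
        c = out.class_counts()
        assert c.max() / c.min() <= 1.02

    def test_target_below_count_rejected(self):
        with pytest.raises(ValueError):
            balance_with_augmentation(_dataset((5, 5)), [5, 4], seed=0)


def tiny_model(n_classes=2):
    nodes = [
        LayerNode("in", "input", {"shape": (12, 12, 3)}),
        LayerNode("c1", "conv2d", {"filters": 8, "kernel": 3, "stride": 2,
                                   "padding": "same", "use_bias": False}, ("in",)),
        LayerNode("bn1", "batch_norm", {}, ("c1",)),
        LayerNode("r1", "relu_activation", {}, ("bn1",)),
        LayerNode("gap", "global_avg_pool", {}, ("r1",)),
        LayerNode("fc", "dense", {"units": n_classes, "use_bias": True}, ("gap",)),
        LayerNode("sm", "softmax", {}, ("fc",)),
    ]
    return ModelGraph(nodes, "sm")


class TestTrain:
    def test_separable_task_reaches_high_training_accuracy(self):
        ds = _dataset((40, 40), seed=3)  # colour-separable two-class task
        g = tiny_model()
        w = E.init_weights(g, 0)
        w, hist = train(g, w, ds, TrainConfig(max_epochs=15, seed=0))
        assert len(hist["epoch"]) <= 15
        assert max(hist["train_acc"]) > 0.9

    def test_plateau_schedule_reduces_lr_then_stops(self):
        from dermprune.training import PlateauSchedule

        cfg = TrainConfig(learning_rate=1e-3, max_epochs=50, early_stop_patience=10,
                          lr_reduce_patience=3)
        sched = PlateauSchedule(cfg)
        # improvement for 3 epochs, then 10 flat epochs
        losses = [1.0, 0.8, 0.7] + [0.7] * 10
        stops = []
        for v in losses:
            stops.append(sched.update(v)[1])
        # flat window: reductions at flat epochs 3, 6 and 9 -> 1e-3 * 0.1^3
        assert sched.lr == pytest.approx(1e-3 * 0.1**3)
        assert stops[-1] and not any(stops[:-1])  # stops exactly at patience 10

    def test_zero_lr_training_early_stops_at_patience(self):
        ds = _dataset((20, 20), seed=4)
        g = tiny_model()
        w = E.init_weights(g, 1)
        cfg = TrainConfig(learning_rate=0.0, max_epochs=12, early_stop_patience=5,
                          lr_reduce_patience=2, seed=1)
        w, hist = train(g, w, ds, cfg)
        # with frozen weights the validation loss never improves after epoch 1
        assert hist["stopped_epoch"] == 6  # best epoch 1 + patience 5
        assert len(hist["epoch"]) == 6 <= cfg.max_epochs

    def test_divergence_aborts_with_diagnostic(self):
        ds = _dataset((12, 12), seed=5)
        g = tiny_model()
        w = E.init_weights(g, 2)
        w["fc"]["W"][:] = 1e308  # overflow the logits into NaN softmax shifts
        with pytest.raises(RuntimeError, match="diverged"):
            train(g, w, ds, TrainConfig(max_epochs=2, seed=0))


class TestMetrics:
    def test_perfect_predictions(self):
        rep = compute_metrics([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert (rep.accuracy, rep.precision, rep.recall, rep.f1) == (100.0, 100.0, 100.0, 100.0)

    def test_two_class_hand_computation(self):
        # confusion [[3,1],[1,3]]: accuracy 6/8, weighted P/R/F1 all 75.00
        y_true = [0, 0, 0, 0, 1, 1, 1, 1]
        y_pred = [0, 0, 0, 1, 1, 1, 1, 0]
        rep = compute_metrics(y_true, y_pred, 2)
        assert rep.accuracy == 75.0 and rep.f1 == 75.0
        assert rep.confusion == [[3, 1], [1, 3]]

    def test_weighted_recall_equals_accuracy(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 60))
            y_true = rng.integers(0, 4, n)
            y_pred = rng.integers(0, 4, n)
            rep = compute_metrics(y_true, y_pred, 4)
            assert rep.recall == rep.accuracy

    def test_confusion_rows_sum_to_class_counts(self, rng):
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        rep = compute_metrics(y_true, y_pred, 3)
        assert np.array(rep.confusion).sum() == 50
        np.testing.assert_array_equal(np.array(rep.confusion).sum(axis=1),
                                      np.bincount(y_true, minlength=3))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics([], [], 2)
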