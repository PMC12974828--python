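"""Sparsity profiling, cut selection, truncation and head reattachment."""

import numpy as np
import pytest

import dermprune.engine as E
from dermprune.data import LabeledImageSet
from dermprune.graph import GraphError, LayerNode, ModelGraph, ancestors, parameter_count
from dermprune.pruning import (
    InvalidCutError,
    SparsityConfig,
    SparsityProfile,
    activation_sparsity,
    attach_classifier_head,
    candidate_cut_points,
    profile_model,
    prune_and_retrain,
    select_cut,
    truncate,
    valid_cut_points,
)
from dermprune.training import TrainConfig


class TestActivationSparsity:
    def test_all_zero_is_one(self):
        assert activation_sparsity([np.zeros((3, 3))]) == 1.0

    def test_strictly_positive_is_zero(self):
        assert activation_sparsity([np.ones((3, 3))]) == 0.0

    def test_batch_average_of_hand_counts(self):
        a = np.ones(12)
        a[:3] = 0.0  # 3/12 zeros
        b = np.ones(12)
        b[:6] = 0.0  # 6/12 zeros
        assert activation_sparsity([a, b]) == pytest.approx(0.375)

    def test_tolerance_counts_near_zeros(self):
        assert activation_sparsity([np.array([0.0, 1e-9, 1.0, -1e-9])], 1e-8) == 0.75

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            activation_sparsity([])


def hand_net():
    """2-layer 1x1-conv ReLU net on 2x2x1 inputs with known weights."""
    nodes = [
        LayerNode("in", "input", {"shape": (2, 2, 1)}),
        LayerNode("c1", "conv2d", {"filters": 1, "kernel": 1, "padding": "valid",
                                   "use_bias": True}, ("in",)),
        LayerNode("r1", "relu_activation", {}, ("c1",)),
        LayerNode("c2", "conv2d", {"filters": 1, "kernel": 1, "padding": "valid",
                                   "use_bias": True}, ("r1",)),
        LayerNode("r2", "relu_activation", {}, ("c2",)),
    ]
    g = ModelGraph(nodes, "r2")
    w = {
        "c1": {"W": np.ones((1, 1, 1, 1)), "b": np.array([-0.5])},
        "c2": {"W": np.full((1, 1, 1, 1), -1.0), "b": np.array([0.25])},
    }
    return g, w


class TestProfileModel:
    def test_profile_equals_manual_forward(self):
        g, w = hand_net()
        batch = np.array([
            [[[0.0], [1.0]], [[0.25], [0.75]]],
            [[[0.6], [0.6]], [[0.4], [0.2]]],
        ])
        # manual forward, plain numpy: r1 = max(x-0.5, 0); r2 = max(0.25-r1, 0)
        r1 = np.maximum(batch - 0.5, 0.0)
        r2 = np.maximum(0.25 - r1, 0.0)
        exp_r1 = np.mean([(s == 0).mean() for s in r1])
        exp_r2 = np.mean([(s == 0).mean() for s in r2])
        prof = profile_model(g, w, batch, SparsityConfig(batch_size=2))
        assert prof.as_dict() == {"r1": pytest.approx(exp_r1), "r2": pytest.approx(exp_r2)}
        assert exp_r1 == pytest.approx(0.5)  # sanity: 2 of 4 zeros in each sample

    def test_deterministic_profile_and_fingerprint(self):
        g, w = hand_net()
        batch = np.random.default_rng(3).random((4, 2, 2, 1))
        p1 = profile_model(g, w, batch)
        p2 = profile_model(g, w, batch)
        assert p1.entries == p2.entries
        assert p1.batch_fingerprint == p2.batch_fingerprint

    def test_black_images_zero_bias_fully_sparse(self):
        g, w = hand_net()
        w["c1"]["b"][:] = 0.0
        w["c2"]["b"][:] = 0.0
        prof = profile_model(g, w, np.zeros((3, 2, 2, 1)))
        assert all(s == 1.0 for _, s in prof.entries)

    def test_no_candidate_layers_rejected(self):
        nodes = [LayerNode("in", "input", {"shape": (2, 2, 1)}),
                 LayerNode("f", "flatten", {}, ("in",))]
        with pytest.raises(GraphError):
            profile_model(ModelGraph(nodes, "f"), {}, np.zeros((1, 2, 2, 1)))

    def test_all_sparsities_in_unit_interval(self, micro_graph, rng):
        w = E.init_weights(micro_graph, 0)
        prof = profile_model(micro_graph, w, rng.random((2, 32, 32, 3)))
        assert all(0.0 <= s <= 1.0 for _, s in prof.entries)


class TestSelectCut:
    def test_argmax(self):
        prof = SparsityProfile([("a", 0.2), ("b", 0.9), ("c", 0.5)])
        assert select_cut(prof) == "b"

    def test_tie_goes_to_earliest(self):
        assert select_cut(SparsityProfile([("a", 0.9), ("b", 0.9)])) == "a"

    def test_published_profile_shape_selects_block12(self):
        rows = [("block14_sepconv1_act", 79.6), ("block13_sepconv2_act", 90.4),
                ("block12_sepconv3_act", 91.3), ("block11_sepconv3_act", 84.9),
                ("block10_sepconv3_act", 81.0), ("block9_sepconv3_act", 78.7),
                ("block8_sepconv3_act", 79.4), ("block6_sepconv3_act", 78.3)]
        prof = SparsityProfile([(l, s / 100) for l, s in rows])
        assert select_cut(prof) == "block12_sepconv3_act"

    def test_matches_brute_force_on_random_profiles(self, rng):
        for _ in range(50):
            n = rng.integers(1, 12)
            entries = [(f"l{i}", float(rng.random())) for i in range(n)]
            prof = SparsityProfile(entries)
            brute = max(range(n), key=lambda i: (entries[i][1], -i))
            assert select_cut(prof) == entries[brute][0]


class TestTruncate:
    def test_linear_chain_cut(self):
        nodes = [LayerNode("a", "input", {"shape": (4, 4, 3)})]
        for prev, nid in zip("abc", "bcd"):
            nodes.append(LayerNode(nid, "relu_activation", {}, (prev,)))
        g = ModelGraph(nodes, "d")
        cut = truncate(g, "b")
        assert [n.id for n in cut.nodes] == ["a", "b"]
        assert cut.output_id == "b"

    def test_cut_at_final_backbone_node_keeps_backbone(self, micro_graph):
        last_act = [n.id for n in micro_graph.nodes if n.kind == "relu_activation"][-1]
        cut = truncate(micro_graph, last_act)
        assert {n.id for n in cut.nodes} == ancestors(micro_graph, last_act)
        assert cut.output_id == last_act

    def test_prefix_fidelity_with_copied_weights(self, micro_graph, rng):
        w = E.init_weights(micro_graph, 11)
        cut_id = "block3_sepconv2_act"
        backbone, wsub = truncate(micro_graph, cut_id, w)
        x = rng.random((5, 32, 32, 3))
        full_acts, _ = E.forward(micro_graph, w, x, keep={cut_id})
        cut_acts, _ = E.forward(backbone, wsub, x, keep=set())
        np.testing.assert_allclose(cut_acts[cut_id], full_acts[cut_id], atol=1e-6)

    def test_cut_inside_residual_branch_rejected_with_suggestions(self, micro_graph):
        with pytest.raises(InvalidCutError) as err:
            truncate(micro_graph, "block5_sepconv2_act")
        msg = str(err.value)
        assert "block5_sepconv2_act" in msg and "valid cuts" in msg

    def test_valid_cut_points_are_block_boundaries(self, micro_graph):
        cuts = valid_cut_points(micro_graph)
        assert "block6_sepconv3_act" in cuts          # middle-flow boundary
        assert "block5_sepconv1_act" not in cuts      # mid-branch
        assert "block7_sepconv1_act" not in cuts      # exit-flow branch interior

    def test_unknown_cut_rejected(self, micro_graph):
        with pytest.raises(GraphError):
            truncate(micro_graph, "nope")


class TestAttachHead:
    def _spatial_graph(self, channels):
        nodes = [
            LayerNode("in", "input", {"shape": (8, 8, 3)}),
            LayerNode("c", "conv2d", {"filters": channels, "kernel": 3, "padding": "same"},
                      ("in",)),
            LayerNode("r", "relu_activation", {}, ("c",)),
        ]
        return ModelGraph(nodes, "r")

    def test_head_parameter_arithmetic(self):
        g = self._spatial_graph(26)
        with_head = attach_classifier_head(g, 7)
        assert parameter_count(with_head) - parameter_count(g) == 26 * 7 + 7  # 189
        assert with_head.output_id == "softmax"

    def test_double_head_rejected(self):
        g = attach_classifier_head(self._spatial_graph(4), 7)
        with pytest.raises(GraphError):
            attach_classifier_head(g, 7)

    def test_shallower_cut_shrinks_head(self, micro_graph):
        deep = attach_classifier_head(truncate(micro_graph, "block6_sepconv3_act"), 7)
        shallow = attach_classifier_head(truncate(micro_graph, "block2_sepconv2_act"), 7)
        deep_dense = deep.node("predictions")
        shallow_dense = shallow.node("predictions")
        from dermprune.graph import infer_shapes

        assert (infer_shapes(shallow)[shallow.node("avg_pool").predecessors[0]][-1]
                < infer_shapes(deep)[deep.node("avg_pool").predecessors[0]][-1])
        assert parameter_count(shallow) < parameter_count(deep)


@pytest.fixture(scope="module")
def tiny_run(micro_graph, small_imbalanced_set):
    ds = small_imbalanced_set.subset(np.arange(0, len(small_imbalanced_set), 2))
    cfg = TrainConfig(max_epochs=2, seed=5)
    w = E.init_weights(micro_graph, 5)
    return [
        prune_and_retrain(micro_graph, w, ds, SparsityConfig(batch_size=8), cfg)
        for _ in range(2)
    ]


class TestPruneAndRetrain:
    def test_proper_cut_reduces_parameters(self, tiny_run):
        _, result, _ = tiny_run[0]
        assert result.parameters_after < result.parameters_before
        assert result.cut_layer_id in result.pruned_graph
        assert result.pruned_graph.output_id == "softmax"

    def test_end_to_end_determinism(self, tiny_run):
        (_, r1, h1), (_, r2, h2) = tiny_run
        assert r1.cut_layer_id == r2.cut_layer_id
        assert r1.parameters_after == r2.parameters_after
        assert h1["val_loss"] == h2["val_loss"]

    def test_cut_restricted_to_proper_boundaries(self, micro_graph):
        cands = candidate_cut_points(micro_graph)
        assert all("_sepconv" in c for c in cands)
        last_act = [n.id for n in micro_graph.nodes if n.kind == "relu_activation"][-1]
        assert last_act not in cands
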