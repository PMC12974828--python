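"""Activation-sparsity profiling and layer truncation.

The pruning procedure: run a validation batch through the trained model,
measure for every candidate layer (post-ReLU outputs by default) the
fraction of exactly-zero activations averaged over the batch,

    S(l) = (1/B) Σ_b  #zeros(a_{l,b}) / size(a_{l,b}),

cut the network at the layer with maximal sparsity — keeping that layer and
every ancestor — reattach a global-average-pool + dense + softmax head, and
retrain the reduced architecture from scratch.  High sparsity is read as
low layer importance, so everything after the sparsest layer is discarded.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import engine
from .data import LabeledImageSet
from .graph import GraphError, LayerNode, ModelGraph, ancestors, infer_shapes, parameter_count

__all__ = [
    "SparsityConfig",
    "SparsityProfile",
    "PruneResult",
    "InvalidCutError",
    "activation_sparsity",
    "profile_model",
    "select_cut",
    "select_profiled_cut",
    "valid_cut_points",
    "candidate_cut_points",
    "truncate",
    "attach_classifier_head",
    "prune_and_retrain",
]


class InvalidCutError(GraphError):
    """The requested cut sits inside an unmerged residual branch."""


@dataclass
class SparsityConfig:
    """Profiling settings: batch size, zero tolerance, candidate layer kinds.

    ReLU emits exact zeros, so the default tolerance is 0.0; a positive
    tolerance supports activations that only approach zero.
    """

    batch_size: int = 16
    zero_tolerance: float = 0.0
    candidate_kinds: tuple = ("relu_activation",)

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.zero_tolerance < 0:
            raise ValueError("zero_tolerance must be >= 0")


@dataclass
class SparsityProfile:
    """Ordered (layer_id, sparsity) records plus a hash of the batch used."""

    entries: list
    batch_fingerprint: str = ""

    def __post_init__(self):
        if not self.entries:
            raise ValueError("a sparsity profile cannot be empty")
        for lid, s in self.entries:
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"sparsity of {lid!r} is {s}, outside [0, 1]")

    def as_dict(self) -> dict:
        return dict(self.entries)


@dataclass
class PruneResult:
    cut_layer_id: str
    pruned_graph: ModelGraph
    parameters_before: int
    parameters_after: int
    profile: SparsityProfile = field(default=None, repr=False)


def activation_sparsity(batch_activations, tolerance: float = 0.0) -> float:
    """Batch-averaged fraction of (near-)zero activations, in [0, 1]."""
    samples = list(batch_activations)
    if not samples:
        raise ValueError("empty activation batch")
    fracs = [np.mean(np.abs(np.asarray(a, dtype=float)) <= tolerance) for a in samples]
    return float(np.mean(fracs))


def profile_model(graph: ModelGraph, weights: dict, batch: np.ndarray,
                  config: SparsityConfig | None = None) -> SparsityProfile:
    """Sparsity of every candidate layer on a validation batch.

    One inference-mode forward pass per sample; deterministic for fixed
    weights and batch.
    """
    config = config or SparsityConfig()
    batch = np.asarray(batch, dtype=float)
    candidates = [n.id for n in graph.nodes if n.kind in config.candidate_kinds]
    if not candidates:
        raise GraphError(f"graph has no candidate layers of kinds {config.candidate_kinds}")
    per_layer = {c: [] for c in candidates}
    for b in range(batch.shape[0]):
        acts, _ = engine.forward(graph, weights, batch[b : b + 1], keep=set(candidates))
        for c in candidates:
            per_layer[c].append(acts[c][0])
    entries = [(c, activation_sparsity(per_layer[c], config.zero_tolerance)) for c in candidates]
    fp = hashlib.sha1(np.ascontiguousarray(batch).tobytes()).hexdigest()[:16]
    return SparsityProfile(entries, fp)


def select_cut(profile: SparsityProfile) -> str:
    """Layer id with maximal sparsity; ties go to the earliest layer."""
    best_id, best_s = profile.entries[0]
    for lid, s in profile.entries[1:]:
        if s > best_s:
            best_id, best_s = lid, s
    return best_id


def _valid_cut(graph: ModelGraph, cut_id: str, kept: set) -> list:
    """Dropped add_merge nodes whose branches the cut splits.

    A cut is inside an unmerged residual branch exactly when some dropped
    merge has the cut among the ancestors of one predecessor branch but not
    of all of them: part of the merge's computation is kept while a sibling
    branch is discarded.
    """
    offenders = []
    for n in graph.nodes:
        if n.kind == "add_merge" and n.id not in kept:
            on_branch = [cut_id == p or cut_id in ancestors(graph, p) for p in n.predecessors]
            if any(on_branch) and not all(on_branch):
                offenders.append(n.id)
    return offenders


def valid_cut_points(graph: ModelGraph, kinds=("relu_activation",)) -> list:
    """All layers of the given kinds at which truncation is valid."""
    return [
        n.id
        for n in graph.nodes
        if n.kind in kinds and not _valid_cut(graph, n.id, ancestors(graph, n.id))
    ]


def candidate_cut_points(graph: ModelGraph) -> list:
    """Valid cut points restricted to proper separable-block boundaries.

    The stem activations (plain convolutions before the first separable
    block) are excluded — cutting there leaves no separable backbone — and
    so is the terminal backbone activation, where truncation is a no-op
    rather than a cut.
    """
    cuts = [c for c in valid_cut_points(graph) if "_sepconv" in c]
    deepest = None
    for n in graph.nodes:  # last ReLU ancestor of the output = the no-op cut
        if n.kind == "relu_activation" and n.id in ancestors(graph, graph.output_id):
            deepest = n.id
    return [c for c in cuts if c != deepest]


def select_profiled_cut(graph: ModelGraph, profile: SparsityProfile) -> str:
    """Max-sparsity layer among the architecturally valid cut candidates."""
    allowed = set(candidate_cut_points(graph))
    entries = [(lid, s) for lid, s in profile.entries if lid in allowed]
    if not entries:
        raise GraphError("profile contains no valid separable-block cut candidates")
    return select_cut(SparsityProfile(entries, profile.batch_fingerprint))


def truncate(graph: ModelGraph, cut_layer_id: str, weights: dict | None = None):
    """Induced subgraph on the cut layer's ancestors, with the cut as output.

    A cut strictly inside a residual branch — one whose add-merge is dropped
    while a kept node still feeds it — raises :class:`InvalidCutError`
    listing the nearest valid activation cut points up- and downstream.
    When ``weights`` is given, the kept nodes' weights are copied verbatim
    and returned alongside the graph.
    """
    graph.node(cut_layer_id)
    kept = ancestors(graph, cut_layer_id)
    offenders = _valid_cut(graph, cut_layer_id, kept)
    if offenders:
        valid = valid_cut_points(graph)
        order = [n.id for n in graph.nodes]
        pos = order.index(cut_layer_id)
        upstream = [v for v in valid if order.index(v) < pos]
        downstream = [v for v in valid if order.index(v) > pos]
        raise InvalidCutError(
            f"cut at {cut_layer_id!r} lies inside an unmerged residual branch "
            f"(merges {offenders} lose a branch); nearest valid cuts: "
            f"upstream {upstream[-1:] or None}, downstream {downstream[:1] or None}"
        )
    nodes = [n for n in graph.nodes if n.id in kept]
    pruned = ModelGraph(
        [LayerNode(n.id, n.kind, dict(n.hyperparams), n.predecessors) for n in nodes],
        cut_layer_id,
    )
    if weights is None:
        return pruned
    return pruned, {nid: {k: v.copy() for k, v in w.items()}
                    for nid, w in weights.items() if nid in kept}


def attach_classifier_head(graph: ModelGraph, n_classes: int) -> ModelGraph:
    """Append global_avg_pool + dense(n_classes) + softmax to a spatial output."""
    out = graph.node(graph.output_id)
    if out.kind in ("softmax", "dense", "global_avg_pool", "flatten"):
        raise GraphError(f"graph already ends in a head ({out.kind}); refusing to stack another")
    shapes = infer_shapes(graph)
    if len(shapes[graph.output_id]) != 3:
        raise GraphError(f"output {graph.output_id!r} is not spatial: shape {shapes[graph.output_id]}")
    nodes = [LayerNode(n.id, n.kind, dict(n.hyperparams), n.predecessors) for n in graph.nodes]
    nodes.append(LayerNode("avg_pool", "global_avg_pool", {}, (graph.output_id,)))
    nodes.append(LayerNode("predictions", "dense", {"units": n_classes, "use_bias": True}, ("avg_pool",)))
    nodes.append(LayerNode("softmax", "softmax", {}, ("predictions",)))
    return ModelGraph(nodes, "softmax")


def prune_and_retrain(graph: ModelGraph, weights: dict, dataset: LabeledImageSet,
                      sparsity_config: SparsityConfig, train_config):
    """Full pruning pass: profile → select → truncate → new head → retrain.

    Retraining starts from a fresh initialization ("from scratch"); the
    profiled weights only guide where to cut.  Returns
    ``(trained_weights, PruneResult, history)``.
    """
    from .training import train  # local import to avoid a cycle

    rng = np.random.default_rng(train_config.seed)
    idx = rng.choice(len(dataset), size=min(sparsity_config.batch_size, len(dataset)),
                     replace=False)
    batch = dataset.features[idx].astype(float) / 255.0
    profile = profile_model(graph, weights, batch, sparsity_config)
    cut = select_profiled_cut(graph, profile)
    backbone = truncate(graph, cut)
    pruned = attach_classifier_head(backbone, dataset.n_classes)
    result = PruneResult(cut, pruned, parameter_count(graph), parameter_count(pruned),
                         profile)
    fresh = engine.init_weights(pruned, seed=train_config.seed)
    trained, history = train(pruned, fresh, dataset, train_config)
    return trained, result, history
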