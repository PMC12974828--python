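"""Explicit layer-DAG representation of CNN classifiers.

A model is a :class:`ModelGraph`: typed :class:`LayerNode` records held in a
fixed topological order.  The graph is the object that sparsity-guided
truncation and pooling surgery operate on; the NumPy execution engine
(:mod:`dermprune.engine`) interprets it.

The Xception-style backbone built here uses post-activation ordering
(conv -> batch norm -> ReLU, and a ReLU after every residual add).  The
block-boundary ReLU of block *N* carries the conventional
``blockN_sepconvM_act`` name, so published cut points such as
``block12_sepconv3_act`` are addressable strings that sit on valid block
boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "LayerNode",
    "ModelGraph",
    "XceptionConfig",
    "GraphError",
    "InvalidConfigError",
    "build_xception",
    "parameter_count",
    "node_parameter_count",
    "ancestors",
    "infer_shapes",
]

LAYER_KINDS = frozenset(
    {
        "input",
        "conv2d",
        "separable_conv2d",
        "batch_norm",
        "relu_activation",
        "max_pool",
        "avg_topk_pool",
        "global_avg_pool",
        "add_merge",
        "dense",
        "softmax",
        "flatten",
        "dropout",
    }
)


class GraphError(ValueError):
    """Structural problem in a model graph."""


class InvalidConfigError(ValueError):
    """A backbone configuration that cannot be realized."""


@dataclass(frozen=True)
class LayerNode:
    """One typed layer in the DAG.

    ``hyperparams`` are kind-specific (kernel size, channels, stride,
    padding policy, pool window, K, units, rate).  ``predecessors`` is empty
    only for the unique input node.
    """

    id: str
    kind: str
    hyperparams: dict = field(default_factory=dict)
    predecessors: tuple = ()

    def __post_init__(self):
        if self.kind not in LAYER_KINDS:
            raise GraphError(f"unknown layer kind {self.kind!r} for node {self.id!r}")
        object.__setattr__(self, "predecessors", tuple(self.predecessors))
        if self.kind == "input":
            if self.predecessors:
                raise GraphError(f"input node {self.id!r} must have no predecessors")
        elif not self.predecessors:
            raise GraphError(f"non-input node {self.id!r} has no predecessors")
        for key in ("filters", "kernel", "units", "window", "K", "stride"):
            v = self.hyperparams.get(key)
            if v is not None and (not isinstance(v, int) or v <= 0):
                raise GraphError(f"node {self.id!r}: {key}={v!r} must be a positive integer")


@dataclass
class ModelGraph:
    """A DAG of layers in a deterministic topological order."""

    nodes: list
    output_id: str

    def __post_init__(self):
        self.validate()

    # -- queries ---------------------------------------------------------
    def node(self, node_id: str) -> LayerNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise GraphError(f"unknown node id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def successors(self, node_id: str) -> tuple:
        self.node(node_id)
        return tuple(n.id for n in self.nodes if node_id in n.predecessors)

    @property
    def input_id(self) -> str:
        return self._input_id

    def validate(self) -> None:
        self._index = {}
        for n in self.nodes:
            if n.id in self._index:
                raise GraphError(f"duplicate node id {n.id!r}")
            self._index[n.id] = n
        inputs = [n.id for n in self.nodes if n.kind == "input"]
        if len(inputs) != 1:
            raise GraphError(f"graph must have exactly one input node, found {inputs}")
        self._input_id = inputs[0]
        if self.output_id not in self._index:
            raise GraphError(f"output_id {self.output_id!r} not in graph")
        seen = set()
        for n in self.nodes:
            for p in n.predecessors:
                if p not in self._index:
                    raise GraphError(f"node {n.id!r} references unknown predecessor {p!r}")
                if p not in seen:
                    raise GraphError(
                        f"node order is not topological: {n.id!r} precedes its predecessor {p!r}"
                    )
            seen.add(n.id)
        for n in self.nodes:
            if n.kind == "add_merge" and len(n.predecessors) < 2:
                raise GraphError(f"add_merge node {n.id!r} needs >=2 predecessors")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {
                    "id": n.id,
                    "kind": n.kind,
                    "hyperparams": n.hyperparams,
                    "predecessors": list(n.predecessors),
                }
                for n in self.nodes
            ],
            "output_id": self.output_id,
        }
        return json.dumps(doc, indent=1, sort_keys=False)

    @classmethod
    def from_json(cls, text: str) -> "ModelGraph":
        doc = json.loads(text)
        nodes = [
            LayerNode(d["id"], d["kind"], dict(d["hyperparams"]), tuple(d["predecessors"]))
            for d in doc["nodes"]
        ]
        return cls(nodes, doc["output_id"])


def ancestors(graph: ModelGraph, node_id: str) -> set:
    """All nodes on any path from the input to ``node_id``, inclusive."""
    graph.node(node_id)
    result = set()
    stack = [node_id]
    while stack:
        nid = stack.pop()
        if nid in result:
            continue
        result.add(nid)
        stack.extend(graph.node(nid).predecessors)
    return result


# ---------------------------------------------------------------------------
# shape inference
# ---------------------------------------------------------------------------

def _pool_out(size: int, window: int, stride: int, padding: str) -> int:
    if padding == "same":
        return math.ceil(size / stride)
    if size < window:
        raise GraphError(f"spatial size {size} smaller than window {window} under valid padding")
    return (size - window) // stride + 1


def infer_shapes(graph: ModelGraph) -> dict:
    """Per-node output shapes (H, W, C) for spatial nodes, (F,) for flat ones.

    Raises :class:`GraphError` naming the offending node when a shape cannot
    be inferred.
    """
    shapes: dict = {}
    for n in graph.nodes:
        pre = [shapes[p] for p in n.predecessors]
        h = n.hyperparams
        try:
            if n.kind == "input":
                shapes[n.id] = tuple(h["shape"])
            elif n.kind in ("conv2d", "separable_conv2d"):
                H, W, _ = pre[0]
                k = h["kernel"]
                s = h.get("stride", 1)
                shapes[n.id] = (
                    _pool_out(H, k, s, h.get("padding", "same")),
                    _pool_out(W, k, s, h.get("padding", "same")),
                    h["filters"],
                )
            elif n.kind in ("batch_norm", "relu_activation", "softmax", "dropout"):
                shapes[n.id] = pre[0]
            elif n.kind in ("max_pool", "avg_topk_pool"):
                H, W, C = pre[0]
                w = h["window"]
                s = h.get("stride", w)
                pad = h.get("padding", "valid")
                shapes[n.id] = (_pool_out(H, w, s, pad), _pool_out(W, w, s, pad), C)
            elif n.kind == "global_avg_pool":
                shapes[n.id] = (pre[0][-1],)
            elif n.kind == "flatten":
                shapes[n.id] = (int(math.prod(pre[0])),)
            elif n.kind == "add_merge":
                if len(set(pre)) != 1:
                    raise GraphError(
                        f"add_merge {n.id!r} has mismatched input shapes {pre}"
                    )
                shapes[n.id] = pre[0]
            elif n.kind == "dense":
                if len(pre[0]) != 1:
                    raise GraphError(f"dense {n.id!r} needs a flat input, got {pre[0]}")
                shapes[n.id] = (h["units"],)
            else:  # pragma: no cover
                raise GraphError(f"no shape rule for kind {n.kind!r}")
        except (KeyError, IndexError, TypeError) as exc:
            raise GraphError(f"cannot infer shape of node {n.id!r}: {exc}") from exc
    return shapes


# ---------------------------------------------------------------------------
# parameter counting
# ---------------------------------------------------------------------------

def node_parameter_count(node: LayerNode, in_channels: int | None) -> int:
    """Closed-form trainable+stat parameter count of one node.

    conv: k^2*Cin*Cout (+Cout bias); separable: k^2*Cin + Cin*Cout (+Cout);
    batch_norm: 4*C (gamma, beta, running mean/var); dense: in*out (+out);
    everything else is parameterless.
    """
    h = node.hyperparams
    if node.kind == "conv2d":
        n = h["kernel"] ** 2 * in_channels * h["filters"]
        return n + (h["filters"] if h.get("use_bias", False) else 0)
    if node.kind == "separable_conv2d":
        n = h["kernel"] ** 2 * in_channels + in_channels * h["filters"]
        return n + (h["filters"] if h.get("use_bias", False) else 0)
    if node.kind == "batch_norm":
        return 4 * in_channels
    if node.kind == "dense":
        return in_channels * h["units"] + (h["units"] if h.get("use_bias", True) else 0)
    return 0


def parameter_count(graph: ModelGraph) -> int:
    """Total parameter count, summed over nodes from per-kind closed forms."""
    shapes = infer_shapes(graph)
    total = 0
    for n in graph.nodes:
        if n.predecessors:
            cin = shapes[n.predecessors[0]][-1]
        else:
            cin = None
        total += node_parameter_count(n, cin)
    return total


# ---------------------------------------------------------------------------
# Xception-style backbone builder
# ---------------------------------------------------------------------------

@dataclass
class XceptionConfig:
    """Backbone configuration.

    ``width_multiplier`` rescales every channel width; the micro preset
    (width 0.125, 2 middle blocks, 32 px input) exists so that full forward
    and backward passes stay cheap on a single CPU.
    """

    input_size: int = 128
    n_classes: int = 7
    width_multiplier: float = 1.0
    middle_blocks: int = 8

    def validate(self) -> None:
        if self.input_size < 32 or self.input_size % 4:
            raise InvalidConfigError("input_size must be >= 32 and divisible by 4")
        if self.n_classes < 2:
            raise InvalidConfigError("n_classes must be >= 2")
        if self.middle_blocks < 0:
            raise InvalidConfigError("middle_blocks must be >= 0")


MICRO = XceptionConfig(input_size=32, n_classes=7, width_multiplier=0.125, middle_blocks=2)
"""Micro preset: width 0.125, two middle-flow blocks, 32 px input."""


def _width(c: int, mult: float) -> int:
    w = int(round(c * mult))
    if w < 1:
        raise InvalidConfigError(
            f"width_multiplier {mult} collapses a {c}-channel stage to 0 channels"
        )
    return w


class _Builder:
    def __init__(self):
        self.nodes: list = []

    def add(self, id, kind, pre, **hyper):
        self.nodes.append(LayerNode(id, kind, hyper, tuple(pre) if isinstance(pre, (list, tuple)) else (pre,)))
        return id

    def conv_bn_act(self, name, pre, filters, kernel, stride=1, act=True):
        c = self.add(name, "conv2d", pre, filters=filters, kernel=kernel, stride=stride,
                     padding="same", use_bias=False)
        b = self.add(f"{name}_bn", "batch_norm", c)
        if act:
            return self.add(f"{name}_act", "relu_activation", b)
        return b

    def sepconv_bn(self, name, pre, filters, act):
        c = self.add(name, "separable_conv2d", pre, filters=filters, kernel=3, stride=1,
                     padding="same", use_bias=False)
        b = self.add(f"{name}_bn", "batch_norm", c)
        if act:
            return self.add(f"{name}_act", "relu_activation", b)
        return b


def build_xception(config: XceptionConfig) -> ModelGraph:
    """Build a separable-convolution backbone with entry/middle/exit flows.

    Entry flow: two plain convolutions then three downsampling residual
    blocks (128/256/728 channels before width scaling).  Middle flow:
    ``config.middle_blocks`` residual blocks of three 728-channel separable
    convolutions.  Exit flow: one downsampling residual block (728/1024)
    and two wide separable convolutions (1536/2048), then a
    global-average-pool + dense + softmax head.

    The ReLU that closes block *N* is named ``blockN_sepconvM_act`` (M = the
    block's last separable conv), making published cut-point names valid
    block-boundary layers.
    """
    config.validate()
    mult = config.width_multiplier
    g = _Builder()
    g.add("input", "input", (), shape=(config.input_size, config.input_size, 3))
    x = g.conv_bn_act("block1_conv1", "input", _width(32, mult), 3, stride=2)
    x = g.conv_bn_act("block1_conv2", x, _width(64, mult), 3)

    def residual_down_block(n, x, filters, n_seps):
        shortcut = g.add(f"block{n}_residual_conv", "conv2d", x, filters=filters, kernel=1,
                         stride=2, padding="same", use_bias=False)
        shortcut = g.add(f"block{n}_residual_bn", "batch_norm", shortcut)
        for m in range(1, n_seps + 1):
            last = m == n_seps
            x = g.sepconv_bn(f"block{n}_sepconv{m}", x, filters, act=not last)
        x = g.add(f"block{n}_pool", "max_pool", x, window=3, stride=2, padding="same")
        x = g.add(f"block{n}_add", "add_merge", (x, shortcut))
        return g.add(f"block{n}_sepconv{n_seps}_act", "relu_activation", x)

    x = residual_down_block(2, x, _width(128, mult), 2)
    x = residual_down_block(3, x, _width(256, mult), 2)
    x = residual_down_block(4, x, _width(728, mult), 2)

    w728 = _width(728, mult)
    for i in range(config.middle_blocks):
        n = 5 + i
        inp = x
        x = g.sepconv_bn(f"block{n}_sepconv1", x, w728, act=True)
        x = g.sepconv_bn(f"block{n}_sepconv2", x, w728, act=True)
        x = g.sepconv_bn(f"block{n}_sepconv3", x, w728, act=False)
        x = g.add(f"block{n}_add", "add_merge", (x, inp))
        x = g.add(f"block{n}_sepconv3_act", "relu_activation", x)

    n = 5 + config.middle_blocks  # exit-flow residual block (block 13 at full scale)
    inp = x
    shortcut = g.add(f"block{n}_residual_conv", "conv2d", inp, filters=_width(1024, mult),
                     kernel=1, stride=2, padding="same", use_bias=False)
    shortcut = g.add(f"block{n}_residual_bn", "batch_norm", shortcut)
    x = g.sepconv_bn(f"block{n}_sepconv1", x, w728, act=True)
    x = g.sepconv_bn(f"block{n}_sepconv2", x, _width(1024, mult), act=False)
    x = g.add(f"block{n}_pool", "max_pool", x, window=3, stride=2, padding="same")
    x = g.add(f"block{n}_add", "add_merge", (x, shortcut))
    x = g.add(f"block{n}_sepconv2_act", "relu_activation", x)

    n += 1  # block 14 at full scale
    x = g.sepconv_bn(f"block{n}_sepconv1", x, _width(1536, mult), act=True)
    x = g.sepconv_bn(f"block{n}_sepconv2", x, _width(2048, mult), act=True)

    x = g.add("avg_pool", "global_avg_pool", x)
    x = g.add("predictions", "dense", x, units=config.n_classes, use_bias=True)
    x = g.add("softmax", "softmax", x)
    graph = ModelGraph(g.nodes, x)
    infer_shapes(graph)  # fail fast on inconsistent configs
    return graph


def renumber_full_scale_names(middle_blocks: int) -> dict:
    """Map full-scale cut names (8 middle blocks) to a narrower preset.

    ``block12_sepconv3_act`` is the last middle block at full scale; with
    ``middle_blocks`` blocks the analogue is ``block{4+middle_blocks}_sepconv3_act``.
    """
    mapping = {}
    for i in range(8):
        mapping[f"block{5 + i}_sepconv3_act"] = (
            f"block{5 + min(i, middle_blocks - 1)}_sepconv3_act" if middle_blocks else None
        )
    mapping["block13_sepconv2_act"] = f"block{5 + middle_blocks}_sepconv2_act"
    mapping["block14_sepconv1_act"] = f"block{6 + middle_blocks}_sepconv1_act"
    return mapping
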