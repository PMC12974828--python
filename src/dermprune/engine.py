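"""Compact NumPy execution engine for :class:`~dermprune.graph.ModelGraph`.

Implements forward and backward passes for every layer kind in the graph
schema (standard and depthwise-separable convolution, batch normalization,
ReLU, max / Avg-TopK / global-average pooling, dense, residual add,
softmax) plus He-normal initialization and an Adam optimizer.  Everything
is vectorized with ``sliding_window_view`` + ``einsum``; it is built for
desk-scale models (the micro backbone preset), not for GPU throughput.

Weights are a plain ``{node_id: {param_name: ndarray}}`` dict so that graph
surgery (truncation, pooling replacement) can copy or drop per-node entries
directly.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .graph import ModelGraph, infer_shapes
from .pooling import PoolingSpec, _backward as _pool_bwd, _forward as _pool_fwd

__all__ = ["init_weights", "forward", "forward_backward", "AdamState", "adam_step", "copy_weights"]

BN_EPS = 1e-3
BN_MOMENTUM = 0.99

_TRAINABLE = {
    "conv2d": ("W", "b"),
    "separable_conv2d": ("Wd", "Wp", "b"),
    "batch_norm": ("gamma", "beta"),
    "dense": ("W", "b"),
}


def init_weights(graph: ModelGraph, seed: int) -> dict:
    """He-normal initialization for every parameterized node."""
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(graph)
    weights: dict = {}
    for n in graph.nodes:
        h = n.hyperparams
        cin = shapes[n.predecessors[0]][-1] if n.predecessors else None
        if n.kind == "conv2d":
            k, cout = h["kernel"], h["filters"]
            std = np.sqrt(2.0 / (k * k * cin))
            w = {"W": rng.normal(0.0, std, (k, k, cin, cout))}
            if h.get("use_bias", False):
                w["b"] = np.zeros(cout)
            weights[n.id] = w
        elif n.kind == "separable_conv2d":
            k, cout = h["kernel"], h["filters"]
            w = {
                "Wd": rng.normal(0.0, np.sqrt(2.0 / (k * k)), (k, k, cin)),
                "Wp": rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)),
            }
            if h.get("use_bias", False):
                w["b"] = np.zeros(cout)
            weights[n.id] = w
        elif n.kind == "batch_norm":
            weights[n.id] = {
                "gamma": np.ones(cin),
                "beta": np.zeros(cin),
                "running_mean": np.zeros(cin),
                "running_var": np.ones(cin),
            }
        elif n.kind == "dense":
            fan_in = cin
            w = {"W": rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, h["units"]))}
            if h.get("use_bias", True):
                w["b"] = np.zeros(h["units"])
            weights[n.id] = w
    return weights


def copy_weights(weights: dict) -> dict:
    return {nid: {k: v.copy() for k, v in w.items()} for nid, w in weights.items()}


# ---------------------------------------------------------------------------
# padding / conv primitives
# ---------------------------------------------------------------------------

def _pad_same(x, k, s):
    def amounts(size):
        out = -(-size // s)
        total = max((out - 1) * s + k - size, 0)
        return total // 2, total - total // 2

    (pt, pb), (pl, pr) = amounts(x.shape[1]), amounts(x.shape[2])
    return np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))), (pt, pl)


def _conv_windows(xp, k, s):
    return sliding_window_view(xp, (k, k), axis=(1, 2))[:, ::s, ::s]


def _unpad_grad(dxp, offs, shape):
    pt, pl = offs
    return dxp[:, pt : pt + shape[1], pl : pl + shape[2], :]


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------

def _node_forward(node, x_in, w, training, rng, update_bn):
    """Returns (output, cache)."""
    h = node.hyperparams
    kind = node.kind
    if kind == "input":
        return x_in[0], None
    x = x_in[0]
    if kind == "conv2d":
        k, s = h["kernel"], h.get("stride", 1)
        xp, offs = _pad_same(x, k, s) if h.get("padding", "same") == "same" else (x, (0, 0))
        win = _conv_windows(xp, k, s)
        y = np.einsum("bijckl,klco->bijo", win, w["W"], optimize=True)
        if "b" in w:
            y = y + w["b"]
        return y, {"xp": xp, "offs": offs, "x_shape": x.shape}
    if kind == "separable_conv2d":
        k, s = h["kernel"], h.get("stride", 1)
        xp, offs = _pad_same(x, k, s) if h.get("padding", "same") == "same" else (x, (0, 0))
        win = _conv_windows(xp, k, s)
        y_dw = np.einsum("bijckl,klc->bijc", win, w["Wd"], optimize=True)
        y = np.tensordot(y_dw, w["Wp"], axes=([3], [0]))
        if "b" in w:
            y = y + w["b"]
        return y, {"xp": xp, "offs": offs, "x_shape": x.shape, "y_dw": y_dw}
    if kind == "batch_norm":
        axes = tuple(range(x.ndim - 1))
        if training:
            m = x.mean(axis=axes)
            v = x.var(axis=axes)
            if update_bn:
                w["running_mean"] *= BN_MOMENTUM
                w["running_mean"] += (1 - BN_MOMENTUM) * m
                w["running_var"] *= BN_MOMENTUM
                w["running_var"] += (1 - BN_MOMENTUM) * v
        else:
            m, v = w["running_mean"], w["running_var"]
        inv = 1.0 / np.sqrt(v + BN_EPS)
        xhat = (x - m) * inv
        return w["gamma"] * xhat + w["beta"], {"xhat": xhat, "inv": inv, "axes": axes}
    if kind == "relu_activation":
        return np.maximum(x, 0.0), {"mask": x > 0}
    if kind == "max_pool":
        spec = PoolingSpec(h["window"], h.get("stride", h["window"]), 1, h.get("padding", "valid"))
        return _pool_fwd(x, spec)
    if kind == "avg_topk_pool":
        spec = PoolingSpec(h["window"], h.get("stride", h["window"]), h["K"], h.get("padding", "valid"))
        return _pool_fwd(x, spec)
    if kind == "global_avg_pool":
        return x.mean(axis=(1, 2)), {"hw": x.shape[1] * x.shape[2], "x_shape": x.shape}
    if kind == "flatten":
        return x.reshape(x.shape[0], -1), {"x_shape": x.shape}
    if kind == "add_merge":
        return sum(x_in), {"n": len(x_in)}
    if kind == "dense":
        y = x @ w["W"]
        if "b" in w:
            y = y + w["b"]
        return y, {"x": x}
    if kind == "dropout":
        rate = h.get("rate", 0.5)
        if training and rate > 0:
            if rng is None:
                raise ValueError("dropout in training mode needs an rng")
            mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
            return x * mask, {"mask": mask}
        return x, {"mask": None}
    if kind == "softmax":
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True), None
    raise ValueError(f"no forward rule for kind {kind!r}")  # pragma: no cover


def forward(graph: ModelGraph, weights: dict, x: np.ndarray, *, training: bool = False,
            rng=None, update_bn: bool = False, keep: set | None = None):
    """Run the graph on a batch ``x`` [B,H,W,C].

    Returns ``(activations, caches)``; ``activations`` maps node id to output.
    With ``keep`` given, only those activations are retained (plus the output)
    and caches are discarded — cheaper for inference/profiling.
    """
    x = np.asarray(x, dtype=float)
    acts: dict = {}
    caches: dict = {} if keep is None else None
    if keep is not None:
        keep = set(keep) | {graph.output_id}
    for node in graph.nodes:
        xs = [acts[p] for p in node.predecessors] if node.predecessors else [x]
        y, cache = _node_forward(node, xs, weights.get(node.id), training, rng, update_bn)
        acts[node.id] = y
        if caches is not None:
            caches[node.id] = cache
    if keep is not None:
        acts = {k: v for k, v in acts.items() if k in keep}
    return acts, caches


def _node_backward(node, dy, w, cache, acts):
    """Returns (list of dx per predecessor, param grads dict or None)."""
    h = node.hyperparams
    kind = node.kind
    if kind == "conv2d":
        k, s = h["kernel"], h.get("stride", 1)
        win = _conv_windows(cache["xp"], k, s)
        dW = np.einsum("bijckl,bijo->klco", win, dy, optimize=True)
        grads = {"W": dW}
        if "b" in w:
            grads["b"] = dy.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(cache["xp"])
        Ho, Wo = dy.shape[1:3]
        for a in range(k):
            for b in range(k):
                dxp[:, a : a + Ho * s : s, b : b + Wo * s : s, :] += np.einsum(
                    "bijo,co->bijc", dy, w["W"][a, b], optimize=True
                )
        return [_unpad_grad(dxp, cache["offs"], cache["x_shape"])], grads
    if kind == "separable_conv2d":
        k, s = h["kernel"], h.get("stride", 1)
        y_dw = cache["y_dw"]
        grads = {"Wp": np.einsum("bijc,bijo->co", y_dw, dy, optimize=True)}
        if "b" in w:
            grads["b"] = dy.sum(axis=(0, 1, 2))
        d_dw = np.tensordot(dy, w["Wp"], axes=([3], [1]))
        win = _conv_windows(cache["xp"], k, s)
        grads["Wd"] = np.einsum("bijckl,bijc->klc", win, d_dw, optimize=True)
        dxp = np.zeros_like(cache["xp"])
        Ho, Wo = dy.shape[1:3]
        for a in range(k):
            for b in range(k):
                dxp[:, a : a + Ho * s : s, b : b + Wo * s : s, :] += d_dw * w["Wd"][a, b]
        return [_unpad_grad(dxp, cache["offs"], cache["x_shape"])], grads
    if kind == "batch_norm":
        xhat, inv, axes = cache["xhat"], cache["inv"], cache["axes"]
        N = np.prod([xhat.shape[a] for a in axes])
        dgamma = (dy * xhat).sum(axis=axes)
        dbeta = dy.sum(axis=axes)
        dxhat = dy * w["gamma"]
        dx = (inv / N) * (N * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        return [dx], {"gamma": dgamma, "beta": dbeta}
    if kind == "relu_activation":
        return [dy * cache["mask"]], None
    if kind in ("max_pool", "avg_topk_pool"):
        return [_pool_bwd(dy, cache)], None
    if kind == "global_avg_pool":
        B, H, W, C = cache["x_shape"]
        return [np.broadcast_to(dy[:, None, None, :] / cache["hw"], (B, H, W, C)).copy()], None
    if kind == "flatten":
        return [dy.reshape(cache["x_shape"])], None
    if kind == "add_merge":
        return [dy] * cache["n"], None
    if kind == "dense":
        grads = {"W": cache["x"].T @ dy}
        if "b" in w:
            grads["b"] = dy.sum(axis=0)
        return [dy @ w["W"].T], grads
    if kind == "dropout":
        mask = cache["mask"]
        return [dy if mask is None else dy * mask], None
    raise ValueError(f"no backward rule for kind {kind!r}")  # pragma: no cover


def forward_backward(graph: ModelGraph, weights: dict, x: np.ndarray, labels: np.ndarray,
                     *, rng=None, update_bn: bool = True):
    """One training step's loss and gradients.

    The graph must end in a softmax node; the loss is sparse categorical
    cross-entropy on integer ``labels``.  Softmax and cross-entropy are
    differentiated jointly ((p - onehot)/B at the softmax input) for
    numerical stability.
    """
    out_node = graph.node(graph.output_id)
    if out_node.kind != "softmax":
        raise ValueError("forward_backward expects a softmax output node")
    acts, caches = forward(graph, weights, x, training=True, rng=rng, update_bn=update_bn)
    probs = acts[graph.output_id]
    B = probs.shape[0]
    labels = np.asarray(labels)
    loss = float(-np.mean(np.log(probs[np.arange(B), labels] + 1e-12)))
    onehot = np.zeros_like(probs)
    onehot[np.arange(B), labels] = 1.0
    dy_map: dict = {out_node.predecessors[0]: (probs - onehot) / B}
    grads: dict = {}
    for node in reversed(graph.nodes):
        if node.id not in dy_map or node.kind in ("input", "softmax"):
            continue
        dy = dy_map.pop(node.id)
        dxs, g = _node_backward(node, dy, weights.get(node.id), caches[node.id], acts)
        if g:
            grads[node.id] = g
        for p, dx in zip(node.predecessors, dxs):
            if p in dy_map:
                dy_map[p] = dy_map[p] + dx
            else:
                dy_map[p] = dx
    return loss, probs, grads


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class AdamState:
    """First/second-moment accumulators for every trainable parameter."""

    def __init__(self, weights: dict, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for nid, w in weights.items():
            for name, arr in w.items():
                if name in ("running_mean", "running_var"):
                    continue
                self.m[(nid, name)] = np.zeros_like(arr)
                self.v[(nid, name)] = np.zeros_like(arr)


def adam_step(weights: dict, grads: dict, state: AdamState, lr: float) -> None:
    """In-place Adam update on every parameter present in ``grads``."""
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    corr1 = 1 - b1 ** state.t
    corr2 = 1 - b2 ** state.t
    for nid, g in grads.items():
        for name, grad in g.items():
            key = (nid, name)
            m = state.m[key]
            v = state.v[key]
            m *= b1
            m += (1 - b1) * grad
            v *= b2
            v += (1 - b2) * grad * grad
            weights[nid][name] -= lr * (m / corr1) / (np.sqrt(v / corr2) + state.eps)
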