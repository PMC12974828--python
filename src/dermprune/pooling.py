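"""Avg-TopK pooling: forward, backward and graph surgery.

The operator returns, for each pooling window, the mean of the K largest
values.  It interpolates between max pooling (K=1) and average pooling
(K = window size): on the worked 3x3 window [[1,5,2],[3,8,6],[4,7,0]] with
K=3 the output is (8+7+6)/3 = 7, versus 8 for max pooling and 4 for full
averaging.

Ties at the K-th largest value are broken by row-major scan order, which
makes both the forward selection and the backward routing deterministic.
Under "same" padding, padded positions are excluded from the ranking and K
is clamped to the number of real elements in the window.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["PoolingSpec", "topk_mean", "avg_topk_pool2d", "avg_topk_backward", "replace_max_pooling"]


@dataclass
class PoolingSpec:
    """Window geometry and K for one pooling layer."""

    window: int = 2
    stride: int = 2
    K: int = 3
    padding: str = "valid"
    tie_policy: str = "row_major"

    def validate(self) -> None:
        if self.window < 1 or self.stride < 1 or self.K < 1:
            raise ValueError("window, stride and K must all be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {self.padding!r}")
        if self.tie_policy != "row_major":
            raise ValueError(f"unknown tie policy {self.tie_policy!r}")


def topk_mean(values, K: int) -> float:
    """Mean of the K largest values (K clamped to the element count)."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("topk_mean requires at least one value")
    if K < 1:
        raise ValueError("K must be >= 1")
    k = min(K, v.size)
    top = np.sort(v)[::-1][:k]
    return float(top.mean())


def _pad_amounts(size: int, window: int, stride: int) -> tuple:
    out = -(-size // stride)  # ceil
    total = max((out - 1) * stride + window - size, 0)
    return total // 2, total - total // 2


def _windows(x: np.ndarray, spec: PoolingSpec):
    """Return (windows [B,Ho,Wo,C,w*w], padded shape); padded cells are -inf."""
    B, H, W, C = x.shape
    w, s = spec.window, spec.stride
    if spec.padding == "same":
        (pt, pb), (pl, pr) = _pad_amounts(H, w, s), _pad_amounts(W, w, s)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)), constant_values=-np.inf)
    else:
        if H < w or W < w:
            raise ValueError(f"window {w} larger than input {H}x{W} under valid padding")
        xp = x
        pt = pl = 0
    win = sliding_window_view(xp, (w, w), axis=(1, 2))[:, ::s, ::s]
    B, Ho, Wo, C = win.shape[:4]
    return win.reshape(B, Ho, Wo, C, w * w), xp.shape, (pt, pl)


def _forward(x: np.ndarray, spec: PoolingSpec):
    """Batched forward on [B,H,W,C]; returns (y, cache) with selection cached."""
    spec.validate()
    win, padded_shape, offs = _windows(x, spec)
    order = np.argsort(-win, axis=-1, kind="stable")  # descending, row-major ties
    svals = np.take_along_axis(win, order, axis=-1)
    n_valid = np.isfinite(svals).sum(axis=-1)
    if np.any(n_valid == 0):  # pragma: no cover - same padding always keeps >=1 cell
        raise ValueError("pooling window with no valid elements")
    k_eff = np.minimum(spec.K, n_valid)
    csum = np.cumsum(np.where(np.isfinite(svals), svals, 0.0), axis=-1)
    y = np.take_along_axis(csum, (k_eff - 1)[..., None], axis=-1)[..., 0] / k_eff
    cache = {"order": order, "k_eff": k_eff, "x_shape": x.shape,
             "padded_shape": padded_shape, "offsets": offs, "spec": spec}
    return y, cache


def _backward(dy: np.ndarray, cache: dict) -> np.ndarray:
    """Route upstream/K to each selected position; overlaps accumulate."""
    spec: PoolingSpec = cache["spec"]
    order, k_eff = cache["order"], cache["k_eff"]
    if dy.shape != k_eff.shape:
        raise ValueError(f"upstream gradient shape {dy.shape} != pooled shape {k_eff.shape}")
    w, s = spec.window, spec.stride
    ranks = np.arange(w * w)
    g_sorted = np.where(ranks < k_eff[..., None], (dy / k_eff)[..., None], 0.0)
    g_win = np.zeros_like(g_sorted)
    np.put_along_axis(g_win, order, g_sorted, axis=-1)
    B, Ho, Wo, C = dy.shape
    g_win = g_win.reshape(B, Ho, Wo, C, w, w)
    dxp = np.zeros(cache["padded_shape"], dtype=float)
    for a in range(w):
        for b in range(w):
            dxp[:, a : a + Ho * s : s, b : b + Wo * s : s, :] += g_win[..., a, b]
    pt, pl = cache["offsets"]
    H, W = cache["x_shape"][1:3]
    return dxp[:, pt : pt + H, pl : pl + W, :]


def avg_topk_pool2d(feature_map, spec: PoolingSpec):
    """Pool a single H×W(-, C) feature map; returns (pooled, cache).

    2-D inputs are treated as single-channel and returned 2-D.
    """
    x = np.asarray(feature_map, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[..., None]
    if x.ndim != 3:
        raise ValueError(f"expected H×W or H×W×C input, got shape {x.shape}")
    y, cache = _forward(x[None], spec)
    cache["squeeze"] = squeeze
    return (y[0, ..., 0] if squeeze else y[0]), cache


def avg_topk_backward(upstream_gradient, cache: dict) -> np.ndarray:
    """Input gradient for :func:`avg_topk_pool2d` given its cached selection."""
    dy = np.asarray(upstream_gradient, dtype=float)
    if cache.get("squeeze"):
        dy = dy[..., None]
    dx = _backward(dy[None], cache)[0]
    return dx[..., 0] if cache.get("squeeze") else dx


def replace_max_pooling(graph, K: int = 3):
    """Return a new graph with every max_pool node swapped for avg_topk_pool.

    Window, stride and padding are preserved; only the node kind changes and
    a ``K`` hyperparameter is added.  A graph without max-pool nodes is
    returned unchanged (as a copy).
    """
    from .graph import LayerNode, ModelGraph

    if K < 1:
        raise ValueError("K must be >= 1")
    new_nodes = []
    n_replaced = 0
    for n in graph.nodes:
        if n.kind == "max_pool":
            hyper = dict(n.hyperparams)
            hyper["K"] = K
            new_nodes.append(LayerNode(n.id, "avg_topk_pool", hyper, n.predecessors))
            n_replaced += 1
        else:
            new_nodes.append(LayerNode(n.id, n.kind, copy.deepcopy(n.hyperparams), n.predecessors))
    if n_replaced == 0:
        import logging

        logging.getLogger(__name__).info("replace_max_pooling: no max_pool nodes found")
    return ModelGraph(new_nodes, graph.output_id)
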