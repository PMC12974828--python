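"""SMOTE oversampling with the four target-count strategies.

Synthetic samples are convex combinations x_new = x_i + λ·(x_nn − x_i) of a
class member and one of its k nearest same-class neighbours (λ ~ U(0,1)),
applied elementwise — per pixel per channel in pixel space, per coordinate
in deep-feature space.

Strategy semantics for the per-class target counts:

* ``minority`` — only the single smallest class is raised to the largest
  class's count;
* ``not_minority`` — every class except the single smallest is raised to
  the largest count;
* ``not_majority`` — every class except the single largest is raised to the
  largest count;
* ``multiplier(k)`` — every non-largest class is set to
  min(k × its count, largest count); the largest class is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import LabeledImageSet

__all__ = [
    "ImbalanceStrategy",
    "SmoteConfig",
    "AmbiguousExtremeError",
    "target_counts",
    "smote_interpolate",
    "nearest_neighbors",
    "resample",
]

log = logging.getLogger(__name__)


class AmbiguousExtremeError(ValueError):
    """Tied smallest class makes the strategy ambiguous without a tie-break."""


@dataclass(frozen=True)
class ImbalanceStrategy:
    """One of {minority, not_minority, not_majority, multiplier}; ``k`` is
    the multiplication factor in multiplier mode."""

    mode: str
    k: int = 1

    _MODES = ("minority", "not_minority", "not_majority", "multiplier")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"unknown strategy mode {self.mode!r}")
        if self.mode == "multiplier" and self.k < 1:
            raise ValueError("multiplier strategy needs k >= 1")

    @classmethod
    def parse(cls, text: str) -> "ImbalanceStrategy":
        t = text.strip().lower().replace("-", "_")
        if t.endswith("x") and t[:-1].isdigit():
            return cls("multiplier", int(t[:-1]))
        return cls(t)


@dataclass
class SmoteConfig:
    """k-nearest-neighbour count, RNG seed, and interpolation space."""

    k_neighbors: int = 5
    seed: int = 0
    space: str = "pixel"

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.space not in ("pixel", "feature"):
            raise ValueError(f"unknown SMOTE space {self.space!r}")


def target_counts(counts, strategy: ImbalanceStrategy, tie_break: int | None = None):
    """Per-class target counts under ``strategy``.

    A tie for the single smallest class (minority / not_minority modes)
    changes the result, so it raises :class:`AmbiguousExtremeError` unless a
    ``tie_break`` class index is supplied.  Ties for the largest class never
    change the outcome and are resolved silently.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.ndim != 1 or counts.size < 2:
        raise ValueError("need a 1-D vector of at least two class counts")
    if np.any(counts < 0):
        raise ValueError("class counts must be non-negative")
    maxc = int(counts.max())
    out = counts.copy()
    if strategy.mode in ("minority", "not_minority"):
        smallest = np.flatnonzero(counts == counts.min())
        if len(smallest) > 1:
            if tie_break is None or tie_break not in smallest:
                raise AmbiguousExtremeError(
                    f"classes {smallest.tolist()} tie for smallest; supply tie_break"
                )
            smallest = np.array([tie_break])
        if strategy.mode == "minority":
            out[smallest[0]] = maxc
        else:
            out[:] = maxc
            out[smallest[0]] = counts[smallest[0]]
    elif strategy.mode == "not_majority":
        out[:] = maxc
    else:  # multiplier
        largest = int(np.flatnonzero(counts == maxc)[0])
        for i in range(counts.size):
            if i != largest:
                out[i] = min(strategy.k * counts[i], maxc)
    return out


def smote_interpolate(x_i, x_nn, lam: float):
    """Elementwise convex combination x_i + λ(x_nn − x_i); promotes to float."""
    x_i = np.asarray(x_i, dtype=float)
    x_nn = np.asarray(x_nn, dtype=float)
    if x_i.shape != x_nn.shape:
        raise ValueError(f"shape mismatch {x_i.shape} vs {x_nn.shape}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return x_i + lam * (x_nn - x_i)


def nearest_neighbors(class_samples, k: int):
    """Indices of each sample's k nearest same-class neighbours.

    Euclidean distance on flattened features; self excluded; distance ties
    broken by ascending index; k clamped (with a logged warning) to
    class size − 1.
    """
    x = np.asarray(class_samples, dtype=float).reshape(len(class_samples), -1)
    n = len(x)
    if n < 2:
        raise ValueError("nearest_neighbors needs at least two samples")
    if k >= n:
        log.warning("k_neighbors=%d >= class size %d; clamping to %d", k, n, n - 1)
        k = n - 1
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")  # stable: ties -> ascending index
    return [order[i, :k].tolist() for i in range(n)]


def resample(dataset: LabeledImageSet, strategy: ImbalanceStrategy,
             config: SmoteConfig) -> LabeledImageSet:
    """Grow classes to their strategy target counts with SMOTE samples.

    Base samples cycle round-robin through a seeded shuffle of the class;
    the neighbour is drawn uniformly from the base's k nearest; λ ~ U(0,1).
    Originals pass through bit-for-bit; synthetic items carry
    provenance ``"synthetic"``.  Intended for training splits only.
    """
    counts = dataset.class_counts()
    targets = target_counts(counts, strategy)
    rng = np.random.default_rng(config.seed)
    new_feats, new_labels = [], []
    for cls in range(dataset.n_classes):
        deficit = int(targets[cls] - counts[cls])
        if deficit <= 0:
            continue
        members = np.flatnonzero(dataset.labels == cls)
        if len(members) < 2:
            raise ValueError(
                f"class {dataset.class_names[cls]!r} has {len(members)} sample(s); "
                "SMOTE needs at least two to interpolate"
            )
        feats = dataset.features[members].astype(float)
        nns = nearest_neighbors(feats, config.k_neighbors)
        base_order = rng.permutation(len(members))
        for j in range(deficit):
            i = int(base_order[j % len(members)])
            nn = int(nns[i][rng.integers(len(nns[i]))])
            lam = float(rng.uniform())
            new_feats.append(smote_interpolate(feats[i], feats[nn], lam))
            new_labels.append(cls)
    if not new_feats:
        return dataset.subset(np.arange(len(dataset)))
    synth = LabeledImageSet(
        np.stack(new_feats), np.array(new_labels), list(dataset.class_names),
        np.array(["synthetic"] * len(new_labels), dtype=object),
    )
    return dataset.concat(synth)
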