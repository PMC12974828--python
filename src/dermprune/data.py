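"""Labeled image/feature container shared by all pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabeledImageSet", "PROVENANCES"]

PROVENANCES = ("original", "synthetic", "augmented")


@dataclass
class LabeledImageSet:
    """Images (or flat feature vectors) with integer class labels.

    ``features`` is a single stacked array [N, H, W, 3] (pixel space, stored
    in the 0–255 domain) or [N, D] (deep-feature space).  ``provenance``
    tracks whether each item is an original, a SMOTE-synthesized sample, or
    an augmented copy.
    """

    features: np.ndarray
    labels: np.ndarray
    class_names: list
    provenance: np.ndarray = field(default=None)

    def __post_init__(self):
        self.features = np.asarray(self.features)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.provenance is None:
            self.provenance = np.array(["original"] * len(self.labels), dtype=object)
        else:
            self.provenance = np.asarray(self.provenance, dtype=object)
        if len(self.features) != len(self.labels) or len(self.labels) != len(self.provenance):
            raise ValueError("features, labels and provenance must have equal length")
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range of class_names")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_classes)

    def subset(self, idx) -> "LabeledImageSet":
        idx = np.asarray(idx)
        return LabeledImageSet(self.features[idx], self.labels[idx], list(self.class_names),
                               self.provenance[idx])

    def concat(self, other: "LabeledImageSet") -> "LabeledImageSet":
        if list(other.class_names) != list(self.class_names):
            raise ValueError("cannot concatenate sets with different class tables")
        if len(other) == 0:
            return self.subset(np.arange(len(self)))
        return LabeledImageSet(
            np.concatenate([self.features, other.features.astype(self.features.dtype, copy=False)])
            if self.features.dtype == other.features.dtype
            else np.concatenate([self.features.astype(float), other.features.astype(float)]),
            np.concatenate([self.labels, other.labels]),
            list(self.class_names),
            np.concatenate([self.provenance, other.provenance]),
        )
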