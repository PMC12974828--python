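"""Stochastic geometric augmentation and augmentation-based class balancing.

The recipe: rescale pixel values by 1/255, then a random rotation of up to
±10°, width/height shifts of up to ±20%, shear up to ±0.2, independent
horizontal and vertical flips, with out-of-frame pixels filled by
nearest-neighbour (edge) replication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp

from .data import LabeledImageSet

__all__ = ["AugmentConfig", "sample_augmentation", "balance_with_augmentation"]


@dataclass
class AugmentConfig:
    """Augmentation ranges; defaults follow the dermoscopy training recipe."""

    rescale: float = 1.0 / 255.0
    rotation_max_deg: float = 10.0
    width_shift_frac: float = 0.2
    height_shift_frac: float = 0.2
    shear_range: float = 0.2
    horizontal_flip: bool = True
    vertical_flip: bool = True
    fill_mode: str = "nearest"

    def __post_init__(self):
        if not (0 <= self.width_shift_frac <= 1 and 0 <= self.height_shift_frac <= 1):
            raise ValueError("shift fractions must lie in [0, 1]")
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")


def sample_augmentation(image, config: AugmentConfig, rng) -> np.ndarray:
    """One random augmentation draw; output in [0, 1].

    A draw in which every geometric parameter is zero and no flip fires
    returns exactly ``image * rescale``.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an H×W×3 image, got shape {img.shape}")
    img = img * config.rescale
    H, W = img.shape[:2]
    angle = np.deg2rad(rng.uniform(-config.rotation_max_deg, config.rotation_max_deg))
    tx = rng.uniform(-config.width_shift_frac, config.width_shift_frac) * W
    ty = rng.uniform(-config.height_shift_frac, config.height_shift_frac) * H
    shear = rng.uniform(-config.shear_range, config.shear_range)
    hflip = config.horizontal_flip and rng.random() < 0.5
    vflip = config.vertical_flip and rng.random() < 0.5
    if angle or tx or ty or shear:
        center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        tform = (
            AffineTransform(translation=-center)
            + AffineTransform(rotation=angle, shear=shear)
            + AffineTransform(translation=center + (tx, ty))
        )
        img = warp(img, tform.inverse, mode="edge", order=1)
    if hflip:
        img = img[:, ::-1]
    if vflip:
        img = img[::-1]
    return np.clip(img, 0.0, 1.0)


def balance_with_augmentation(train_set: LabeledImageSet, target_counts,
                              config: AugmentConfig | None = None,
                              seed: int = 0) -> LabeledImageSet:
    """Fill each class's deficit with augmented copies of its own members.

    Parents are drawn with a seeded RNG; new items carry provenance
    ``"augmented"`` and are stored back in the 0–255 pixel domain so the
    set stays homogeneous.
    """
    config = config or AugmentConfig()
    targets = np.asarray(target_counts, dtype=int)
    counts = train_set.class_counts()
    if np.any(targets < counts):
        raise ValueError("targets must be >= current class counts")
    rng = np.random.default_rng(seed)
    new_feats, new_labels = [], []
    for cls in range(train_set.n_classes):
        deficit = int(targets[cls] - counts[cls])
        if deficit == 0:
            continue
        members = np.flatnonzero(train_set.labels == cls)
        if len(members) == 0:
            raise ValueError(
                f"class {train_set.class_names[cls]!r} is empty but has target {targets[cls]}"
            )
        parents = rng.choice(members, size=deficit, replace=True)
        for p in parents:
            aug = sample_augmentation(train_set.features[p], config, rng)
            new_feats.append(aug / config.rescale)  # back to the 0-255 domain
            new_labels.append(cls)
    if not new_feats:
        return train_set.subset(np.arange(len(train_set)))
    extra = LabeledImageSet(np.stack(new_feats), np.array(new_labels),
                            list(train_set.class_names),
                            np.array(["augmented"] * len(new_labels), dtype=object))
    return train_set.concat(extra)
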