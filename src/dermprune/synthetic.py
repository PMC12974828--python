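"""Seeded synthetic dermoscopy-like image generator.

Each image is a skin-toned background carrying one elliptical "lesion"
whose colour, eccentricity, border roughness and internal texture frequency
are drawn from class-conditional parameter distributions, plus pixel noise.
Class parameter separation scales with ``difficulty`` (larger = easier).
The generator's contract is statistical structure — separable classes with
controllable imbalance — not dermatological realism; it exists so the full
pipeline runs with no external image archive.

The default class table mirrors the seven-class dermoscopy distribution
(nv/mel/bkl/bcc/akiec/vasc/df with counts 6705/1113/1099/514/327/142/115,
10,015 images in total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import LabeledImageSet

__all__ = ["SyntheticSpec", "HAM_CLASS_NAMES", "HAM_CLASS_COUNTS", "generate_dataset", "manifest"]

HAM_CLASS_NAMES = ("nv", "mel", "bkl", "bcc", "akiec", "vasc", "df")
HAM_CLASS_COUNTS = (6705, 1113, 1099, 514, 327, 142, 115)

# per-class appearance means: (RGB offset from skin tone, eccentricity,
# border roughness amplitude, texture frequency)
_CLASS_APPEARANCE = {
    "nv": ((-60.0, -75.0, -60.0), 0.25, 0.05, 2.0),
    "mel": ((-110.0, -120.0, -110.0), 0.55, 0.30, 3.0),
    "bkl": ((-40.0, -55.0, -70.0), 0.35, 0.15, 8.0),
    "bcc": ((-20.0, -60.0, -45.0), 0.45, 0.10, 5.0),
    "akiec": ((10.0, -70.0, -65.0), 0.30, 0.22, 11.0),
    "vasc": ((35.0, -90.0, -40.0), 0.15, 0.06, 1.0),
    "df": ((-75.0, -45.0, -25.0), 0.60, 0.12, 14.0),
}
_SKIN_TONE = np.array([205.0, 160.0, 140.0])


@dataclass
class SyntheticSpec:
    """Counts, size, seed and class-separation scale of one synthetic draw."""

    class_counts: tuple = HAM_CLASS_COUNTS
    class_names: tuple = HAM_CLASS_NAMES
    image_size: int = 64
    seed: int = 0
    difficulty: float = 1.0

    def __post_init__(self):
        if len(self.class_counts) != len(self.class_names):
            raise ValueError("class_counts and class_names must have equal length")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be >= 0")
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16")
        if self.difficulty < 0:
            raise ValueError("difficulty must be >= 0")


def _render(rng, size: int, appearance, difficulty: float) -> np.ndarray:
    (dr, dg, db), ecc, rough, freq = appearance
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cx = size * rng.uniform(0.4, 0.6)
    cy = size * rng.uniform(0.4, 0.6)
    r0 = size * rng.uniform(0.22, 0.3)
    theta = np.arctan2(yy - cy, xx - cx)
    angle = rng.uniform(0, np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    ecc_i = np.clip(ecc * difficulty + rng.normal(0, 0.05), 0.0, 0.9)
    rr = np.sqrt(u**2 / (1 - ecc_i * 0.8) + v**2 * (1 + ecc_i))
    rough_i = max(rough * difficulty + rng.normal(0, 0.02), 0.0)
    border = r0 * (1 + rough_i * np.sin(5 * theta + rng.uniform(0, 2 * np.pi)))
    inside = rr <= border
    edge = np.clip((border - rr) / (0.15 * r0), 0.0, 1.0)  # soft rim

    img = np.empty((size, size, 3))
    img[:] = _SKIN_TONE + rng.normal(0, 4, 3)
    freq_i = max(freq * difficulty + rng.normal(0, 0.5), 0.5)
    texture = 12.0 * np.sin(2 * np.pi * freq_i * (u + v) / size + rng.uniform(0, 2 * np.pi))
    lesion_color = _SKIN_TONE + difficulty * np.array([dr, dg, db]) + rng.normal(0, 6, 3)
    for c in range(3):
        img[..., c] = np.where(inside, img[..., c] * (1 - edge) + (lesion_color[c] + texture) * edge,
                               img[..., c])
    img += rng.normal(0, 5, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Deterministic (per seed) synthetic draw with exact per-class counts."""
    rng = np.random.default_rng(spec.seed)
    n_total = int(sum(spec.class_counts))
    feats = np.empty((n_total, spec.image_size, spec.image_size, 3), dtype=np.uint8)
    labels = np.empty(n_total, dtype=int)
    i = 0
    for cls, (name, count) in enumerate(zip(spec.class_names, spec.class_counts)):
        appearance = _CLASS_APPEARANCE.get(name)
        if appearance is None:
            # unseen class name: derive a stable appearance from its index
            hue = 2 * np.pi * cls / len(spec.class_names)
            appearance = (
                (80 * np.cos(hue) - 60, -70.0, 80 * np.sin(hue) - 40),
                0.3 + 0.05 * cls, 0.1, 2.0 + 2.0 * cls,
            )
        for _ in range(count):
            feats[i] = _render(rng, spec.image_size, appearance, spec.difficulty)
            labels[i] = cls
            i += 1
    return LabeledImageSet(feats, labels, list(spec.class_names))


def manifest(dataset: LabeledImageSet) -> pd.DataFrame:
    """Per-class counts broken down by provenance; CSV-serializable."""
    from .data import PROVENANCES

    rows = []
    counts = dataset.class_counts()
    for cls, name in enumerate(dataset.class_names):
        row = {"class": name, "count": int(counts[cls])}
        for prov in PROVENANCES:
            row[prov] = int(np.sum((dataset.labels == cls) & (dataset.provenance == prov)))
        rows.append(row)
    return pd.DataFrame(rows)
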