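"""Disk I/O: per-class PNG directories with a CSV manifest."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .data import LabeledImageSet

__all__ = ["write_labeled_set", "read_image_directory"]

log = logging.getLogger(__name__)


def write_labeled_set(dataset: LabeledImageSet, path) -> Path:
    """Write PNGs into per-class subdirectories plus ``manifest.csv``
    (image_id, label, provenance).  Lossless for 8-bit pixel data."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(len(dataset)):
        name = dataset.class_names[dataset.labels[i]]
        sub = root / name
        sub.mkdir(exist_ok=True)
        image_id = f"img_{i:06d}"
        arr = np.clip(np.round(dataset.features[i]), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(sub / f"{image_id}.png")
        rows.append({"image_id": image_id, "label": name, "provenance": dataset.provenance[i]})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def read_image_directory(path, class_names=None) -> LabeledImageSet:
    """Read a per-class image directory (optionally manifest-driven).

    With ``manifest.csv`` present, its rows define membership, labels and
    provenance; a manifest label missing from the class table (directory
    names or ``class_names``) is a validation error listing the offenders.
    """
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"{root} is not a directory")
    manifest_path = root / "manifest.csv"
    dirs = sorted(d.name for d in root.iterdir() if d.is_dir())
    names = list(class_names) if class_names is not None else dirs
    feats, labels, prov = [], [], []
    if manifest_path.exists():
        df = pd.read_csv(manifest_path)
        unknown = sorted(set(df["label"]) - set(names))
        if unknown:
            raise ValueError(f"manifest labels not in class table {names}: {unknown}")
        for _, row in df.iterrows():
            img = Image.open(root / row["label"] / f"{row['image_id']}.png")
            feats.append(np.asarray(img, dtype=np.uint8))
            labels.append(names.index(row["label"]))
            prov.append(row.get("provenance", "original"))
    else:
        unknown = sorted(set(dirs) - set(names))
        if unknown:
            raise ValueError(f"class directories not in class table {names}: {unknown}")
        for d in dirs:
            for f in sorted((root / d).glob("*.png")):
                feats.append(np.asarray(Image.open(f), dtype=np.uint8))
                labels.append(names.index(d))
                prov.append("original")
    if not feats:
        log.warning("no images found under %s; returning an empty set", root)
        return LabeledImageSet(np.zeros((0, 1, 1, 3), dtype=np.uint8), np.zeros(0, dtype=int),
                               names)
    return LabeledImageSet(np.stack(feats), np.array(labels), names,
                           np.array(prov, dtype=object))
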