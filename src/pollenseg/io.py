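"""Dataset manifests and strict binary-mask PNG IO.

A manifest is a CSV with columns ``path,label,split[,mask_path][,gt_mask_path]``
listing one micrograph per row.  Masks are stored as 8-bit PNGs with
foreground 255 and background 0; loading is strict — any other pixel value is
an error, so silently re-scaled or anti-aliased masks cannot slip in.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .synth import CLASS_NAMES, LabeledSample

__all__ = ["Manifest", "load_manifest", "save_manifest", "save_mask", "load_mask",
           "save_image", "load_image", "write_dataset"]


@dataclass
class Manifest:
    """Validated table of (image, label, split, optional mask paths)."""

    frame: pd.DataFrame
    root: Path

    def __len__(self) -> int:
        return len(self.frame)

    def image_path(self, i: int) -> Path:
        return self.root / self.frame.iloc[i]["path"]


def save_image(image: np.ndarray, path) -> None:
    iio.imwrite(path, np.asarray(image, dtype=np.uint8))


def load_image(path) -> np.ndarray:
    img = iio.imread(path)
    if img.ndim == 3:  # tolerate gray saved as RGB
        img = img[..., 0]
    return img.astype(np.uint8)


def save_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as a {0, 255} 8-bit PNG."""
    m = np.asarray(mask).astype(bool)
    iio.imwrite(path, (m * np.uint8(255)))


def load_mask(path) -> np.ndarray:
    """Read a strict {0, 255} mask PNG back to booleans."""
    img = iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    vals = np.unique(img)
    if not np.isin(vals, (0, 255)).all():
        raise ValueError(f"non-binary mask at {path}: pixel values {vals.tolist()}")
    return img == 255


def load_manifest(path, classes: Sequence[str] = CLASS_NAMES,
                  check_files: bool = True) -> Manifest:
    """Load and validate a manifest CSV.

    Labels may be class names or integer indices into ``classes``; duplicates
    and dangling image paths are rejected with the offending row named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"path", "label", "split"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    root = path.parent
    labels = []
    for i, row in df.iterrows():
        lab = row["label"]
        if lab in classes:
            labels.append(classes.index(lab))
        elif lab.isdigit() and int(lab) < len(classes):
            labels.append(int(lab))
        else:
            raise ValueError(f"row {i}: unknown label {lab!r} (classes: {list(classes)})")
        if row["split"] not in ("train", "test"):
            raise ValueError(f"row {i}: split must be train/test, got {row['split']!r}")
        if check_files and not (root / row["path"]).exists():
            raise FileNotFoundError(f"row {i}: missing image {row['path']}")
    if df["path"].duplicated().any():
        dup = df["path"][df["path"].duplicated()].iloc[0]
        raise ValueError(f"duplicate image path in manifest: {dup}")
    df["label_idx"] = labels
    return Manifest(frame=df, root=root)


def save_manifest(rows: pd.DataFrame, path) -> None:
    cols = [c for c in ("path", "label", "split", "mask_path", "gt_mask_path")
            if c in rows.columns]
    rows[cols].to_csv(path, index=False)


def load_samples(manifest: Manifest) -> list[LabeledSample]:
    """Materialize manifest rows as in-memory samples."""
    out = []
    for i in range(len(manifest)):
        row = manifest.frame.iloc[i]
        gt = None
        if "gt_mask_path" in row and row.get("gt_mask_path"):
            gt = load_mask(manifest.root / row["gt_mask_path"])
        out.append(LabeledSample(image=load_image(manifest.image_path(i)),
                                 label=int(row["label_idx"]), gt_mask=gt,
                                 split=row["split"]))
    return out


def write_dataset(samples: Sequence[LabeledSample], out_dir,
                  classes: Sequence[str] = CLASS_NAMES) -> Path:
    """Write samples as PNGs plus a manifest CSV; returns the manifest path."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "gt_masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(samples):
        img_rel = f"images/sample_{i:04d}.png"
        save_image(s.image, out / img_rel)
        row = {"path": img_rel, "label": classes[s.label], "split": s.split}
        if s.gt_mask is not None:
            gt_rel = f"gt_masks/sample_{i:04d}.png"
            save_mask(s.gt_mask, out / gt_rel)
            row["gt_mask_path"] = gt_rel
        rows.append(row)
    mpath = out / "manifest.csv"
    save_manifest(pd.DataFrame(rows), mpath)
    return mpath
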