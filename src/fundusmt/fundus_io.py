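"""Reading and writing fundus images, vessel masks, grade tables and dataset
manifests; deterministic train/test splitting; resizing to the model grid.

On-disk conventions: images are PNG/JPEG/TIFF/PPM RGB (grayscale sources are
promoted to three equal channels, 16-bit sources rescaled); masks are
single-channel PNG/GIF with 0 = background and 255 = vessel, mapped to {0,1}
in memory by a >127 threshold.  Grade CSVs use the APTOS column dialect
(``id_code``, ``diagnosis``); plain ``id``/``grade`` headers are also
accepted.  Manifest CSVs have columns ``id,image,mask,grade,split``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from PIL import Image

from .specs import N_GRADES

__all__ = [
    "DatasetManifest", "load_image", "load_mask", "save_image", "save_mask",
    "resize_pair", "split_manifest", "load_grade_table", "to_model_input",
]

PathLike = Union[str, Path]


def load_image(path: PathLike) -> np.ndarray:
    """Load an RGB image as float64 (H, W, 3) scaled to [0, 1]."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:
        raise ValueError(f"cannot decode image {path}: {exc}") from exc
    if arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    else:
        arr = arr.astype(np.float64) / 255.0
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.shape[2] != 3:
        raise ValueError(f"unsupported channel count {arr.shape[2]} in {path}")
    return arr


def load_mask(path: PathLike) -> np.ndarray:
    """Load a vessel mask as uint8 {0,1}; pixels > 127 are vessel."""
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            arr = np.asarray(im)
    except Exception as exc:
        raise ValueError(f"cannot decode mask {path}: {exc}") from exc
    if arr.ndim == 3:
        if not (arr[..., :1] == arr[..., :arr.shape[2]]).all():
            raise ValueError(f"multi-channel mask with unequal channels: {path}")
        arr = arr[..., 0]
    mask = (arr.astype(np.int64) > 127).astype(np.uint8)
    if mask.sum() == 0:
        warnings.warn(f"mask {path} has no foreground pixels", RuntimeWarning,
                      stacklevel=2)
    return mask


def save_image(path: PathLike, image: np.ndarray) -> None:
    """Write a [0,1] float (H, W, 3) array as 8-bit RGB."""
    arr = np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(Path(path))


def save_mask(path: PathLike, mask: np.ndarray) -> None:
    """Write a {0,1} mask as single-channel 0/255 PNG."""
    arr = (np.asarray(mask).astype(np.uint8) * 255)
    Image.fromarray(arr, mode="L").save(Path(path))


def resize_pair(image: np.ndarray, mask: Optional[np.ndarray],
                size: int) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Resize an image (bilinear) and its mask (nearest, stays binary)."""
    if size % 16:
        raise ValueError(f"target size {size} not divisible by 16")
    im = Image.fromarray(
        np.clip(np.asarray(image) * 255.0, 0, 255).round().astype(np.uint8))
    image_r = np.asarray(im.resize((size, size), Image.BILINEAR)) / 255.0
    mask_r = None
    if mask is not None:
        m = Image.fromarray(np.asarray(mask).astype(np.uint8))
        mask_r = np.asarray(m.resize((size, size), Image.NEAREST)).astype(np.uint8)
    return image_r, mask_r


def to_model_input(images: Union[np.ndarray, list[np.ndarray]]) -> np.ndarray:
    """Stack (H, W, 3) images into the network's (N, 3, H, W) float32 batch."""
    if isinstance(images, np.ndarray) and images.ndim == 3:
        images = [images]
    batch = np.stack([np.transpose(im, (2, 0, 1)) for im in images])
    return batch.astype(np.float32)


MANIFEST_COLUMNS = ["id", "image", "mask", "grade", "split"]


@dataclass
class DatasetManifest:
    """Inventory of dataset records with optional masks, grades and splits."""

    records: pd.DataFrame
    source: str = "unknown"

    def __post_init__(self) -> None:
        df = self.records.copy()
        for col in MANIFEST_COLUMNS:
            if col not in df.columns:
                df[col] = pd.NA
        df = df[MANIFEST_COLUMNS]
        has_mask = df["mask"].notna()
        has_grade = df["grade"].notna()
        if not (has_mask | has_grade).all():
            bad = df.loc[~(has_mask | has_grade), "id"].tolist()
            raise ValueError(f"records with neither mask nor grade: {bad[:5]}")
        grades = df.loc[has_grade, "grade"].astype(int)
        if len(grades) and (grades.min() < 0 or grades.max() >= N_GRADES):
            raise ValueError("grades outside 0..4 in manifest")
        self.records = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest(
            self.records[self.records["split"] == split].reset_index(drop=True),
            source=self.source)

    def verify_paths(self, root: PathLike = ".") -> None:
        root = Path(root)
        for col in ("image", "mask"):
            for val in self.records[col].dropna():
                if not (root / val).exists():
                    raise FileNotFoundError(f"manifest references missing file {val}")

    # -- serialization -------------------------------------------------
    def to_csv(self, path: PathLike) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: PathLike, source: str = "csv") -> "DatasetManifest":
        df = pd.read_csv(path, dtype={"id": str, "image": str, "mask": str,
                                      "split": str})
        return cls(df, source=source)

    def to_json(self, path: PathLike) -> None:
        payload = {"source": self.source,
                   "records": json.loads(
                       self.records.to_json(orient="records"))}
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: PathLike) -> "DatasetManifest":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["records"]), source=payload["source"])


def split_manifest(manifest: DatasetManifest, train_fraction: float = 0.8,
                   seed: int = 0) -> DatasetManifest:
    """Assign train/test split tags by a seeded shuffle.

    Train size is ``floor(n * fraction)`` — 3662 records at the 4:1 ratio
    give 2929 train / 733 test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train fraction must be in (0,1), got {train_fraction}")
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    n_train = int(np.floor(n * train_fraction))
    order = np.random.default_rng(seed).permutation(n)
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:]] = "test"
    df = manifest.records.copy()
    df["split"] = split
    return DatasetManifest(df, source=manifest.source)


def load_grade_table(csv_path: PathLike) -> dict[str, int]:
    """Load an image-id -> grade map; grades validated in 0..4."""
    df = pd.read_csv(csv_path)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("id_code") or cols.get("id")
    gr_col = cols.get("diagnosis") or cols.get("grade")
    if id_col is None or gr_col is None:
        raise ValueError(f"grade table needs id_code/diagnosis (or id/grade) "
                         f"columns, found {list(df.columns)}")
    table: dict[str, int] = {}
    for row_no, (idx, row) in enumerate(df.iterrows(), start=2):
        key = str(row[id_col])
        try:
            grade = int(row[gr_col])
        except (TypeError, ValueError):
            raise ValueError(f"row {row_no}: non-integer grade {row[gr_col]!r}")
        if not 0 <= grade < N_GRADES:
            raise ValueError(f"row {row_no}: grade {grade} outside 0..{N_GRADES - 1}")
        if key in table:
            raise ValueError(f"row {row_no}: duplicate id {key!r}")
        table[key] = grade
    return table
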