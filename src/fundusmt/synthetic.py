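"""Deterministic synthetic fundus generator.

Emulates the two data kinds the networks train on, with exact ground truth
and no downloads:

* **vessel pairs** — a bright circular fundus field on a dark surround, with
  a recursive binary branching vessel tree of decreasing caliber drawn
  darker than the field; the mask is the exact pre-noise rasterization;
* **graded images** — the same background plus grade-conditioned lesion
  content: Poisson-distributed dark dots (microaneurysm-like) and bright
  blobs (exudate-like) whose mean count is nondecreasing in grade 0..4.

Every sample is a pure function of ``(seed, kind, grade, index)``; contrast
and lesion rates are chosen so small CPU models can learn the tasks in
minutes — the generator is a test instrument, not a clinical simulator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import fundus_io
from .fundus_io import DatasetManifest
from .specs import N_GRADES

__all__ = [
    "SynthConfig", "TABLE2_DISTRIBUTION", "generate_vessel_pair",
    "generate_dr_image", "generate_dataset", "apportion_grades",
    "vessel_batch", "dr_batch",
]

# Published class distribution of the 3662-image retinopathy grade table.
TABLE2_DISTRIBUTION = (1805, 370, 999, 193, 295)

# Intensities on the 0..255 scale.
_BG_OUTSIDE = 35.0
_BG_FIELD = 185.0
_VESSEL_CONTRAST = 75.0
_LESION_DARK = 70.0
_LESION_BRIGHT = 55.0
# fundus-like channel tint applied to the grayscale base
_TINT = np.array([1.0, 0.62, 0.40])


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults target quick CPU learnability."""
    size: int = 128
    n_images: int = 20
    seed: int = 0
    branching_depth: int = 5
    initial_width: float = 4.0
    width_decay: float = 0.8
    lesion_rates: tuple[float, ...] = (0.0, 4.0, 9.0, 16.0, 28.0)
    noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.width_decay < 1.0:
            raise ValueError("width decay must be in (0,1)")
        if len(self.lesion_rates) != N_GRADES:
            raise ValueError(f"need {N_GRADES} lesion rates")
        if any(b > a for a, b in zip(self.lesion_rates[1:], self.lesion_rates[:-1])):
            raise ValueError("lesion rates must be nondecreasing over grades")


def _disc(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r = 0.47 * size
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def _stamp_disk(canvas: np.ndarray, cy: float, cx: float, radius: float) -> None:
    size = canvas.shape[0]
    r = max(radius, 0.5)
    y0, y1 = int(max(0, np.floor(cy - r))), int(min(size, np.ceil(cy + r) + 1))
    x0, x1 = int(max(0, np.floor(cx - r))), int(min(size, np.ceil(cx + r) + 1))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _grow_tree(mask: np.ndarray, rng: np.random.Generator, cfg: SynthConfig) -> None:
    """Recursive binary branching random-walk tree rasterized into ``mask``."""
    size = cfg.size
    c = (size - 1) / 2.0
    field_r = 0.47 * size
    # start near the disc centre, two opposite trunks
    start = np.array([c + rng.uniform(-0.08, 0.08) * size,
                      c + rng.uniform(-0.08, 0.08) * size])
    base_angle = rng.uniform(0, 2 * np.pi)
    stack = [(start.copy(), base_angle, cfg.initial_width, cfg.branching_depth),
             (start.copy(), base_angle + np.pi + rng.uniform(-0.4, 0.4),
              cfg.initial_width, cfg.branching_depth)]
    step = max(2.0, 0.02 * size)
    seg_steps = max(4, int(0.09 * size / step * 4))
    while stack:
        pos, angle, width, depth = stack.pop()
        if depth == 0:
            continue
        for _ in range(seg_steps):
            angle += rng.normal(0.0, 0.18)            # random-walk curvature
            pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
            if (pos[0] - c) ** 2 + (pos[1] - c) ** 2 > (field_r - 1.5) ** 2:
                depth = 0
                break
            _stamp_disk(mask, pos[0], pos[1], width / 2.0)
        if depth > 0:
            spread = rng.uniform(0.35, 0.8)
            child_w = width * cfg.width_decay
            stack.append((pos.copy(), angle - spread, child_w, depth - 1))
            stack.append((pos.copy(), angle + spread, child_w, depth - 1))


def _base_field(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    rad = np.sqrt((yy - c) ** 2 + (xx - c) ** 2) / (0.47 * size)
    inside = _disc(size)
    # gentle radial falloff toward the field edge
    base = np.where(inside, _BG_FIELD * (1.0 - 0.12 * np.clip(rad, 0, 1) ** 2),
                    _BG_OUTSIDE)
    return base


def _finalize(base: np.ndarray, rng: np.random.Generator,
              sigma: float) -> np.ndarray:
    noisy = base + rng.normal(0.0, sigma, size=base.shape)
    gray = np.clip(noisy, 0, 255) / 255.0
    return np.clip(gray[:, :, None] * _TINT[None, None, :], 0.0, 1.0)


def generate_vessel_pair(cfg: SynthConfig, index: int
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One (image, mask) pair, fully determined by (cfg.seed, index).

    The image is (H, W, 3) float in [0,1]; the mask is the exact pre-noise
    {0,1} rasterization of the vessel tree.
    """
    rng = np.random.default_rng((cfg.seed, 0, index))
    size = cfg.size
    mask = np.zeros((size, size), dtype=bool)
    if cfg.branching_depth > 0:
        _grow_tree(mask, rng, cfg)
    base = _base_field(size)
    base[mask] -= _VESSEL_CONTRAST
    image = _finalize(base, rng, cfg.noise_sigma)
    return image, mask.astype(np.uint8)


def generate_dr_image(cfg: SynthConfig, grade: int, index: int
                      ) -> tuple[np.ndarray, int]:
    """One graded fundus image with grade-conditioned lesion content."""
    if not 0 <= grade < N_GRADES:
        raise ValueError(f"grade must be 0..{N_GRADES - 1}, got {grade}")
    rng = np.random.default_rng((cfg.seed, 1, grade, index))
    size = cfg.size
    mask = np.zeros((size, size), dtype=bool)
    if cfg.branching_depth > 0:
        _grow_tree(mask, rng, cfg)
    base = _base_field(size)
    base[mask] -= _VESSEL_CONTRAST
    rate = cfg.lesion_rates[grade]
    c = (size - 1) / 2.0
    field_r = 0.44 * size
    n_dark = rng.poisson(rate)
    n_bright = rng.poisson(rate / 2.0)
    for n_les, delta, rad_range in ((n_dark, -_LESION_DARK, (1.0, 2.5)),
                                    (n_bright, +_LESION_BRIGHT, (1.5, 3.5))):
        for _ in range(n_les):
            ang = rng.uniform(0, 2 * np.pi)
            rr = field_r * np.sqrt(rng.uniform(0, 1))
            cy, cx = c + rr * np.sin(ang), c + rr * np.cos(ang)
            les = np.zeros((size, size), dtype=bool)
            _stamp_disk(les, cy, cx, rng.uniform(*rad_range))
            base[les] += delta
    image = _finalize(base, rng, cfg.noise_sigma)
    return image, grade


def apportion_grades(n: int,
                     distribution: tuple[int, ...] = TABLE2_DISTRIBUTION
                     ) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``n`` images over the 5 grades."""
    dist = np.asarray(distribution, dtype=float)
    quotas = n * dist / dist.sum()
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    return tuple(int(c) for c in counts)


def generate_dataset(cfg: SynthConfig, kind: str, out_dir) -> DatasetManifest:
    """Write a synthetic dataset (images, masks, grade CSV, manifest) to disk.

    ``kind`` is ``vessel`` (image+mask pairs), ``dr`` (graded images with the
    published class imbalance), or ``joint`` (both record types in one
    manifest).  Regenerating with the same config yields byte-identical
    files.
    """
    if kind not in ("vessel", "dr", "joint"):
        raise ValueError(f"kind must be vessel|dr|joint, got {kind!r}")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    grade_rows: list[dict] = []
    if kind in ("vessel", "joint"):
        (out / "masks").mkdir(exist_ok=True)
        for i in range(cfg.n_images):
            image, mask = generate_vessel_pair(cfg, i)
            img_p = f"images/vessel_{i:04d}.png"
            msk_p = f"masks/vessel_{i:04d}.png"
            fundus_io.save_image(out / img_p, image)
            fundus_io.save_mask(out / msk_p, mask)
            rows.append({"id": f"vessel_{i:04d}", "image": img_p,
                         "mask": msk_p, "grade": pd.NA, "split": pd.NA})
    if kind in ("dr", "joint"):
        counts = apportion_grades(cfg.n_images)
        idx = 0
        for grade, cnt in enumerate(counts):
            for j in range(cnt):
                image, _ = generate_dr_image(cfg, grade, j)
                img_p = f"images/dr_{idx:04d}.png"
                fundus_io.save_image(out / img_p, image)
                rows.append({"id": f"dr_{idx:04d}", "image": img_p,
                             "mask": pd.NA, "grade": grade, "split": pd.NA})
                grade_rows.append({"id_code": f"dr_{idx:04d}",
                                   "diagnosis": grade})
                idx += 1
        pd.DataFrame(grade_rows).to_csv(out / "grades.csv", index=False)
    manifest = DatasetManifest(pd.DataFrame(rows), source=f"synthetic-{kind}")
    manifest.to_csv(out / "manifest.csv")
    return manifest


# -- in-memory batches for training/tests (no disk round-trip) -------------

def vessel_batch(cfg: SynthConfig, indices: range
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(N, 3, H, W) float32 images and (N, H, W) uint8 masks."""
    pairs = [generate_vessel_pair(cfg, i) for i in indices]
    images = fundus_io.to_model_input([p[0] for p in pairs])
    masks = np.stack([p[1] for p in pairs])
    return images, masks


def dr_batch(cfg: SynthConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    """(N, 3, H, W) float32 images and (N,) int grades, class-balanced by
    the published distribution."""
    counts = apportion_grades(n)
    images, grades = [], []
    for grade, cnt in enumerate(counts):
        for j in range(cnt):
            im, g = generate_dr_image(cfg, grade, j)
            images.append(im)
            grades.append(g)
    return fundus_io.to_model_input(images), np.asarray(grades, dtype=int)
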