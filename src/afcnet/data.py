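"""Dataset manifests, split/merge protocol, paired augmentation and loading."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .nd import bilinear_resize_array
from .synthdata import ManifestRow, read_manifest, write_manifest  # noqa: F401


def split_dataset(
    rows: list[ManifestRow], train_fraction: float, seed: int
) -> tuple[list[ManifestRow], list[ManifestRow]]:
    """Shuffle with `seed`; train gets floor(train_fraction * n) items, the
    remainder is the test split.  Disjoint and exhaustive by construction."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if not rows:
        raise ValueError("cannot split an empty manifest")
    order = np.random.default_rng(seed).permutation(len(rows))
    n_train = int(np.floor(train_fraction * len(rows)))
    train = [
        ManifestRow(rows[i].image, rows[i].mask, "train") for i in order[:n_train]
    ]
    test = [ManifestRow(rows[i].image, rows[i].mask, "test") for i in order[n_train:]]
    return train, test


def merge_manifests(parts: list[list[ManifestRow]]) -> list[ManifestRow]:
    """Concatenate manifests in order; duplicate paths warn but are kept."""
    merged: list[ManifestRow] = []
    seen: set[str] = set()
    for part in parts:
        for r in part:
            if r.image in seen:
                warnings.warn(f"duplicate image path in merged manifest: {r.image}")
            seen.add(r.image)
            merged.append(r)
    return merged


# --------------------------------------------------------------- augmentation

def rotate90(image: np.ndarray, mask: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    return np.rot90(image, k, axes=(0, 1)).copy(), np.rot90(mask, k, axes=(0, 1)).copy()


def hflip(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return image[:, ::-1].copy(), mask[:, ::-1].copy()


def vflip(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return image[::-1].copy(), mask[::-1].copy()


def coarse_mask(
    image: np.ndarray,
    rng: np.random.Generator,
    max_rects: int = 8,
    side_range: tuple[float, float] = (0.05, 0.15),
) -> np.ndarray:
    """Occlude 1..max_rects random rectangles with the image mean (image only)."""
    out = image.copy()
    h, w = image.shape[:2]
    fill = image.mean(axis=(0, 1))
    for _ in range(int(rng.integers(1, max_rects + 1))):
        rh = int(rng.uniform(*side_range) * h)
        rw = int(rng.uniform(*side_range) * w)
        y0 = int(rng.integers(0, max(h - rh, 1)))
        x0 = int(rng.integers(0, max(w - rw, 1)))
        out[y0 : y0 + rh, x0 : x0 + rw] = fill
    return out


def augment(
    image: np.ndarray, mask: np.ndarray, rng: np.random.Generator | int
) -> tuple[np.ndarray, np.ndarray]:
    """Right-angle rotation, random flips (paired) and coarse masking (image only)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    image, mask = rotate90(image, mask, int(rng.integers(0, 4)))
    if rng.random() < 0.5:
        image, mask = hflip(image, mask)
    if rng.random() < 0.5:
        image, mask = vflip(image, mask)
    if rng.random() < 0.5:
        image = coarse_mask(image, rng)
    return image, mask


# -------------------------------------------------------------------- loading

def load_pair(
    row: ManifestRow, input_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Load an image/mask pair as ((H,W,3) float [0,1], (H,W) uint8 {0,1}).

    If `input_size` is given and differs from the stored resolution the image
    is resized bilinearly and the mask with nearest-neighbour.
    """
    for p in (row.image, row.mask):
        if not Path(p).exists():
            raise FileNotFoundError(f"manifest references missing file: {p}")
    image = np.asarray(Image.open(row.image).convert("RGB"), dtype=float) / 255.0
    mask = (np.asarray(Image.open(row.mask).convert("L")) > 127).astype(np.uint8)
    if input_size is not None and image.shape[:2] != (input_size, input_size):
        warnings.warn(
            f"resizing {row.image} from {image.shape[:2]} to model input {input_size}"
        )
        image = bilinear_resize_array(image, input_size, input_size)
        mask_img = Image.fromarray(mask * np.uint8(255), mode="L").resize(
            (input_size, input_size), Image.NEAREST
        )
        mask = (np.asarray(mask_img) > 127).astype(np.uint8)
    return image, mask


def load_pairs(
    rows: list[ManifestRow], input_size: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack a manifest into ((N,3,H,W), (N,H,W)) arrays ready for the model."""
    images, masks = [], []
    for row in rows:
        img, msk = load_pair(row, input_size)
        images.append(img.transpose(2, 0, 1))
        masks.append(msk)
    return np.stack(images), np.stack(masks)
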