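"""Seeded generator of endoscopy-like frames with paired binary lesion masks.

Each frame: smooth reddish mucosa texture (low-pass filtered noise), one
radially-deformed elliptical lesion with a blurred boundary and configurable
contrast, a dark circular field-of-view vignette, a few specular highlight
spots and additive Gaussian noise.  The mask is the lesion support before
blurring.  Everything is a pure function of (spec.seed, index).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .exceptions import GenerationError

# defaults follow the printed foreground-area range of the clinical frames
DEFAULT_AREA_RANGE = (0.0034, 0.4588)


@dataclass
class SynthSpec:
    image_size: int = 352
    area_fraction_range: tuple[float, float] = DEFAULT_AREA_RANGE
    contrast_offset_range: tuple[float, float] = (0.10, 0.30)
    highlight_count_range: tuple[int, int] = (0, 4)
    noise_sd: float = 0.02
    vignette_strength: float = 0.6
    deform_harmonics: int = 4
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_fraction_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError(f"invalid area fraction range {self.area_fraction_range}")
        if self.image_size % 16 != 0:
            raise ValueError("image_size must be divisible by 16")


def smoke_spec(image_size: int = 96, seed: int = 0) -> SynthSpec:
    """Reduced-difficulty spec for the CPU training smoke protocol.

    Narrows the lesion area range and raises contrast so a width-16 model
    can reach a high Dice within a few hundred optimizer steps; the default
    spec keeps the full clinical area range (including sub-1% lesions) for
    data-generation and evaluation fixtures.
    """
    return SynthSpec(
        image_size=image_size,
        area_fraction_range=(0.02, 0.30),
        contrast_offset_range=(0.18, 0.35),
        noise_sd=0.01,
        seed=seed,
    )


@dataclass
class SamplePair:
    image: np.ndarray  # (H, W, 3) float in [0, 1]
    mask: np.ndarray  # (H, W) uint8 in {0, 1}


@dataclass
class ManifestRow:
    image: str
    mask: str
    split: str = "all"


def _lesion_mask(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Wobbly-ellipse support whose pixel fraction lands inside the spec range."""
    n = spec.image_size
    lo, hi = spec.area_fraction_range
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    for _ in range(12):
        # log-uniform target keeps small lesions well represented
        target = float(np.exp(rng.uniform(np.log(lo * 1.08), np.log(hi * 0.92))))
        cx = rng.uniform(0.38, 0.62) * n
        cy = rng.uniform(0.38, 0.62) * n
        elong = rng.uniform(0.7, 1.4)
        phase = rng.uniform(0, 2 * np.pi, size=spec.deform_harmonics)
        amp = rng.uniform(0, 0.12, size=spec.deform_harmonics) / np.arange(
            1, spec.deform_harmonics + 1
        )
        rot = rng.uniform(0, np.pi)
        r0 = n * np.sqrt(target / np.pi)
        for _ in range(6):
            dx, dy = xx - cx, yy - cy
            dxr = dx * np.cos(rot) + dy * np.sin(rot)
            dyr = -dx * np.sin(rot) + dy * np.cos(rot)
            rx = r0 * np.sqrt(elong)
            ry = r0 / np.sqrt(elong)
            rho = np.sqrt((dxr / rx) ** 2 + (dyr / ry) ** 2)
            theta = np.arctan2(dyr / ry, dxr / rx)
            wobble = np.ones_like(theta)
            for h in range(spec.deform_harmonics):
                wobble += amp[h] * np.cos((h + 2) * theta + phase[h])
            mask = (rho <= wobble).astype(np.uint8)
            frac = mask.mean()
            if lo <= frac <= hi and mask.any():
                return mask
            if frac <= 0:
                break
            r0 = r0 * np.sqrt(target / max(frac, 1e-9))
    raise GenerationError(
        f"could not draw a lesion with area fraction in [{lo}, {hi}] "
        f"at image size {n}"
    )


def _render(spec: SynthSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (image, mask, lesion_additive_component)."""
    n = spec.image_size
    mask = _lesion_mask(spec, rng)

    base = np.array([0.55, 0.27, 0.22]) + rng.uniform(-0.05, 0.05, size=3)
    texture = gaussian_filter(rng.normal(size=(n, n)), sigma=n / 10.0)
    texture = texture / (np.abs(texture).max() + 1e-12)
    chan_gain = np.array([1.0, 0.7, 0.6]) * 0.07
    image = base[None, None, :] + texture[:, :, None] * chan_gain[None, None, :]

    offset = rng.uniform(*spec.contrast_offset_range) * rng.choice([-1.0, 1.0])
    soft = gaussian_filter(mask.astype(float), sigma=2.0)
    lesion_component = offset * soft[:, :, None] * np.array([1.0, 0.8, 0.75])[None, None, :]
    image = image + lesion_component

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    d = np.sqrt((xx - n / 2) ** 2 + (yy - n / 2) ** 2)
    falloff = np.clip((d - 0.30 * n) / (0.25 * n), 0.0, 1.0)
    image = image * (1.0 - spec.vignette_strength * falloff**2)[:, :, None]

    k_lo, k_hi = spec.highlight_count_range
    for _ in range(int(rng.integers(k_lo, k_hi + 1))):
        hx, hy = rng.uniform(0.15 * n, 0.85 * n, size=2)
        sigma = rng.uniform(1.0, 3.5)
        amp = rng.uniform(0.3, 0.8)
        spot = amp * np.exp(-((xx - hx) ** 2 + (yy - hy) ** 2) / (2 * sigma**2))
        image = image + spot[:, :, None]

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask, lesion_component


def generate_sample(spec: SynthSpec, index: int) -> SamplePair:
    rng = np.random.default_rng([spec.seed, int(index)])
    image, mask, _ = _render(spec, rng)
    return SamplePair(image=image, mask=mask)


def generate_dataset(spec: SynthSpec, n: int, out_dir: str | Path) -> list[ManifestRow]:
    """Write n PNG image/mask pairs plus a TSV manifest; deterministic in spec."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows: list[ManifestRow] = []
    for i in range(n):
        pair = generate_sample(spec, i)
        img_path = out_dir / "images" / f"sample_{i:05d}.png"
        mask_path = out_dir / "masks" / f"sample_{i:05d}.png"
        img8 = np.round(pair.image * 255.0).astype(np.uint8)
        Image.fromarray(img8, mode="RGB").save(img_path)
        Image.fromarray(pair.mask * np.uint8(255), mode="L").save(mask_path)
        rows.append(ManifestRow(image=str(img_path), mask=str(mask_path)))
    write_manifest(rows, out_dir / "manifest.tsv")
    return rows


def write_manifest(rows: list[ManifestRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["image", "mask", "split"])
        for r in rows:
            w.writerow([r.image, r.mask, r.split])


def read_manifest(path: str | Path) -> list[ManifestRow]:
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["image", "mask"]:
            raise ValueError(f"unrecognized manifest header {header} in {path}")
        for rec in reader:
            rows.append(ManifestRow(image=rec[0], mask=rec[1], split=rec[2] if len(rec) > 2 else "all"))
    return rows
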