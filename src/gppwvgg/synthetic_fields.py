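"""Seeded generator of class-conditioned synthetic canopy images.

Stands in for field photographs of crop canopies so the full pipeline
(reading, augmentation, training, evaluation) runs with no external data.
Each class is defined by a texture signature: leaf-stripe orientation
``theta`` (degrees), stripe frequency ``freq`` (cycles/image) and a green
hue centre ``hue`` (HSV units in [0, 1]).  An image is an oriented
sinusoidal stripe texture in a green hue band, composited over a brown
cluttered background, with additive pixel noise.  Class difficulty is tuned
by signature spacing, noise level and clutter density.

Generation is a pure function of (spec, seed): the same spec writes
byte-identical PNG files.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv

from .layers import ConfigError

DIFFICULTY = {
    #            hue spacing, sigma, clutter
    "easy":   (0.025, 0.03, 0.10),
    "medium": (0.012, 0.06, 0.30),
    "hard":   (0.006, 0.10, 0.50),
}

GREEN_HUE_BASE = 0.22     # HSV hue of the greenest class band
BROWN_HUE = 0.08          # background soil hue


@dataclass(frozen=True)
class ClassSignature:
    theta: float  # stripe orientation, degrees in [0, 180)
    freq: float   # stripe frequency, cycles per image side
    hue: float    # leaf hue centre, HSV units in [0, 1)


def default_signatures(num_classes: int, difficulty: str = "easy"
                       ) -> tuple[ClassSignature, ...]:
    spacing = DIFFICULTY[difficulty][0]
    return tuple(
        ClassSignature(
            theta=(10.0 + 180.0 * c / num_classes) % 180.0,
            freq=8.0 + 2.0 * c,
            hue=GREEN_HUE_BASE + spacing * c,
        )
        for c in range(num_classes)
    )


@dataclass(frozen=True)
class SyntheticSpec:
    num_classes: int = 6
    n_per_class: int = 20
    size: int = 224
    seed: int = 0
    difficulty: str = "easy"
    signatures: tuple[ClassSignature, ...] | None = None
    sigma: float | None = None     # pixel-noise std in [0,1] units
    clutter: float | None = None   # background area fraction in [0, 1)

    def __post_init__(self):
        if self.num_classes < 1 or self.n_per_class < 1 or self.size < 8:
            raise ConfigError("num_classes, n_per_class >= 1 and size >= 8 required")
        if self.difficulty not in DIFFICULTY:
            raise ConfigError(f"unknown difficulty {self.difficulty!r}")
        sigs = self.resolved_signatures
        if len(sigs) != self.num_classes:
            raise ConfigError("one signature per class required")
        triples = {(round(s.theta, 6), round(s.freq, 6), round(s.hue, 6))
                   for s in sigs}
        if len(triples) != self.num_classes:
            raise ConfigError("class signatures must be pairwise distinct")
        if not 0 <= self.clutter_density < 1:
            raise ConfigError("clutter density must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ConfigError("noise sigma must be non-negative")

    @property
    def resolved_signatures(self) -> tuple[ClassSignature, ...]:
        if self.signatures is not None:
            return self.signatures
        return default_signatures(self.num_classes, self.difficulty)

    @property
    def noise_sigma(self) -> float:
        return DIFFICULTY[self.difficulty][1] if self.sigma is None else self.sigma

    @property
    def clutter_density(self) -> float:
        return DIFFICULTY[self.difficulty][2] if self.clutter is None else self.clutter


def _smooth_noise(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude low-frequency noise field."""
    z = rng.standard_normal((size, size))
    z = ndimage.gaussian_filter(z, sigma=scale, mode="wrap")
    span = np.abs(z).max()
    return z / span if span > 0 else z


def generate_image(class_id: int, spec: SyntheticSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """One uint8 (size, size, 3) RGB image for ``class_id``."""
    if not 0 <= class_id < spec.num_classes:
        raise ConfigError(f"class_id {class_id} outside 0..{spec.num_classes - 1}")
    sig = spec.resolved_signatures[class_id]
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s] / s
    theta = math.radians(sig.theta)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    stripe = 0.5 * (1.0 + np.sin(
        2.0 * math.pi * sig.freq * (xx * math.cos(theta) + yy * math.sin(theta))
        + phase))

    hsv = np.empty((s, s, 3))
    hsv[..., 0] = sig.hue
    hsv[..., 1] = 0.55 + 0.25 * stripe
    hsv[..., 2] = 0.35 + 0.45 * stripe

    clutter = spec.clutter_density
    if clutter > 0:
        # brown cluttered background visible through gaps in the canopy
        bg = np.empty((s, s, 3))
        bg[..., 0] = np.mod(BROWN_HUE + 0.02 * _smooth_noise(rng, s, s / 24), 1.0)
        bg[..., 1] = 0.45 + 0.1 * _smooth_noise(rng, s, s / 24)
        bg[..., 2] = 0.30 + 0.20 * np.abs(_smooth_noise(rng, s, s / 32))
        gap_field = _smooth_noise(rng, s, s / 16)
        threshold = np.quantile(gap_field, clutter)
        mask = (gap_field >= threshold)[..., None]
        hsv = np.where(mask, hsv, np.clip(bg, 0.0, 1.0))

    rgb = hsv2rgb(np.clip(hsv, 0.0, 1.0))
    sigma = spec.noise_sigma
    if sigma > 0:
        rgb = rgb + rng.normal(0.0, sigma, size=rgb.shape)
    return (np.clip(rgb, 0.0, 1.0) * 255.0 + 0.5).astype(np.uint8)


def generate_arrays(spec: SyntheticSpec) -> tuple[np.ndarray, np.ndarray]:
    """The whole dataset in memory: uint8 (n, size, size, 3) images + labels."""
    rng = np.random.default_rng(spec.seed)
    images, labels = [], []
    for c in range(spec.num_classes):
        for _ in range(spec.n_per_class):
            images.append(generate_image(c, spec, rng))
            labels.append(c)
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def generate_dataset(spec: SyntheticSpec, out_dir, overwrite: bool = False) -> Path:
    """Write the dataset as ``out/<class_name>/*.png`` plus a CSV manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{out} exists and is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    rows = []
    for c in range(spec.num_classes):
        sig = spec.resolved_signatures[c]
        cls_name = f"class_{c:02d}"
        cls_dir = out / cls_name
        cls_dir.mkdir(exist_ok=True)
        for i in range(spec.n_per_class):
            img = generate_image(c, spec, rng)
            path = cls_dir / f"{cls_name}_{i:04d}.png"
            Image.fromarray(img).save(path)
            rows.append([str(path.relative_to(out)), cls_name,
                         f"{sig.theta:.3f}", f"{sig.freq:.3f}", f"{sig.hue:.4f}",
                         f"{spec.noise_sigma:.4f}", f"{spec.clutter_density:.3f}"])
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "theta_deg", "freq_cpi", "hue",
                         "sigma", "clutter"])
        writer.writerows(rows)
    return out


def hue_histogram(img: np.ndarray, bins: int = 32) -> np.ndarray:
    """Normalised hue histogram of an RGB image (a simple colour descriptor)."""
    arr = np.asarray(img)
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    hue = rgb2hsv(arr)[..., 0].ravel()
    hist, _ = np.histogram(hue, bins=bins, range=(0.0, 1.0))
    return hist / hist.sum()
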