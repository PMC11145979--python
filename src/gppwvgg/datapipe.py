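"""Dataset protocol: augmentation, splitting, directory reading, preprocessing.

The augmentation pipeline mirrors the field protocol: independent vertical /
horizontal flips, rotation uniform in [-30, +30] degrees (reflect-padded),
brightness / hue / saturation factors uniform in [0.9, 1.1], a random
300 x 400 crop and a bilinear resize to 224 x 224.  Hue/saturation factors act
in HSV space: saturation and value are multiplied by their factor, hue is
shifted by 0.25 x (factor - 1) (a bounded hue rotation; the protocol states
only the numeric factor range).

Splits are stratified: a 60/40 train/test partition or k-fold (default 3)
cross-validation folds, all driven by a single seed.

The mobile-app rule (:func:`app_preprocess`) resizes any image whose longer
side exceeds 300 px to 300 x 300 before the final 224 x 224 resize; smaller
images go straight to 224 x 224.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.color import hsv2rgb, rgb2hsv
from sklearn.model_selection import StratifiedKFold, train_test_split

IMAGE_EXTENSIONS = {".jpg", ".jpeg", ".png", ".bmp", ".tif", ".tiff"}


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    vflip: bool = True
    hflip: bool = True
    rotation_range: tuple[float, float] = (-30.0, 30.0)
    brightness: tuple[float, float] = (0.9, 1.1)
    hue: tuple[float, float] = (0.9, 1.1)
    saturation: tuple[float, float] = (0.9, 1.1)
    crop_size: tuple[int, int] = (300, 400)     # (width, height)
    final_size: tuple[int, int] = (224, 224)    # (width, height)
    seed: int = 0

    HUE_SHIFT_SCALE = 0.25  # hue shift = scale * (factor - 1), in [0,1) hue units


@dataclass(frozen=True)
class AugmentFactors:
    """One concrete draw of the augmentation randomness."""

    vflip: bool
    hflip: bool
    angle: float
    brightness: float
    hue: float
    saturation: float
    crop_cx: float  # crop-origin positions as fractions of the valid range
    crop_cy: float

    @classmethod
    def identity(cls) -> "AugmentFactors":
        """No flip/rotation, unit photometric factors, centred crop."""
        return cls(False, False, 0.0, 1.0, 1.0, 1.0, 0.5, 0.5)


def sample_factors(cfg: AugmentConfig, rng: np.random.Generator) -> AugmentFactors:
    """Draw augmentation factors; every factor stays in its closed interval."""
    return AugmentFactors(
        vflip=cfg.vflip and bool(rng.random() < 0.5),
        hflip=cfg.hflip and bool(rng.random() < 0.5),
        angle=float(rng.uniform(*cfg.rotation_range)),
        brightness=float(rng.uniform(*cfg.brightness)),
        hue=float(rng.uniform(*cfg.hue)),
        saturation=float(rng.uniform(*cfg.saturation)),
        crop_cx=float(rng.random()),
        crop_cy=float(rng.random()),
    )


def _to_float_array(img) -> np.ndarray:
    if isinstance(img, Image.Image):
        img = np.asarray(img.convert("RGB"))
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {img.shape}")
    if img.dtype == np.uint8:
        return img.astype(np.float64) / 255.0
    return np.clip(img.astype(np.float64), 0.0, 1.0)


def apply_factors(img, cfg: AugmentConfig, f: AugmentFactors) -> Image.Image:
    """Deterministically apply one draw: flip -> rotate -> jitter -> crop -> resize."""
    arr = _to_float_array(img)
    h, w = arr.shape[:2]
    cw, ch = cfg.crop_size
    if w < cw or h < ch:
        raise ValueError(
            f"image {w}x{h} is smaller than the crop size; needs at least "
            f"{cw}x{ch} (width x height)")
    if f.vflip:
        arr = arr[::-1]
    if f.hflip:
        arr = arr[:, ::-1]
    if f.angle != 0.0:
        arr = ndimage.rotate(arr, f.angle, axes=(1, 0), reshape=False,
                             mode="reflect", order=1)
        arr = np.clip(arr, 0.0, 1.0)
    if not (f.brightness == f.hue == f.saturation == 1.0):
        hsv = rgb2hsv(arr)
        hsv[..., 0] = np.mod(hsv[..., 0] + cfg.HUE_SHIFT_SCALE * (f.hue - 1.0), 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * f.saturation, 0.0, 1.0)
        hsv[..., 2] = np.clip(hsv[..., 2] * f.brightness, 0.0, 1.0)
        arr = hsv2rgb(hsv)
    x0 = int(round(f.crop_cx * (w - cw)))
    y0 = int(round(f.crop_cy * (h - ch)))
    arr = arr[y0 : y0 + ch, x0 : x0 + cw]
    out = Image.fromarray((np.clip(arr, 0, 1) * 255.0 + 0.5).astype(np.uint8))
    return out.resize(cfg.final_size, Image.BILINEAR)


def augment_image(img, cfg: AugmentConfig,
                  rng: np.random.Generator | None = None,
                  factors: AugmentFactors | None = None) -> Image.Image:
    """One augmented sample; deterministic given the seed (or explicit factors)."""
    if factors is None:
        rng = rng if rng is not None else np.random.default_rng(cfg.seed)
        factors = sample_factors(cfg, rng)
    return apply_factors(img, cfg, factors)


def app_preprocess(img) -> Image.Image:
    """The mobile-app resize rule: >300 px longer side -> 300x300 -> 224x224."""
    if isinstance(img, np.ndarray):
        if img.dtype != np.uint8:
            img = (np.clip(img, 0, 1) * 255.0 + 0.5).astype(np.uint8)
        img = Image.fromarray(img)
    img = img.convert("RGB")
    if max(img.size) > 300:
        img = img.resize((300, 300), Image.BILINEAR)
    return img.resize((224, 224), Image.BILINEAR)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.6
    k: int | None = None   # when set, produce k stratified CV folds instead
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train fraction must be in (0, 1)")
        if self.k is not None and self.k < 2:
            raise ValueError("k-fold splitting requires k >= 2")


def split_dataset(labels, spec: SplitSpec = SplitSpec()):
    """Stratified split of ``labels`` into train/test indices or k CV folds."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    classes, counts = np.unique(labels, return_counts=True)
    if spec.k is not None:
        if counts.min() < spec.k:
            lacking = classes[counts < spec.k]
            raise ValueError(
                f"classes {lacking.tolist()} have fewer than {spec.k} items; "
                f"cannot build {spec.k} folds")
        skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.seed)
        return [(idx[tr], idx[te]) for tr, te in skf.split(idx, labels)]
    if counts.min() < 2:
        raise ValueError("stratified splitting needs at least 2 items per class")
    train_idx, test_idx = train_test_split(
        idx, train_size=spec.train_fraction, stratify=labels,
        random_state=spec.seed)
    return np.sort(train_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# Class-per-directory reading
# ---------------------------------------------------------------------------

@dataclass
class DatasetIndex:
    root: Path
    classes: list[str]
    paths: list[Path]
    labels: np.ndarray

    def __len__(self):
        return len(self.paths)

    @property
    def label_map(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.classes)}


def read_dataset(root, warn_empty: bool = True) -> DatasetIndex:
    """Index a ``root/<class_name>/*.png`` layout.

    Classes and files are ordered lexicographically so the label map is
    deterministic; empty class directories are warned about and excluded;
    non-image files are ignored.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir()) if root.is_dir() else []
    classes, paths, labels = [], [], []
    for d in class_dirs:
        files = sorted(p for p in d.iterdir()
                       if p.is_file() and p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            if warn_empty:
                warnings.warn(f"class directory {d.name!r} contains no images; "
                              "excluded", stacklevel=2)
            continue
        label = len(classes)
        classes.append(d.name)
        paths.extend(files)
        labels.extend([label] * len(files))
    if not classes and warn_empty:
        warnings.warn(f"no class directories with images under {root}", stacklevel=2)
    return DatasetIndex(root=root, classes=classes, paths=paths,
                        labels=np.asarray(labels, dtype=np.int64))


def load_images(index: DatasetIndex, size: int | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Load an index into a uint8 (n, H, W, 3) array; failures are collected."""
    images, errors = [], []
    for p in index.paths:
        try:
            with Image.open(p) as im:
                im = im.convert("RGB")
                if size is not None:
                    im = im.resize((size, size), Image.BILINEAR)
                images.append(np.asarray(im))
        except Exception as exc:  # noqa: BLE001 - report per-file failures
            errors.append(f"{p}: {exc}")
    if errors:
        raise IOError("unreadable image files:\n" + "\n".join(errors))
    return np.stack(images), index.labels.copy()


def write_manifest(index: DatasetIndex, path, folds: dict | None = None):
    """CSV manifest ``path,label[,fold]`` for an indexed dataset."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        header = ["path", "label"] + (["fold"] if folds else [])
        writer.writerow(header)
        for i, (p, lab) in enumerate(zip(index.paths, index.labels)):
            row = [str(p), index.classes[lab]]
            if folds:
                row.append(folds.get(i, ""))
            writer.writerow(row)
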