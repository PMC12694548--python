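"""Image loading, augmentation, stratified splitting and k-fold assignment.

The augmentation recipe mirrors the study's field-robustness transforms and
is applied to the *training split only*: random horizontal flip (p = 0.5),
random rotation in [-15, +15] degrees (reflect padding, size preserved),
independent multiplicative brightness and contrast jitter in [0.9, 1.1],
and 3x3 Gaussian blur with probability 0.3 (sigma drawn uniform from
[0.1, 2.0]).  Validation and test images only pass through
:func:`resize_normalize`.

Split apportionment: per class, the validation and test subsets each receive
``round(ratio * n)`` images and the training subset the remainder — on the
study's per-class totals this reproduces the published 4839/606/606 split
exactly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

IMAGE_SIZE = 224
SPLITS = ("train", "val", "test")

MANIFEST_COLUMNS = ["path", "label", "class_name", "split", "fold",
                    "occlusion_band", "occlusion_frac"]


@dataclasses.dataclass(frozen=True)
class AugmentConfig:
    hflip_p: float = 0.5
    rotation_deg: float = 15.0
    brightness_range: tuple[float, float] = (0.9, 1.1)
    contrast_range: tuple[float, float] = (0.9, 1.1)
    blur_p: float = 0.3
    blur_kernel: int = 3
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)

    def __post_init__(self):
        for p in (self.hflip_p, self.blur_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rotation_deg < 0:
            raise ValueError("rotation bound must be non-negative (range is "
                             "symmetric)")


@dataclasses.dataclass(frozen=True)
class NormalizeConfig:
    """Per-channel normalization after scaling to [0, 1]."""

    mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    std: tuple[float, float, float] = (0.5, 0.5, 0.5)


IMAGENET_NORMALIZE = NormalizeConfig((0.485, 0.456, 0.406),
                                     (0.229, 0.224, 0.225))


class DatasetManifest:
    """Tabular record of every image: path, class, split, fold, occlusion."""

    def __init__(self, df: pd.DataFrame):
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    @property
    def num_classes(self) -> int:
        return int(self.df["label"].nunique())

    def per_class_counts(self) -> dict[str, int]:
        return self.df.groupby("class_name").size().to_dict()

    def subset(self, split: str) -> pd.DataFrame:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}")
        return self.df[self.df["split"] == split]

    def fold_subset(self, fold: int, role: str) -> pd.DataFrame:
        mask = self.df["fold"] == fold
        return self.df[mask if role == "test" else ~mask]

    def save(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        return cls(pd.read_csv(path, keep_default_na=False))

    @classmethod
    def from_directory(cls, root: str | Path) -> "DatasetManifest":
        """Scan a class-per-folder image directory (JPEG/PNG)."""
        root = Path(root)
        classes = sorted(p.name for p in root.iterdir() if p.is_dir())
        rows = []
        for label, cname in enumerate(classes):
            for img in sorted((root / cname).iterdir()):
                if img.suffix.lower() in (".jpg", ".jpeg", ".png"):
                    rows.append({"path": str(img), "label": label,
                                 "class_name": cname, "split": "",
                                 "fold": -1, "occlusion_band": "",
                                 "occlusion_frac": np.nan})
        if not rows:
            raise ValueError(f"no images found under {root}")
        return cls(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))


# ----------------------------------------------------------------- splits

def split_counts(n: int, ratios: tuple[float, float, float]) -> tuple[int, int, int]:
    """Per-class apportionment: val/test take round(r*n), train the rest."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    val = round(ratios[1] * n)
    test = round(ratios[2] * n)
    train = n - val - test
    if min(train, val, test) < 0:
        raise ValueError(f"class of size {n} too small for ratios {ratios}")
    return train, val, test


def stratified_split(manifest: DatasetManifest,
                     ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0) -> DatasetManifest:
    """Assign train/val/test per class; deterministic for a given seed."""
    rng = np.random.default_rng(seed)
    df = manifest.df.copy()
    df["split"] = ""
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        if len(idx) < 10:
            raise ValueError(f"class {label} has fewer than 10 images")
        rng.shuffle(idx)
        n_train, n_val, n_test = split_counts(len(idx), ratios)
        df.loc[idx[:n_train], "split"] = "train"
        df.loc[idx[n_train:n_train + n_val], "split"] = "val"
        df.loc[idx[n_train + n_val:], "split"] = "test"
    return DatasetManifest(df)


def make_folds(manifest: DatasetManifest, k: int = 5,
               seed: int = 0) -> DatasetManifest:
    """Stratified k-fold ids; per-class fold sizes differ by at most one."""
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    df = manifest.df.copy()
    df["fold"] = -1
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        if len(idx) < k:
            raise ValueError(f"class {label} smaller than k={k}")
        rng.shuffle(idx)
        df.loc[idx, "fold"] = np.arange(len(idx)) % k
    return DatasetManifest(df)


# ------------------------------------------------------------ image ops

def load_image(path: str | Path) -> np.ndarray:
    """RGB image as float32 HWC in [0, 1]."""
    with Image.open(path) as im:
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.float32) / 255.0


def augment(image: np.ndarray, config: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Training-time augmentation on a float HWC RGB image in [0, 1]."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("augment expects an RGB HWC image")
    out = image
    if rng.random() < config.hflip_p:
        out = out[:, ::-1, :]
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    if angle != 0.0:
        out = ndimage.rotate(out, angle, axes=(0, 1), reshape=False,
                             mode="reflect", order=1)
    b = rng.uniform(*config.brightness_range)
    c = rng.uniform(*config.contrast_range)
    out = out * b
    m = out.mean(axis=(0, 1), keepdims=True)
    out = (out - m) * c + m
    if rng.random() < config.blur_p:
        sigma = rng.uniform(*config.blur_sigma_range)
        radius = config.blur_kernel // 2
        out = ndimage.gaussian_filter(
            out, sigma=(sigma, sigma, 0.0), truncate=radius / sigma)
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def resize_normalize(image: np.ndarray, size: int = IMAGE_SIZE,
                     normalize: NormalizeConfig = NormalizeConfig()
                     ) -> np.ndarray:
    """Bilinear resize to size x size, then per-channel normalize -> CHW."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("resize_normalize expects an RGB HWC image")
    if image.shape[:2] != (size, size):
        im = Image.fromarray(
            (np.clip(image, 0, 1) * 255.0 + 0.5).astype(np.uint8))
        image = np.asarray(im.resize((size, size), Image.BILINEAR),
                           dtype=np.float32) / 255.0
    mean = np.asarray(normalize.mean, dtype=np.float32)
    std = np.asarray(normalize.std, dtype=np.float32)
    chw = ((image - mean) / std).transpose(2, 0, 1)
    return np.ascontiguousarray(chw, dtype=np.float32)
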