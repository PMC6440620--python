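"""Dataset indexing, preprocessing, augmentation and a synthetic generator.

The on-disk layout mirrors the community convention for breast-tumor
histology collections: ``root/<class>/<subtype>/<patient>/<mag>X/`` with
filenames ``SOB_<B|M>_<subtype>-<patient>-<magnification>-<index>.png``.
Eight subtypes map deterministically onto the two tumor classes:

    benign    : A (adenosis), F (fibroadenoma), TA (tubular adenoma),
                PT (phyllodes tumor)
    malignant : DC (ductal), LC (lobular), MC (mucinous), PC (papillary
                carcinoma)

``generate_synthetic_breakhis`` writes a seeded stand-in dataset with the
same layout and census whose two classes differ in texture statistics
(benign: smooth low-frequency blobs at low contrast; malignant: dense
high-frequency speckle at high contrast), so that a small CNN can learn
to separate them.
"""

from __future__ import annotations

import os
import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "CLASSES",
    "SUBTYPES",
    "BENIGN_SUBTYPES",
    "MALIGNANT_SUBTYPES",
    "MAGNIFICATIONS",
    "DEFAULT_CENSUS",
    "subtype_class",
    "ImageRecord",
    "DatasetIndex",
    "SyntheticSpec",
    "generate_synthetic_breakhis",
    "scan_breakhis",
    "split",
    "ChannelStats",
    "load_image",
    "resize_image",
    "preprocess",
    "shift_image",
    "hflip",
    "augment",
    "load_arrays",
]

CLASSES: Tuple[str, str] = ("benign", "malignant")
BENIGN_SUBTYPES: Tuple[str, ...] = ("A", "F", "TA", "PT")
MALIGNANT_SUBTYPES: Tuple[str, ...] = ("DC", "LC", "MC", "PC")
SUBTYPES: Tuple[str, ...] = BENIGN_SUBTYPES + MALIGNANT_SUBTYPES
MAGNIFICATIONS: Tuple[int, ...] = (40, 100, 200, 400)

# Per-subtype, per-magnification image counts of the reference census.
DEFAULT_CENSUS: Dict[str, Dict[int, int]] = {
    "A": {40: 114, 100: 113, 200: 111, 400: 106},
    "F": {40: 253, 100: 260, 200: 264, 400: 237},
    "TA": {40: 109, 100: 121, 200: 108, 400: 115},
    "PT": {40: 149, 100: 150, 200: 140, 400: 130},
    "DC": {40: 864, 100: 903, 200: 896, 400: 788},
    "LC": {40: 156, 100: 170, 200: 163, 400: 137},
    "MC": {40: 205, 100: 222, 200: 196, 400: 169},
    "PC": {40: 145, 100: 142, 200: 135, 400: 138},
}


def subtype_class(subtype: str) -> str:
    if subtype in BENIGN_SUBTYPES:
        return "benign"
    if subtype in MALIGNANT_SUBTYPES:
        return "malignant"
    raise ValueError(f"unknown subtype {subtype!r}")


@dataclass(frozen=True)
class ImageRecord:
    path: str
    magnification: int
    subtype: str

    def __post_init__(self) -> None:
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"unknown magnification {self.magnification}")
        subtype_class(self.subtype)  # validates

    @property
    def class_label(self) -> str:
        return subtype_class(self.subtype)


@dataclass
class DatasetIndex:
    records: List[ImageRecord]

    def __len__(self) -> int:
        return len(self.records)

    def census(self) -> Dict[Tuple[str, int], int]:
        """Counts per (subtype, magnification)."""
        return dict(Counter((r.subtype, r.magnification) for r in self.records))

    def count_by_class(self) -> Dict[str, int]:
        return dict(Counter(r.class_label for r in self.records))

    def count_by_magnification(self) -> Dict[int, int]:
        return dict(Counter(r.magnification for r in self.records))

    def filter(self, magnification: Optional[int] = None,
               subtype: Optional[str] = None) -> "DatasetIndex":
        recs = [
            r for r in self.records
            if (magnification is None or r.magnification == magnification)
            and (subtype is None or r.subtype == subtype)
        ]
        return DatasetIndex(recs)

    def labels(self, level: str = "binary") -> np.ndarray:
        """Integer labels: binary (0=benign, 1=malignant) or subtype (0..7)."""
        if level == "binary":
            return np.array([CLASSES.index(r.class_label) for r in self.records])
        if level == "subtype":
            return np.array([SUBTYPES.index(r.subtype) for r in self.records])
        raise ValueError(f"unknown label level {level!r}")

    def to_csv(self, path, split_column: Optional[Sequence[str]] = None) -> None:
        import pandas as pd

        frame = pd.DataFrame(
            {
                "path": [r.path for r in self.records],
                "magnification": [r.magnification for r in self.records],
                "class": [r.class_label for r in self.records],
                "subtype": [r.subtype for r in self.records],
            }
        )
        if split_column is not None:
            frame["split"] = list(split_column)
        frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Synthetic generator
# ---------------------------------------------------------------------------

# Base colors roughly evoking hematoxylin/eosin staining; the class signal
# lives in the texture statistics, not the tint.
_CLASS_COLOR = {"benign": (0.85, 0.72, 0.80), "malignant": (0.64, 0.52, 0.74)}
_CLASS_SIGMA = {"benign": 6.0, "malignant": 0.8}
_CLASS_CONTRAST = {"benign": 0.08, "malignant": 0.30}


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic dataset generator."""

    census: Mapping[str, Mapping[int, int]] = field(
        default_factory=lambda: {s: dict(m) for s, m in DEFAULT_CENSUS.items()}
    )
    image_size: int = 64
    seed: int = 0
    variance_margin: float = 0.01  # guaranteed gap in mean pixel variance

    def __post_init__(self) -> None:
        for subtype, row in self.census.items():
            subtype_class(subtype)
            for mag, count in row.items():
                if mag not in MAGNIFICATIONS:
                    raise ValueError(f"unknown magnification {mag}")
                if count < 0:
                    raise ValueError("census counts must be >= 0")
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")

    def total(self) -> int:
        return sum(c for row in self.census.values() for c in row.values())


def _render_image(subtype: str, magnification: int, index: int,
                  size: int, seed: int) -> np.ndarray:
    """One synthetic tissue image as (H, W, 3) uint8, fully seeded."""
    sub_idx = SUBTYPES.index(subtype)
    rng = np.random.default_rng([seed, sub_idx, magnification, index])
    label = subtype_class(subtype)
    # feature scale grows with optical magnification
    mag_scale = (magnification / 100.0) ** 0.3
    sigma = _CLASS_SIGMA[label] * mag_scale * size / 64.0
    contrast = _CLASS_CONTRAST[label]
    field_ = gaussian_filter(rng.standard_normal((size, size)), sigma=sigma, mode="wrap")
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    # subtype-specific blob overlay: density and scale vary with the
    # subtype's position within its class
    within = sub_idx % 4
    blob_sigma = (2.0 + within) * mag_scale * size / 64.0
    blobs = gaussian_filter(rng.standard_normal((size, size)), sigma=blob_sigma, mode="wrap")
    bsd = blobs.std()
    if bsd > 0:
        blobs = blobs / bsd
    density = 0.8 + 0.4 * within
    mask = (blobs > density).astype(float)
    base = np.array(_CLASS_COLOR[label])
    img = base[None, None, :] + contrast * field_[:, :, None]
    img = img - 0.12 * mask[:, :, None]
    img += 0.02 * rng.standard_normal((size, size, 3))
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def generate_synthetic_breakhis(spec: SyntheticSpec, out_dir) -> DatasetIndex:
    """Write a seeded synthetic dataset in the standard layout.

    Deterministic: equal specs produce byte-identical file trees.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    records: List[ImageRecord] = []
    for subtype in SUBTYPES:
        row = spec.census.get(subtype, {})
        label = subtype_class(subtype)
        code = "B" if label == "benign" else "M"
        patient = f"{SUBTYPES.index(subtype) + 1:04d}"
        for mag in MAGNIFICATIONS:
            count = int(row.get(mag, 0))
            if count == 0:
                continue
            mag_dir = out_dir / label / subtype / f"SOB_{code}_{subtype}_{patient}" / f"{mag}X"
            mag_dir.mkdir(parents=True, exist_ok=True)
            for idx in range(1, count + 1):
                name = f"SOB_{code}_{subtype}-{patient}-{mag}-{idx:03d}.png"
                path = mag_dir / name
                arr = _render_image(subtype, mag, idx, spec.image_size, spec.seed)
                Image.fromarray(arr, mode="RGB").save(path)
                records.append(ImageRecord(str(path), mag, subtype))
    return DatasetIndex(records)


# ---------------------------------------------------------------------------
# Scanner
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(
    r"^SOB_(?P<code>[BM])_(?P<subtype>[A-Z]+)-(?P<patient>[\w.]+)-(?P<mag>\d+)-(?P<idx>\d+)\.png$"
)


class ScanError(ValueError):
    def __init__(self, message: str, bad_files: Sequence[str] = ()) -> None:
        super().__init__(message)
        self.bad_files = list(bad_files)


def scan_breakhis(root) -> DatasetIndex:
    """Index every PNG under ``root`` by parsing the standard filenames."""
    root = Path(root)
    if not root.is_dir():
        raise ScanError(f"{root} is not a directory")
    records: List[ImageRecord] = []
    bad: List[str] = []
    for dirpath, _dirnames, filenames in os.walk(root):
        for fname in sorted(filenames):
            if not fname.lower().endswith(".png"):
                continue
            m = _NAME_RE.match(fname)
            if m is None:
                bad.append(os.path.join(dirpath, fname))
                continue
            subtype = m.group("subtype")
            mag = int(m.group("mag"))
            try:
                expected = "B" if subtype_class(subtype) == "benign" else "M"
            except ValueError:
                bad.append(os.path.join(dirpath, fname))
                continue
            if m.group("code") != expected or mag not in MAGNIFICATIONS:
                bad.append(os.path.join(dirpath, fname))
                continue
            records.append(ImageRecord(os.path.join(dirpath, fname), mag, subtype))
    if bad:
        raise ScanError(
            f"{len(bad)} file(s) with unparseable names, e.g. {bad[0]}", bad_files=bad
        )
    if not records:
        raise ScanError(f"no images found under {root}")
    return DatasetIndex(records)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------


def split(
    index: DatasetIndex,
    train_fraction: float,
    seed: int = 0,
    level: str = "binary",
) -> Tuple[DatasetIndex, DatasetIndex]:
    """Disjoint, exhaustive train/test partition.

    Stratified by label (class for ``binary``, subtype for ``subtype``)
    within each magnification; reproducible given the seed.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    if level not in ("binary", "subtype"):
        raise ValueError(f"unknown level {level!r}")
    rng = np.random.default_rng(seed)
    strata: Dict[Tuple[int, str], List[ImageRecord]] = {}
    for r in index.records:
        key = (r.magnification, r.class_label if level == "binary" else r.subtype)
        strata.setdefault(key, []).append(r)
    train: List[ImageRecord] = []
    test: List[ImageRecord] = []
    for key in sorted(strata):
        recs = strata[key]
        n = len(recs)
        if n < 2:
            raise ValueError(f"stratum {key} has fewer than 2 images; cannot split")
        n_train = int(round(n * train_fraction))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        train.extend(recs[i] for i in order[:n_train])
        test.extend(recs[i] for i in order[n_train:])
    return DatasetIndex(train), DatasetIndex(test)


# ---------------------------------------------------------------------------
# Preprocessing and augmentation
# ---------------------------------------------------------------------------


def load_image(path) -> np.ndarray:
    """Load an RGB PNG as a (3, H, W) float array in [0, 1]."""
    with Image.open(path) as im:
        if im.mode != "RGB":
            raise ValueError(f"{path}: expected an RGB image, got mode {im.mode}")
        arr = np.asarray(im, dtype=np.float64) / 255.0
    return arr.transpose(2, 0, 1)


def resize_image(image: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of a (3, H, W) array to (3, size, size)."""
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a (3, H, W) RGB array")
    if image.shape[1] == size and image.shape[2] == size:
        return image.copy()
    hwc = np.clip(image, 0.0, 1.0).transpose(1, 2, 0)
    im = Image.fromarray((hwc * 255.0).round().astype(np.uint8), mode="RGB")
    im = im.resize((size, size), Image.BILINEAR)
    return (np.asarray(im, dtype=np.float64) / 255.0).transpose(2, 0, 1)


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel mean and standard deviation (std floored at 1e-6).

    Must be computed on the training split only and then applied to every
    split.
    """

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def from_arrays(cls, images: Sequence[np.ndarray]) -> "ChannelStats":
        stack = np.stack(list(images))  # (N, 3, H, W)
        mean = stack.mean(axis=(0, 2, 3))
        std = np.maximum(stack.std(axis=(0, 2, 3)), 1e-6)
        return cls(mean=mean, std=std)


def preprocess(image: np.ndarray, stats: ChannelStats, size: Optional[int] = None) -> np.ndarray:
    """Optionally resize, then standardize channels with training-set stats."""
    if image.ndim != 3 or image.shape[0] != 3:
        raise ValueError("expected a (3, H, W) RGB array")
    if size is not None:
        image = resize_image(image, size)
    return (image - stats.mean[:, None, None]) / stats.std[:, None, None]


def shift_image(image: np.ndarray, dy: int, dx: int, fill: float = 0.0) -> np.ndarray:
    """Translate a (C, H, W) array by (dy, dx) pixels with constant fill."""
    c, h, w = image.shape
    out = np.full_like(image, fill)
    ys_src = slice(max(0, -dy), min(h, h - dy))
    ys_dst = slice(max(0, dy), min(h, h + dy))
    xs_src = slice(max(0, -dx), min(w, w - dx))
    xs_dst = slice(max(0, dx), min(w, w + dx))
    out[:, ys_dst, xs_dst] = image[:, ys_src, xs_src]
    return out


def hflip(image: np.ndarray) -> np.ndarray:
    return image[:, :, ::-1].copy()


def augment(
    image: np.ndarray,
    rng: np.random.Generator,
    shift_fraction: float = 0.125,
    fill: float = 0.0,
) -> np.ndarray:
    """Random translation up to +/- shift_fraction of each dimension
    (constant fill) and a horizontal flip with probability 1/2.

    Draw order: dy, dx, then the flip coin.
    """
    c, h, w = image.shape
    max_dy = int(h * shift_fraction)
    max_dx = int(w * shift_fraction)
    dy = int(rng.integers(-max_dy, max_dy + 1)) if max_dy else 0
    dx = int(rng.integers(-max_dx, max_dx + 1)) if max_dx else 0
    out = shift_image(image, dy, dx, fill=fill)
    if rng.random() < 0.5:
        out = hflip(out)
    return out


def load_arrays(
    index: DatasetIndex,
    size: int,
    stats: Optional[ChannelStats] = None,
    level: str = "binary",
) -> Tuple[np.ndarray, np.ndarray]:
    """Materialize an index as (X, y) arrays, optionally standardized."""
    images = [resize_image(load_image(r.path), size) for r in index.records]
    X = np.stack(images) if images else np.zeros((0, 3, size, size))
    if stats is not None:
        X = (X - stats.mean[None, :, None, None]) / stats.std[None, :, None, None]
    return X, index.labels(level)
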