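"""Dataset loading, stratified splitting and augmentation.

The on-disk layout is the usual class-per-subdirectory arrangement of
PNG/JPEG files.  Images are converted to grayscale (channel average for
RGB sources), resized to the working resolution with bilinear
interpolation and rescaled to [0, 1].

The 80:10:10 split is stratified per class with a fixed rounding rule:
``train = round_half_up(0.8 N)``, ``test = round_half_up(0.1 N)`` and
validation takes the remainder.  Applied to the nine class totals of the
gallbladder ultrasound corpus this reproduces the published per-class
train/test/validation table exactly (1,069 test and 1,069 validation
images overall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import AffineTransform, resize, warp

from . import CLASS_NAMES

__all__ = [
    "ImageRecord",
    "DatasetSplit",
    "LoadReport",
    "AugmentationConfig",
    "load_dataset",
    "shuffle_records",
    "stratified_split",
    "augment",
]

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg"}


@dataclass
class ImageRecord:
    """A labeled grayscale image with pixels in [0, 1]."""

    path: Path | None
    label: str
    pixels: np.ndarray

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grayscale grid")


@dataclass
class LoadReport:
    """Bookkeeping for a dataset load: per-class counts and skipped files."""

    class_counts: dict[str, int] = field(default_factory=dict)
    skipped: list[tuple[Path, str]] = field(default_factory=list)

    @property
    def empty_classes(self) -> list[str]:
        return [name for name, count in self.class_counts.items() if count == 0]


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test record lists plus the per-class
    count table (rows ordered like ``class_names``, columns
    train/test/validation)."""

    train: list[ImageRecord]
    validation: list[ImageRecord]
    test: list[ImageRecord]
    class_counts: dict[str, tuple[int, int, int]]
    seed: int

    def __post_init__(self):
        paths = [r.path for part in (self.train, self.validation, self.test)
                 for r in part if r.path is not None]
        if len(paths) != len(set(paths)):
            raise ValueError("split parts are not disjoint by source path")


def _to_grayscale(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)  # luminance by channel averaging
    return arr


def load_image(path: str | Path, size: int = 128) -> np.ndarray:
    """Read one image file -> (size, size) float32 grid in [0, 1]."""
    with Image.open(path) as img:
        arr = np.asarray(img, dtype=np.float32)
    arr = _to_grayscale(arr) / 255.0
    if arr.shape != (size, size):
        arr = resize(arr, (size, size), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(arr, 0.0, 1.0).astype(np.float32)


def load_dataset(root: str | Path, class_names=CLASS_NAMES, size: int = 128,
                 report: LoadReport | None = None) -> list[ImageRecord]:
    """Read a class-per-subdirectory image tree into records.

    Records are ordered deterministically (class order, then lexicographic
    path).  Unreadable files are skipped with a warning and noted in
    ``report``; a missing class directory is an error.
    """
    root = Path(root)
    missing = [name for name in class_names if not (root / name).is_dir()]
    if missing:
        raise FileNotFoundError(
            f"missing class directories under {root}: {', '.join(missing)}")
    if report is None:
        report = LoadReport()
    records: list[ImageRecord] = []
    for name in class_names:
        count = 0
        files = sorted(p for p in (root / name).iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        for path in files:
            try:
                pixels = load_image(path, size=size)
            except Exception as exc:  # unreadable file: skip, keep going
                warnings.warn(f"skipping unreadable image {path}: {exc}")
                report.skipped.append((path, str(exc)))
                continue
            records.append(ImageRecord(path=path, label=name, pixels=pixels))
            count += 1
        report.class_counts[name] = count
    for name in report.empty_classes:
        warnings.warn(f"class {name!r} has no readable images")
    return records


def shuffle_records(records: list[ImageRecord], seed: int) -> list[ImageRecord]:
    """One seeded uniform permutation (a composition of uniform shuffles is
    itself a uniform shuffle, so this stands in for repeated shuffling)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    return [records[i] for i in order]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(records: list[ImageRecord],
                     fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                     seed: int = 0,
                     class_names=None) -> DatasetSplit:
    """Stratified train/test/validation split.

    Per class of size N: ``train = round_half_up(f_train * N)``,
    ``test = round_half_up(f_test * N)``, validation takes the remainder.
    Membership is chosen by a seeded permutation within each class after
    sorting records by path, so the split depends only on the record set
    and the seed, not on input order.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    f_train, f_test, _ = fractions
    by_class: dict[str, list[ImageRecord]] = {}
    for rec in records:
        by_class.setdefault(rec.label, []).append(rec)
    if class_names is None:
        class_names = [n for n in CLASS_NAMES if n in by_class] or sorted(by_class)
    unknown = set(by_class) - set(class_names)
    if unknown:
        raise ValueError(f"records with labels outside the class set: {unknown}")
    small = {n: len(by_class.get(n, [])) for n in class_names
             if len(by_class.get(n, [])) < 3}
    if small:
        raise ValueError(f"classes need at least 3 records, got {small}")

    rng = np.random.default_rng(seed)
    train, validation, test = [], [], []
    counts: dict[str, tuple[int, int, int]] = {}
    for name in class_names:
        group = sorted(by_class[name],
                       key=lambda r: str(r.path) if r.path is not None else "")
        n = len(group)
        n_train = _round_half_up(f_train * n)
        n_test = _round_half_up(f_test * n)
        n_val = n - n_train - n_test
        order = rng.permutation(n)
        picked = [group[i] for i in order]
        train.extend(picked[:n_train])
        test.extend(picked[n_train:n_train + n_test])
        validation.extend(picked[n_train + n_test:])
        counts[name] = (n_train, n_test, n_val)
    return DatasetSplit(train=train, validation=validation, test=test,
                        class_counts=counts, seed=seed)


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-time augmentation: random shear, random zoom, random
    horizontal flip.  ``rescale`` documents the 1/255 intensity scaling
    applied at load time; shear_range is the affine shear coefficient
    bound and zoom_range the relative scale bound."""

    rescale: float = 1.0 / 255.0
    zoom_range: float = 0.2
    shear_range: float = 0.2
    horizontal_flip: bool = True

    def __post_init__(self):
        if self.zoom_range < 0 or self.shear_range < 0:
            raise ValueError("zoom and shear ranges must be nonnegative")


def augment(image: np.ndarray, config: AugmentationConfig,
            rng: np.random.Generator, *, force_flip: bool | None = None) -> np.ndarray:
    """Apply, in order: random shear in [-s, s], random zoom in
    [1-z, 1+z], horizontal flip with probability 0.5 — all about the image
    center, bilinear with reflect padding, clipped to [0, 1].

    ``force_flip`` overrides the flip coin for testing.
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape
    shear = rng.uniform(-config.shear_range, config.shear_range) \
        if config.shear_range > 0 else 0.0
    zoom = rng.uniform(1.0 - config.zoom_range, 1.0 + config.zoom_range) \
        if config.zoom_range > 0 else 1.0
    out = image
    if shear != 0.0 or zoom != 1.0:
        # x' = A (x - c) + c with A = zoom * [[1, shear], [0, 1]]
        a = np.array([[zoom, zoom * shear, 0.0],
                      [0.0, zoom, 0.0],
                      [0.0, 0.0, 1.0]])
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        a[:2, 2] = c - a[:2, :2] @ c
        tform = AffineTransform(matrix=np.linalg.inv(a))
        out = warp(out, tform, order=1, mode="reflect", preserve_range=True)
    if config.horizontal_flip:
        flip = force_flip if force_flip is not None else bool(rng.random() < 0.5)
        if flip:
            out = out[:, ::-1]
    return np.clip(out, 0.0, 1.0).astype(np.float32)
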