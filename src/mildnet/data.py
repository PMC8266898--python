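"""Image/mask I/O, preprocessing, patch extraction, splitting and augmentation.

The protocol implemented here: images are min-max scaled to [0, 1] and
resized to 256x256 with bilinear interpolation (masks nearest-neighbor,
then re-binarized); small datasets are enlarged by cutting 256x256
patches from reflect-padded (16 px) images on a non-overlapping grid;
splitting happens at whole-image level BEFORE patching — 30% (rounded to
the nearest integer) held out as the test set, the rest divided into 5
cross-validation folds as equally as possible.

Augmentation pairs every geometric transform between image and mask
(rotations from {0, 60, 120, 180, 270} degrees, horizontal/vertical
flips, random scale +-10%, shear in [-45, 45] degrees, elastic
deformation) and applies photometric transforms (color jitter, Gaussian
blur, Gaussian noise) to the image only; masks are re-binarized after
any interpolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import AffineTransform, resize, warp


class DataError(ValueError):
    pass


# ----------------------------------------------------------------------
# samples and I/O

@dataclass
class ImageSample:
    """One image/mask pair: image (H, W, C) in [0, 1], mask (H, W) in {0, 1}."""

    id: str
    image: np.ndarray
    mask: np.ndarray
    original_size: tuple[int, int]

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=float)
        if self.image.ndim == 2:
            self.image = self.image[:, :, None]
        self.mask = np.asarray(self.mask)
        if self.image.shape[:2] != self.mask.shape:
            raise DataError(
                f"sample {self.id!r}: image {self.image.shape[:2]} and mask "
                f"{self.mask.shape} spatial dims differ"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError(f"sample {self.id!r}: mask is not binary")
        self.mask = self.mask.astype(np.uint8)


def _min_max_scale(img: np.ndarray) -> np.ndarray:
    img = img.astype(float)
    lo, hi = img.min(), img.max()
    if hi - lo == 0:
        return np.zeros_like(img)  # zero-range images map to 0
    return (img - lo) / (hi - lo)


def load_sample(image_path, mask_path, sample_id: str | None = None) -> ImageSample:
    """Read an image/mask pair from PNG/TIFF/JPEG files."""
    image_path, mask_path = Path(image_path), Path(mask_path)
    try:
        img = np.asarray(iio.imread(image_path))
    except OSError as exc:
        raise DataError(f"cannot read image {image_path}: {exc}") from exc
    try:
        msk = np.asarray(iio.imread(mask_path))
    except OSError as exc:
        raise DataError(f"cannot read mask {mask_path}: {exc}") from exc
    if msk.ndim == 3:
        msk = msk[..., 0]
    if img.shape[:2] != msk.shape:
        raise DataError(
            f"image {image_path.name} {img.shape[:2]} and mask {mask_path.name} "
            f"{msk.shape} have different spatial dims"
        )
    sid = sample_id if sample_id is not None else image_path.stem
    return ImageSample(
        id=sid,
        image=_min_max_scale(img),
        mask=(msk.astype(float) > 0.5 * max(float(msk.max()), 1.0)).astype(np.uint8)
        if msk.dtype != bool else msk.astype(np.uint8),
        original_size=img.shape[:2],
    )


def save_sample(sample: ImageSample, image_path, mask_path) -> None:
    img8 = np.clip(np.round(sample.image * 255), 0, 255).astype(np.uint8)
    if img8.shape[2] == 1:
        img8 = img8[:, :, 0]
    iio.imwrite(Path(image_path), img8)
    iio.imwrite(Path(mask_path), (sample.mask * 255).astype(np.uint8))


def preprocess(sample: ImageSample, target: tuple[int, int] = (256, 256)) -> ImageSample:
    """Bilinear-resize the image and nearest-resize (then re-binarize) the mask."""
    th, tw = target
    if th <= 0 or tw <= 0:
        raise DataError(f"target size must be positive, got {target}")
    if sample.image.shape[:2] == (th, tw):
        return replace(sample, image=sample.image.copy(), mask=sample.mask.copy())
    img = resize(sample.image, (th, tw), order=1, mode="reflect",
                 anti_aliasing=False, preserve_range=True)
    msk = resize(sample.mask.astype(float), (th, tw), order=0, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    return replace(sample, image=np.clip(img, 0.0, 1.0),
                   mask=(msk > 0.5).astype(np.uint8))


# ----------------------------------------------------------------------
# patch extraction

def extract_patches(sample: ImageSample, patch: int = 256,
                    padding: int = 16) -> list[ImageSample]:
    """Reflect-pad by ``padding`` then tile a non-overlapping ``patch`` grid.

    Only patches fully inside the padded canvas are kept; a 512x512 image
    padded by 16 (544x544) therefore yields 4 patches of 256x256. Images
    smaller than one patch produce a single edge-padded/cropped patch.
    """
    img = np.pad(sample.image, ((padding, padding), (padding, padding), (0, 0)),
                 mode="reflect")
    msk = np.pad(sample.mask, padding, mode="reflect")
    h, w = msk.shape
    ny, nx = h // patch, w // patch
    if ny == 0 or nx == 0:
        warnings.warn(
            f"sample {sample.id!r} ({h}x{w} padded) smaller than patch {patch}; "
            "emitting one padded center patch",
            stacklevel=2,
        )
        py, px = max(patch - h, 0), max(patch - w, 0)
        pads = ((py // 2, py - py // 2), (px // 2, px - px // 2))
        img = np.pad(img, pads + ((0, 0),), mode="edge")
        msk = np.pad(msk, pads, mode="edge")
        y0 = (img.shape[0] - patch) // 2
        x0 = (img.shape[1] - patch) // 2
        return [ImageSample(f"{sample.id}_p0", img[y0:y0 + patch, x0:x0 + patch],
                            msk[y0:y0 + patch, x0:x0 + patch], (patch, patch))]
    out = []
    for iy in range(ny):
        for ix in range(nx):
            y0, x0 = iy * patch, ix * patch
            out.append(ImageSample(
                f"{sample.id}_p{iy * nx + ix}",
                img[y0:y0 + patch, x0:x0 + patch],
                msk[y0:y0 + patch, x0:x0 + patch],
                (patch, patch),
            ))
    return out


# ----------------------------------------------------------------------
# splitting

@dataclass
class SplitPlan:
    """Image-level assignment to test set and five cross-validation folds."""

    assignments: dict[str, str]  # id -> "test" | "fold_1".."fold_5"
    seed: int
    test_fraction: float = 0.3
    folds: int = 5

    @property
    def test_ids(self) -> list[str]:
        return [i for i, a in self.assignments.items() if a == "test"]

    def fold_ids(self, k: int) -> list[str]:
        return [i for i, a in self.assignments.items() if a == f"fold_{k}"]

    def train_ids(self, validation_fold: int = 5) -> list[str]:
        return [
            i for i, a in self.assignments.items()
            if a.startswith("fold_") and a != f"fold_{validation_fold}"
        ]

    def validation_ids(self, validation_fold: int = 5) -> list[str]:
        return self.fold_ids(validation_fold)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "test_fraction": self.test_fraction,
                "folds": self.folds,
                "assignments": {k: self.assignments[k] for k in sorted(self.assignments)},
            },
            indent=2,
            sort_keys=True,
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "SplitPlan":
        raw = json.loads(Path(path).read_text())
        return cls(assignments=raw["assignments"], seed=raw["seed"],
                   test_fraction=raw["test_fraction"], folds=raw["folds"])


def make_split_plan(ids, seed: int, test_fraction: float = 0.3,
                    folds: int = 5) -> SplitPlan:
    """Shuffle, hold out round(test_fraction * n) ids, split the rest into folds.

    The test count uses round-half-up; remaining training ids are divided
    into folds whose sizes differ by at most one (earlier folds take the
    remainder). Assignment is at whole-image level, before any patching.
    """
    ids = list(ids)
    if len(ids) < 10:
        raise DataError(f"need at least 10 ids to split, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise DataError("duplicate ids in split input")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    n_test = int(np.floor(test_fraction * len(ids) + 0.5))
    assignments: dict[str, str] = {i: "test" for i in order[:n_test]}
    train = order[n_test:]
    base, extra = divmod(len(train), folds)
    pos = 0
    for k in range(folds):
        size = base + (1 if k < extra else 0)
        for i in train[pos:pos + size]:
            assignments[i] = f"fold_{k + 1}"
        pos += size
    return SplitPlan(assignments=assignments, seed=seed,
                     test_fraction=test_fraction, folds=folds)


# ----------------------------------------------------------------------
# manifests

def write_manifest(rows, path) -> None:
    """rows: iterable of (id, image_path, mask_path); written as CSV."""
    pd.DataFrame(rows, columns=["id", "image_path", "mask_path"]).to_csv(
        Path(path), index=False)


def load_manifest(path, root=None) -> list[ImageSample]:
    path = Path(path)
    root = Path(root) if root is not None else path.parent
    df = pd.read_csv(path)
    return [
        load_sample(root / row.image_path, root / row.mask_path, sample_id=str(row.id))
        for row in df.itertuples()
    ]


# ----------------------------------------------------------------------
# augmentation

@dataclass(frozen=True)
class AugmentationConfig:
    rotations: tuple[float, ...] = (0, 60, 120, 180, 270)
    horizontal_flip: bool = True
    vertical_flip: bool = True
    scale_limit: float = 0.1
    shear_limit: tuple[float, float] = (-45.0, 45.0)
    elastic: bool = True
    elastic_alpha: float = 34.0
    elastic_sigma: float = 4.0
    color_jitter: tuple[float, float, float, float] = (0.2, 0.2, 0.2, 0.2)
    gaussian_blur_limit: tuple[int, int] = (3, 7)
    gauss_noise_var: tuple[float, float] = (10.0, 50.0)
    probability: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise DataError(f"probability must be in [0, 1], got {self.probability}")
        if self.scale_limit < 0:
            raise DataError(f"scale_limit must be >= 0, got {self.scale_limit}")
        lo, hi = self.shear_limit
        if lo > hi or lo < -90 or hi > 90:
            raise DataError(f"shear_limit must satisfy -90 <= lo <= hi <= 90, got {self.shear_limit}")
        if any(c < 0 for c in self.color_jitter):
            raise DataError("color_jitter factors must be >= 0")
        if self.gauss_noise_var[0] < 0 or self.gauss_noise_var[0] > self.gauss_noise_var[1]:
            raise DataError(f"invalid gauss_noise_var {self.gauss_noise_var}")
        if self.gaussian_blur_limit[0] < 3 or self.gaussian_blur_limit[0] > self.gaussian_blur_limit[1]:
            raise DataError(f"invalid gaussian_blur_limit {self.gaussian_blur_limit}")

    @classmethod
    def identity(cls) -> "AugmentationConfig":
        """A configuration under which the augmenter is a no-op."""
        return cls(rotations=(0,), horizontal_flip=False, vertical_flip=False,
                   scale_limit=0.0, shear_limit=(0.0, 0.0), elastic=False,
                   color_jitter=(0.0, 0.0, 0.0, 0.0), probability=0.0)


def _rot90k(arr: np.ndarray, k: int) -> np.ndarray:
    return np.rot90(arr, k, axes=(0, 1))


class Augmenter:
    """Deterministic-under-seed paired image/mask augmentation."""

    def __init__(self, config: AugmentationConfig, seed: int):
        self.config = config
        self.rng = np.random.default_rng(seed)

    def __call__(self, sample: ImageSample) -> ImageSample:
        cfg, rng = self.config, self.rng
        img = sample.image.astype(float)
        msk = sample.mask.astype(float)

        angle = float(rng.choice(np.asarray(cfg.rotations, dtype=float)))
        if angle % 90 == 0:
            k = int(angle // 90) % 4
            if k:
                img, msk = _rot90k(img, k), _rot90k(msk, k)
            angle = 0.0
        if cfg.horizontal_flip and rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]
        if cfg.vertical_flip and rng.random() < 0.5:
            img, msk = img[::-1], msk[::-1]

        scale = 1.0 + (rng.uniform(-cfg.scale_limit, cfg.scale_limit)
                       if cfg.scale_limit > 0 and rng.random() < cfg.probability else 0.0)
        shear = (np.deg2rad(rng.uniform(*cfg.shear_limit))
                 if cfg.shear_limit != (0.0, 0.0) and rng.random() < cfg.probability
                 else 0.0)
        if angle != 0.0 or scale != 1.0 or shear != 0.0:
            h, w = msk.shape
            center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
            tf = (AffineTransform(translation=-center)
                  + AffineTransform(rotation=np.deg2rad(angle), scale=scale, shear=shear)
                  + AffineTransform(translation=center))
            img = warp(img, tf.inverse, order=1, mode="reflect", preserve_range=True)
            msk = warp(msk, tf.inverse, order=0, mode="reflect", preserve_range=True)

        if cfg.elastic and rng.random() < cfg.probability:
            img, msk = self._elastic(img, msk, rng)

        img = self._photometric(img, rng)
        return ImageSample(sample.id, np.clip(img, 0.0, 1.0),
                           (msk > 0.5).astype(np.uint8), sample.original_size)

    def _elastic(self, img, msk, rng):
        cfg = self.config
        h, w = msk.shape
        dy = gaussian_filter(rng.uniform(-1, 1, (h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        dx = gaussian_filter(rng.uniform(-1, 1, (h, w)), cfg.elastic_sigma) * cfg.elastic_alpha
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = [yy + dy, xx + dx]
        img = np.stack(
            [map_coordinates(img[:, :, c], coords, order=1, mode="reflect")
             for c in range(img.shape[2])], axis=-1)
        msk = map_coordinates(msk, coords, order=0, mode="reflect")
        return img, msk

    def _photometric(self, img, rng):
        cfg = self.config
        brightness, contrast, saturation, hue = cfg.color_jitter
        if brightness > 0 and rng.random() < cfg.probability:
            img = img * (1.0 + rng.uniform(-brightness, brightness))
        if contrast > 0 and rng.random() < cfg.probability:
            mean = img.mean()
            img = (img - mean) * (1.0 + rng.uniform(-contrast, contrast)) + mean
        if img.shape[2] == 3 and (saturation > 0 or hue > 0) and rng.random() < cfg.probability:
            hsv = rgb2hsv(np.clip(img, 0, 1))
            if saturation > 0:
                hsv[:, :, 1] = np.clip(hsv[:, :, 1] * (1.0 + rng.uniform(-saturation, saturation)), 0, 1)
            if hue > 0:
                hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-hue, hue)) % 1.0
            img = hsv2rgb(hsv)
        if cfg.gaussian_blur_limit is not None and rng.random() < cfg.probability:
            lo, hi = cfg.gaussian_blur_limit
            ksize = int(rng.integers(lo // 2, hi // 2 + 1)) * 2 + 1
            sigma = 0.3 * ((ksize - 1) * 0.5 - 1) + 0.8  # standard kernel->sigma rule
            img = np.stack(
                [gaussian_filter(img[:, :, c], sigma) for c in range(img.shape[2])],
                axis=-1)
        if cfg.gauss_noise_var is not None and rng.random() < cfg.probability:
            var = rng.uniform(*cfg.gauss_noise_var)  # variance on the 0-255 scale
            img = img + rng.normal(0.0, np.sqrt(var) / 255.0, img.shape)
        return np.clip(img, 0.0, 1.0)


def build_augmenter(config: AugmentationConfig, seed: int) -> Augmenter:
    return Augmenter(config, seed)
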