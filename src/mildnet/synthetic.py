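"""Synthetic image/mask generator covering five segmentation challenge regimes.

The generator emulates the statistical structure that makes biomedical
segmentation hard, without any real-data download:

* ``clean`` — smooth bright blobs (unions of random ellipses) on a dark
  background at a configurable contrast, plus Gaussian pixel noise;
* ``outliers`` — the clean regime plus small bright distractor specks
  disjoint from the true foreground;
* ``obscure_boundary`` — blob contrast ramped toward zero along part of
  the object boundary (low-contrast edges);
* ``inconsistent_foreground`` — at least 25% of the object's area takes
  its texture from the background distribution;
* ``majority_class`` — a dominant-foreground canvas crossed by thin
  background curves (membrane-map style), so foreground fraction > 0.5.

Every sample is deterministic given (seed, index).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.draw import ellipse as draw_ellipse

from .data import ImageSample, write_manifest

REGIMES = ("clean", "outliers", "obscure_boundary", "inconsistent_foreground",
           "majority_class")

_BG_LEVEL = 0.2
_FG_SPAN = 0.6  # foreground level = _BG_LEVEL + contrast * _FG_SPAN


@dataclass(frozen=True)
class SyntheticProfile:
    regime: str = "clean"
    image_size: tuple[int, int] = (64, 64)
    n_objects: tuple[int, int] = (1, 3)
    contrast: float = 0.8
    noise_sd: float = 0.03
    distractor_count: int = 6
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError(f"contrast must lie in (0, 1], got {self.contrast}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_objects[0] < 1 or self.n_objects[0] > self.n_objects[1]:
            raise ValueError(f"invalid n_objects range {self.n_objects}")


def _blob_mask(rng: np.random.Generator, shape, n_objects) -> np.ndarray:
    """Union of random ellipses; retried until non-empty."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    n = int(rng.integers(n_objects[0], n_objects[1] + 1))
    for _ in range(n):
        cy = rng.uniform(0.25 * h, 0.75 * h)
        cx = rng.uniform(0.25 * w, 0.75 * w)
        ry = rng.uniform(0.08, 0.22) * h
        rx = rng.uniform(0.08, 0.22) * w
        rot = rng.uniform(0, np.pi)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape, rotation=rot)
        mask[rr, cc] = True
    if not mask.any():  # pragma: no cover - ellipse centers are well inside
        mask[h // 2, w // 2] = True
    return mask


def _membrane_mask(rng: np.random.Generator, shape) -> np.ndarray:
    """Foreground canvas crossed by thin random background curves."""
    h, w = shape
    fg = np.ones(shape, dtype=bool)
    n_curves = int(rng.integers(3, 6))
    for _ in range(n_curves):
        horizontal = rng.random() < 0.5
        length = w if horizontal else h
        offset = rng.uniform(0.15, 0.85) * (h if horizontal else w)
        amp = rng.uniform(0.05, 0.15) * (h if horizontal else w)
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0, 2 * np.pi)
        width = int(rng.integers(1, 3))
        t = np.arange(length)
        curve = offset + amp * np.sin(2 * np.pi * freq * t / length + phase)
        for dt in range(width):
            idx = np.clip(np.round(curve).astype(int) + dt, 0, (h if horizontal else w) - 1)
            if horizontal:
                fg[idx, t] = False
            else:
                fg[t, idx] = False
    return fg


def _half_plane(rng: np.random.Generator, shape, mask: np.ndarray) -> np.ndarray:
    """Random half-plane through the foreground centroid."""
    h, w = shape
    cy, cx = np.argwhere(mask).mean(axis=0)
    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return (np.cos(theta) * (yy - cy) + np.sin(theta) * (xx - cx)) >= 0


def generate_sample(profile: SyntheticProfile, index: int) -> ImageSample:
    """Deterministically generate one image/mask pair for ``(seed, index)``."""
    rng = np.random.default_rng((profile.seed, int(index)))
    shape = tuple(profile.image_size)
    fg_level = _BG_LEVEL + profile.contrast * _FG_SPAN

    if profile.regime == "majority_class":
        mask = _membrane_mask(rng, shape)
        img = np.where(mask, fg_level, _BG_LEVEL)
    else:
        mask = _blob_mask(rng, shape, profile.n_objects)
        img = np.full(shape, _BG_LEVEL)

        if profile.regime == "obscure_boundary":
            # ramp the boundary contrast toward zero inside a random sector
            dist_in = distance_transform_edt(mask)
            ramp_width = max(0.08 * min(shape), 2.0)
            ramp = np.clip(dist_in / ramp_width, 0.0, 1.0)
            sector = _half_plane(rng, shape, mask)
            local = np.where(sector, ramp, 1.0)
            img = img + mask * profile.contrast * _FG_SPAN * local
        else:
            img = img + mask * (fg_level - _BG_LEVEL)

        if profile.regime == "inconsistent_foreground":
            # background-textured patch covering >= 25% of the object
            sector = _half_plane(rng, shape, mask)
            patch = mask & sector
            if patch.sum() < 0.25 * mask.sum():
                patch = mask & ~sector
            img = np.where(patch, _BG_LEVEL, img)

        if profile.regime == "outliers":
            placed = 0
            guard = 0
            dist_out = distance_transform_edt(~mask)
            while placed < profile.distractor_count and guard < 200:
                guard += 1
                y = int(rng.integers(2, shape[0] - 2))
                x = int(rng.integers(2, shape[1] - 2))
                r = int(rng.integers(1, 3))
                if dist_out[y, x] <= r + 1:  # keep distractors disjoint from mask
                    continue
                rr, cc = draw_ellipse(y, x, r, r, shape=shape)
                img[rr, cc] = _BG_LEVEL + 0.95 * _FG_SPAN
                placed += 1

    if profile.noise_sd > 0:
        img = img + rng.normal(0.0, profile.noise_sd, shape)
    img = np.clip(img, 0.0, 1.0)
    return ImageSample(
        id=f"{profile.regime}_{profile.seed}_{index:04d}",
        image=img[:, :, None],
        mask=mask.astype(np.uint8),
        original_size=shape,
    )


def generate_samples(profile: SyntheticProfile, n: int) -> list[ImageSample]:
    return [generate_sample(profile, i) for i in range(n)]


def generate_dataset(profile: SyntheticProfile, n: int, out_dir) -> Path:
    """Write n image/mask PNG pairs plus a CSV manifest; return the manifest path."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    from .data import save_sample  # local import to avoid cycle at module load

    rows = []
    for i in range(n):
        sample = generate_sample(profile, i)
        img_rel = f"images/{sample.id}.png"
        msk_rel = f"masks/{sample.id}.png"
        save_sample(sample, out_dir / img_rel, out_dir / msk_rel)
        rows.append((sample.id, img_rel, msk_rel))
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
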