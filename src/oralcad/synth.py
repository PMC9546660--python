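"""Synthetic fixtures: H&E-toned tissue-like images and feature matrices.

The image generator emulates the two-class setting the pipeline targets —
normal epithelium (class 0) versus carcinoma (class 1) — at cartoon level:
an eosin-pink cytoplasmic background scattered with hematoxylin-purple
elliptical "nuclei", where the carcinoma class has denser, larger and more
pleomorphic nuclei.  A per-image global color jitter (channel gain and
offset) simulates the lab-to-lab staining variation that stain normalization
is meant to remove.  Everything is deterministic given the spec's seed.

The feature generator plants class signal in a known subset of columns
(class-shifted normals) amid pure-noise columns, standing in for extracted
deep-feature matrices with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import FeatureDataset

__all__ = [
    "ImageFixtureSpec",
    "FeatureFixtureSpec",
    "make_image_fixture",
    "make_feature_fixture",
    "write_image_fixture",
]

# default H&E-like palettes: (background RGB, nucleus RGB)
_PALETTE_NORMAL = ((236, 190, 208), (120, 90, 160))   # pale pink / soft purple
_PALETTE_TUMOR = ((228, 170, 196), (70, 45, 120))     # denser pink / dark purple


@dataclass(frozen=True)
class ImageFixtureSpec:
    """Parameters of the two-class synthetic histology image set."""

    n_per_class: int = 20
    image_size: tuple[int, int] = (64, 64)
    class0_palette: tuple = _PALETTE_NORMAL
    class1_palette: tuple = _PALETTE_TUMOR
    nuclei_count: tuple[tuple[int, int], tuple[int, int]] = ((4, 8), (14, 22))
    nucleus_radius: tuple[tuple[int, int], tuple[int, int]] = ((2, 4), (3, 7))
    color_jitter: float = 0.0  # fractional gain jitter + additive offset scale
    noise_sd: float = 4.0  # per-pixel Gaussian texture noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if min(self.image_size) < 8:
            raise ValueError("image_size too small")
        if self.color_jitter < 0:
            raise ValueError("color_jitter must be >= 0")


@dataclass(frozen=True)
class FeatureFixtureSpec:
    """Parameters of the planted-signal synthetic feature matrix."""

    n_samples: int = 200
    n_informative: int = 2
    n_noise: int = 50
    class_separation: float = 3.0
    noise_sd: float = 1.0
    label_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("n_informative must be >= 1")
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not 0 < self.label_balance < 1:
            raise ValueError("label_balance must be in (0, 1)")


def _draw_ellipse(img: np.ndarray, cy, cx, ry, rx, theta, color, rng, edge_sd=0.3):
    """Paint one filled rotated ellipse in place (soft color wobble)."""
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    wobble = rng.normal(0, edge_sd * 10, size=3)
    img[mask] = np.clip(np.asarray(color, float) + wobble, 0, 255)


def make_image_fixture(
    spec: ImageFixtureSpec,
) -> tuple[list[np.ndarray], np.ndarray, pd.DataFrame]:
    """Generate the two-class stained-tissue-like image set.

    Returns
    -------
    images : list of uint8 arrays (H, W, 3)
    labels : int array, 0 = normal-like, 1 = carcinoma-like
    manifest : DataFrame with columns path, label (paths are placeholder
        filenames until :func:`write_image_fixture` persists them)
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    images, labels, names = [], [], []
    for cls, palette, n_rng, r_rng in (
        (0, spec.class0_palette, spec.nuclei_count[0], spec.nucleus_radius[0]),
        (1, spec.class1_palette, spec.nuclei_count[1], spec.nucleus_radius[1]),
    ):
        bg, nuc = palette
        for i in range(spec.n_per_class):
            img = np.tile(np.asarray(bg, float), (h, w, 1))
            img += rng.normal(0, spec.noise_sd, size=img.shape)
            n_nuclei = rng.integers(n_rng[0], n_rng[1] + 1)
            for _ in range(n_nuclei):
                cy, cx = rng.uniform(0, h), rng.uniform(0, w)
                ry = rng.uniform(r_rng[0], r_rng[1])
                rx = ry * rng.uniform(0.6, 1.4)  # pleomorphism
                _draw_ellipse(img, cy, cx, ry, rx, rng.uniform(0, np.pi), nuc, rng)
            if spec.color_jitter > 0:
                gain = 1.0 + rng.uniform(-spec.color_jitter, spec.color_jitter, 3)
                offset = rng.uniform(
                    -spec.color_jitter * 255, spec.color_jitter * 255, 3
                )
                img = img * gain + offset
            images.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
            labels.append(cls)
            names.append(f"class{cls}_{i:03d}.png")
    manifest = pd.DataFrame({"path": names, "label": labels})
    return images, np.asarray(labels), manifest


def write_image_fixture(
    spec: ImageFixtureSpec, out_dir: str | Path
) -> tuple[Path, pd.DataFrame]:
    """Persist a generated image set as PNGs plus a manifest.csv."""
    from PIL import Image

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images, _, manifest = make_image_fixture(spec)
    for img, name in zip(images, manifest["path"]):
        Image.fromarray(img).save(out_dir / name)
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path, manifest


def make_feature_fixture(spec: FeatureFixtureSpec) -> FeatureDataset:
    """Two-class feature matrix with planted informative columns.

    Informative columns are drawn N(0, noise_sd²) for class 0 and
    N(class_separation * noise_sd, noise_sd²) for class 1; noise columns are
    class-independent N(0, noise_sd²).  Column order is shuffled;
    ``meta['informative']`` records the planted indices after shuffling.
    """
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_samples * spec.label_balance))
    n0 = spec.n_samples - n1
    y = np.concatenate([np.zeros(n0, int), np.ones(n1, int)])
    D = spec.n_informative + spec.n_noise
    X = rng.normal(0, spec.noise_sd, size=(spec.n_samples, D))
    shift = spec.class_separation * spec.noise_sd
    X[y == 1, : spec.n_informative] += shift
    order = rng.permutation(D)
    X = X[:, order]
    informative = np.sort(np.argsort(order)[: spec.n_informative])
    perm = rng.permutation(spec.n_samples)
    ds = FeatureDataset(X[perm], y[perm])
    ds.meta["informative"] = informative.tolist()
    ds.meta["spec"] = spec
    return ds
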