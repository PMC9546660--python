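"""Image resizing and deep-feature extraction through a pluggable backbone.

A *backbone* is any callable mapping a resized RGB image (uint8, H x W x 3)
to a fixed-length finite 1-D feature vector — in transfer learning this is a
pretrained CNN truncated at its penultimate (pre-classification) layer.  The
extraction code only relies on that contract, so real networks and the
deterministic stub below are interchangeable.

The four canonical backbone geometries ship as :data:`BACKBONE_SPECS`:
VGG16 224x224, AlexNet 227x227, ResNet50 224x224, InceptionV3 299x299.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .datasets import FeatureDataset

__all__ = [
    "BackboneSpec",
    "BACKBONE_SPECS",
    "resize_for_backbone",
    "extract_features",
    "StubBackbone",
    "stub_backbone",
    "standardize_features",
    "load_manifest",
    "extract_from_manifest",
]

Backbone = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class BackboneSpec:
    """Name, expected input geometry and output width of a feature extractor."""

    name: str
    input_size: tuple[int, int]  # (height, width)
    feature_dim: int

    def __post_init__(self) -> None:
        if self.input_size[0] <= 0 or self.input_size[1] <= 0:
            raise ValueError("input_size must be positive")
        if self.feature_dim < 1:
            raise ValueError("feature_dim must be >= 1")


#: Input geometries of the four standard architectures; feature_dim is the
#: canonical penultimate-layer width of each network.
BACKBONE_SPECS: dict[str, BackboneSpec] = {
    "vgg16": BackboneSpec("vgg16", (224, 224), 4096),
    "alexnet": BackboneSpec("alexnet", (227, 227), 4096),
    "resnet50": BackboneSpec("resnet50", (224, 224), 2048),
    "inceptionv3": BackboneSpec("inceptionv3", (299, 299), 2048),
    "stub": BackboneSpec("stub", (64, 64), 128),
}


def resize_for_backbone(img: np.ndarray, spec: BackboneSpec) -> np.ndarray:
    """Resize an RGB image to the backbone's input geometry (bilinear).

    Aspect ratio is not preserved; the output shape is exactly
    ``spec.input_size``.  A no-op if the image already matches.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got shape {img.shape}")
    if img.shape[0] == 0 or img.shape[1] == 0:
        raise ValueError("zero-area image")
    h, w = spec.input_size
    if img.shape[:2] == (h, w):
        return img.astype(np.uint8)
    out = _sk_resize(
        img.astype(float), (h, w), order=1, mode="edge", anti_aliasing=False
    )
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def extract_features(
    images: Sequence[np.ndarray],
    backbone: Backbone,
    labels: Sequence[int] | None = None,
    sample_ids: Sequence[str] | None = None,
) -> FeatureDataset:
    """Apply a backbone to each image; row i is the vector for image i.

    Raises
    ------
    ValueError
        If the backbone returns vectors of inconsistent length or with
        non-finite entries (contract violation).
    """
    rows = []
    dim = None
    for i, img in enumerate(images):
        vec = np.asarray(backbone(np.asarray(img)), dtype=float).ravel()
        if dim is None:
            dim = vec.size
        elif vec.size != dim:
            raise ValueError(
                f"backbone contract violation: image {i} yielded length "
                f"{vec.size}, expected {dim}"
            )
        if not np.isfinite(vec).all():
            raise ValueError(f"backbone contract violation: non-finite features at image {i}")
        rows.append(vec)
    X = np.vstack(rows)
    y = np.zeros(len(rows), dtype=int) if labels is None else np.asarray(labels)
    return FeatureDataset(X, y, sample_ids=list(sample_ids) if sample_ids else None)


class StubBackbone:
    """Deterministic feature extractor requiring no pretrained weights.

    Computes hand-crafted image statistics — per-channel 16-bin histograms
    and 4x4 block channel means — and projects them through a seeded random
    Gaussian matrix to ``spec.feature_dim`` dimensions.  The block means carry
    spatial/morphological signal (nuclei density) and the histograms carry
    color signal, so visually distinct classes stay separable in feature
    space.  Same seed + same image → identical vector.
    """

    _N_HIST = 16
    _BLOCKS = 4

    def __init__(self, spec: BackboneSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        n_raw = 3 * self._N_HIST + 3 * self._BLOCKS * self._BLOCKS
        rng = np.random.default_rng(seed)
        self._proj = rng.standard_normal((n_raw, spec.feature_dim)) / np.sqrt(n_raw)

    def _raw_stats(self, img: np.ndarray) -> np.ndarray:
        img = np.asarray(img, dtype=float)
        h, w, _ = img.shape
        feats = []
        for c in range(3):
            hist, _ = np.histogram(img[..., c], bins=self._N_HIST, range=(0, 255))
            feats.append(hist / img[..., c].size)
        hb = max(h // self._BLOCKS, 1)
        wb = max(w // self._BLOCKS, 1)
        for bi in range(self._BLOCKS):
            for bj in range(self._BLOCKS):
                block = img[bi * hb : (bi + 1) * hb, bj * wb : (bj + 1) * wb, :]
                feats.append(block.reshape(-1, 3).mean(axis=0) / 255.0)
        return np.concatenate([np.atleast_1d(f) for f in feats])

    def __call__(self, img: np.ndarray) -> np.ndarray:
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("stub backbone expects an H x W x 3 image")
        return self._raw_stats(img) @ self._proj


def stub_backbone(spec: BackboneSpec, seed: int = 0) -> StubBackbone:
    """Construct a :class:`StubBackbone` (functional alias)."""
    return StubBackbone(spec, seed)


def standardize_features(
    train: FeatureDataset, *others: FeatureDataset
) -> tuple[FeatureDataset, ...]:
    """Zero-mean/unit-variance columns using train-set statistics.

    Constant columns are left centered but unscaled.  Returns the transformed
    train set followed by the other sets transformed with the same statistics.
    """
    mu = train.X.mean(axis=0)
    sd = train.X.std(axis=0, ddof=0)
    sd_safe = np.where(sd == 0, 1.0, sd)

    def _apply(ds: FeatureDataset) -> FeatureDataset:
        return FeatureDataset(
            (ds.X - mu) / sd_safe,
            ds.y,
            feature_names=list(ds.feature_names),
            sample_ids=list(ds.sample_ids),
            meta=dict(ds.meta),
        )

    return tuple(_apply(ds) for ds in (train, *others))


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read a ``path,label`` manifest CSV (header optional)."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if "path" not in cols or "label" not in cols:
        # headerless form
        df = pd.read_csv(path, header=None, names=["path", "label"])
    else:
        df.columns = cols
    df["label"] = df["label"].astype(int)
    return df[["path", "label"]]


def extract_from_manifest(
    manifest: str | Path | pd.DataFrame,
    backbone: Backbone,
    spec: BackboneSpec,
    root: str | Path | None = None,
) -> FeatureDataset:
    """Load, resize and featurize every image listed in a manifest."""
    from PIL import Image

    df = manifest if isinstance(manifest, pd.DataFrame) else load_manifest(manifest)
    images, ids = [], []
    for p in df["path"]:
        full = Path(root) / p if root is not None else Path(p)
        img = np.asarray(Image.open(full).convert("RGB"))
        images.append(resize_for_backbone(img, spec))
        ids.append(Path(p).name)
    return extract_features(
        images, backbone, labels=df["label"].to_numpy(), sample_ids=ids
    )
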