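"""Core in-memory container for feature matrices with binary labels.

The pipeline's tabular interchange format is a CSV with header
``sample_id,label,f0,...,fD``; :class:`FeatureDataset` wraps the matrix,
labels and identifiers and owns that dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureDataset"]

#: label conventions: 0 = NEOR (normal oral epithelium), 1 = OSCC (carcinoma)
NEGATIVE_LABEL = 0
POSITIVE_LABEL = 1


@dataclass
class FeatureDataset:
    """n_samples × n_features numeric matrix with binary labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Feature matrix; must be finite.
    y : ndarray of shape (n_samples,)
        Binary labels, 0 = NEOR, 1 = OSCC.
    feature_names : list of str, optional
        Defaults to ``f0 .. fD``.
    sample_ids : list of str, optional
        Defaults to ``s0 .. sN``.
    meta : dict
        Free-form provenance (e.g. planted informative column indices for
        synthetic fixtures).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"row count {self.X.shape[0]} != label count {self.y.shape[0]}"
            )
        if not np.isfinite(self.X).all():
            raise ValueError("feature matrix contains non-finite entries")
        if not np.isin(self.y, (NEGATIVE_LABEL, POSITIVE_LABEL)).all():
            raise ValueError("labels must be binary 0/1")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if self.sample_ids is None:
            self.sample_ids = [f"s{i}" for i in range(self.X.shape[0])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValueError("feature_names length mismatch")
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.y, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset_rows(self, idx: Sequence[int] | np.ndarray) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(
            self.X[idx],
            self.y[idx],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in idx],
            meta=dict(self.meta),
        )

    def subset_columns(self, mask: Sequence[int] | np.ndarray) -> "FeatureDataset":
        """Select feature columns by boolean mask or integer indices."""
        mask = np.asarray(mask)
        if mask.dtype == bool or set(np.unique(mask).tolist()) <= {0, 1}:
            if mask.shape[0] == self.n_features:
                cols = np.flatnonzero(mask)
            else:
                cols = mask.astype(int)
        else:
            cols = mask.astype(int)
        if cols.size == 0:
            raise ValueError("cannot select an empty feature set")
        return FeatureDataset(
            self.X[:, cols],
            self.y,
            feature_names=[self.feature_names[j] for j in cols],
            sample_ids=list(self.sample_ids),
            meta=dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "label", self.y)
        df.insert(0, "sample_id", self.sample_ids)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureDataset":
        if "label" not in df.columns:
            raise ValueError("feature table requires a 'label' column")
        ids = (
            df["sample_id"].astype(str).tolist()
            if "sample_id" in df.columns
            else None
        )
        feat_cols = [c for c in df.columns if c not in ("sample_id", "label")]
        return cls(
            df[feat_cols].to_numpy(dtype=float),
            df["label"].to_numpy(dtype=int),
            feature_names=list(feat_cols),
            sample_ids=ids,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureDataset":
        return cls.from_frame(pd.read_csv(path))
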