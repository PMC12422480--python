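"""Confusion-matrix container shared by the classifier and repertoire stages.

Rows are original (putative) call types, columns are predicted types; cells
are absolute call counts.  Per-row classification error is
``1 - diagonal/rowsum``.  The CSV dialect round-trips the published layout:
labels as header and row names, a final ``classification_error`` column,
integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConfusionMatrix"]


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple[str, ...]
    counts: np.ndarray  # (k, k) ints, rows = original, cols = predicted

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        k = len(self.labels)
        if c.shape != (k, k):
            raise ValueError(f"counts shape {c.shape} does not match {k} labels")
        if (c < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @classmethod
    def from_predictions(cls, labels_true, labels_pred, label_order=None) -> "ConfusionMatrix":
        labels_true = np.asarray(labels_true)
        labels_pred = np.asarray(labels_pred)
        if labels_true.shape != labels_pred.shape:
            raise ValueError("one prediction per call is required")
        if label_order is None:
            label_order = sorted(set(labels_true))
        unknown = set(labels_pred) - set(label_order)
        if unknown:
            raise ValueError(f"predicted labels not in label set: {sorted(unknown)}")
        idx = {l: i for i, l in enumerate(label_order)}
        k = len(label_order)
        c = np.zeros((k, k), dtype=np.int64)
        for t, p in zip(labels_true, labels_pred):
            c[idx[t], idx[p]] += 1
        return cls(tuple(label_order), c)

    @property
    def k(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def trace(self) -> int:
        return int(np.trace(self.counts))

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def per_class_error(self) -> pd.Series:
        """1 - diagonal/rowsum per original call type (NaN for empty rows)."""
        rs = self.row_sums.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            err = 1.0 - np.diag(self.counts) / rs
        return pd.Series(err, index=list(self.labels), name="classification_error")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))
        df["classification_error"] = self.per_class_error().round(3)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="call_type")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ConfusionMatrix":
        df = pd.read_csv(path, index_col=0)
        if "classification_error" in df.columns:
            df = df.drop(columns=["classification_error"])
        labels = tuple(str(l) for l in df.index)
        if tuple(str(c) for c in df.columns) != labels:
            raise ValueError("confusion-matrix CSV rows and columns must carry the same labels")
        return cls(labels, df.to_numpy())
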