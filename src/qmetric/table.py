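"""Labeled feature tables and their CSV representation.

The whole pipeline operates on :class:`LabeledTable`: a dense numeric
feature matrix (samples x features) with one class label per row.  Labels
may be strings or numbers; the classifier maps them to the internal
{-1, +1} encoding and maps back on output.  On disk a table is a UTF-8
CSV with a header row, one feature column per feature and a ``label``
column.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"


@dataclasses.dataclass
class LabeledTable:
    """A numeric feature matrix with one class label per row."""

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D (samples x features) array")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.shape[0] != self.features.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.features.shape[0]} feature rows"
            )
        if self.features.size and not np.isfinite(self.features).all():
            raise ValueError("features contain missing or non-finite values")
        if self.feature_names is None:
            self.feature_names = [f"f{i + 1}" for i in range(self.features.shape[1])]
        else:
            self.feature_names = [str(c) for c in self.feature_names]
            if len(self.feature_names) != self.features.shape[1]:
                raise ValueError("feature_names length does not match feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Distinct label values in sorted order."""
        return np.unique(self.labels)

    def subset(self, index: Sequence[int] | np.ndarray) -> "LabeledTable":
        index = np.asarray(index)
        return LabeledTable(self.features[index], self.labels[index], list(self.feature_names))

    def with_features(self, features: np.ndarray, feature_names: Sequence[str]) -> "LabeledTable":
        """Same rows/labels with a transformed feature matrix."""
        return LabeledTable(features, self.labels.copy(), list(feature_names))

    def class_features(self, label) -> np.ndarray:
        return self.features[self.labels == label]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df[LABEL_COLUMN] = self.labels
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label_column: str = LABEL_COLUMN) -> "LabeledTable":
        """Load a table, rejecting malformed cells with their location.

        Raises
        ------
        ValueError
            If the label column is missing, a feature cell is not numeric
            (the message names the offending row and column), or the label
            column carries more than two distinct classes.
        """
        df = pd.read_csv(path)
        if label_column not in df.columns:
            raise ValueError(f"{path}: no '{label_column}' column in header {list(df.columns)}")
        labels = df[label_column].to_numpy()
        feats = df.drop(columns=[label_column])
        for col in feats.columns:
            converted = pd.to_numeric(feats[col], errors="coerce")
            bad = converted.isna() & feats[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"{path}: non-numeric value {feats[col].iloc[row]!r} "
                    f"in column '{col}', row {row}"
                )
            if converted.isna().any():
                row = int(np.flatnonzero(converted.isna().to_numpy())[0])
                raise ValueError(f"{path}: missing value in column '{col}', row {row}")
            feats[col] = converted
        n_classes = len(np.unique(labels))
        if n_classes > 2:
            raise ValueError(f"{path}: expected a binary label column, found {n_classes} classes")
        return cls(feats.to_numpy(dtype=float), labels, list(feats.columns))

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, LabeledTable):
            return NotImplemented
        return (
            np.array_equal(self.features, other.features)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
        )
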