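"""Shared in-memory containers for the feature-selection and classification stages.

The currency of every stage after feature extraction is a :class:`FeatureTable`:
a samples x named-columns real matrix with an aligned benign/malignant label
vector. It wraps a :class:`pandas.DataFrame` so columns stay named and stable
through selection, fusion and undersampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BENIGN = "benign"
MALIGNANT = "malignant"
#: malignant is the positive class everywhere (confusion matrices, AdaBoost +1).
CLASSES = (BENIGN, MALIGNANT)


@dataclass
class FeatureTable:
    """Samples x named feature columns with an aligned label vector.

    Parameters
    ----------
    values
        Real-valued feature matrix, one row per sample. Column names must be
        unique and no entry may be missing.
    labels
        Per-sample class in ``{"benign", "malignant"}``, same length as
        ``values``.
    """

    values: pd.DataFrame
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.labels) != len(self.values):
            raise ValueError(
                f"label length {len(self.labels)} != sample count {len(self.values)}"
            )
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate column names: {dupes}")
        if self.values.isna().any().any():
            raise ValueError("feature table contains missing values")
        unknown = set(self.labels) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown labels {sorted(unknown)}; expected {CLASSES}")

    # -- conveniences used throughout the pipeline -------------------------
    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    def y(self) -> np.ndarray:
        """Labels as ints with malignant = 1, benign = 0."""
        return (self.labels == MALIGNANT).astype(int)

    def x(self) -> np.ndarray:
        """Feature matrix as a float ndarray."""
        return self.values.to_numpy(dtype=float)

    def subset_rows(self, idx: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.values.iloc[idx].reset_index(drop=True), self.labels[idx]
        )

    def subset_columns(self, keep: np.ndarray) -> "FeatureTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            cols = self.values.columns[keep]
        else:
            cols = self.values.columns[np.asarray(keep, dtype=int)]
        return FeatureTable(self.values.loc[:, cols].copy(), self.labels.copy())

    def class_counts(self) -> dict[str, int]:
        lab, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(lab.tolist(), cnt.tolist()))
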