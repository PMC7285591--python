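"""SMOTE oversampling of the minority class.

Synthetic minority samples are interpolated between a real minority sample
and one of its k nearest minority neighbors:

    x_new = x + u * (x_nn - x),   u ~ Uniform(0, 1)

so every synthetic point is a convex combination of two real minority
points.  The pipeline applies this to training partitions only; test
partitions always consist solely of real samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

REAL = "real"
SYNTHETIC = "synthetic"


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix + binary labels + per-row provenance (real/synthetic)."""

    features: pd.DataFrame
    labels: np.ndarray
    provenance: np.ndarray  # "real" | "synthetic" per row

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        provenance = np.asarray(self.provenance, dtype=object)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "provenance", provenance)
        n = len(self.features)
        if labels.shape[0] != n or provenance.shape[0] != n:
            raise ValueError("features, labels and provenance lengths differ")
        if not set(np.unique(labels)) <= {0, 1}:
            raise ValueError("labels must be binary {0,1}")

    @staticmethod
    def from_real(features: pd.DataFrame, labels: np.ndarray) -> "LabeledDataset":
        labels = np.asarray(labels, dtype=int)
        return LabeledDataset(features, labels, np.array([REAL] * len(labels), dtype=object))

    @property
    def n(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[int, int]:
        return {int(c): int((self.labels == c).sum()) for c in (0, 1)}

    def real_only(self) -> "LabeledDataset":
        mask = self.provenance == REAL
        return LabeledDataset(
            self.features.loc[mask].reset_index(drop=True),
            self.labels[mask],
            self.provenance[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        out = self.features.copy()
        out["label"] = self.labels
        out["provenance"] = self.provenance
        return out


def smote(
    dataset: LabeledDataset,
    k_neighbors: int = 5,
    target_count: int | None = None,
    seed: int = 0,
) -> LabeledDataset:
    """Oversample the minority class to ``target_count`` rows (default: the
    majority count, i.e. full balance).

    Real rows pass through untouched and keep their order; synthetic rows
    are appended after them with the minority label and provenance
    "synthetic".  Reproducible given ``seed``.
    """
    counts = dataset.class_counts()
    minority = 1 if counts[1] < counts[0] else (0 if counts[0] < counts[1] else 1)
    n_min, n_maj = counts[minority], counts[1 - minority]
    if n_min < 2:
        raise ValueError(f"minority class has {n_min} sample(s); SMOTE needs >= 2")
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    if target_count is None:
        target_count = n_maj
    if target_count < n_min:
        raise ValueError(
            f"target_count {target_count} below current minority count {n_min}"
        )
    n_new = target_count - n_min
    if n_new == 0:
        return dataset

    X = dataset.features.to_numpy(dtype=float)
    min_idx = np.flatnonzero(dataset.labels == minority)
    X_min = X[min_idx]
    k = min(k_neighbors, n_min - 1)
    # neighbor order is deterministic; exact ties fall back to row order
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    neighbors = nn.kneighbors(X_min, return_distance=False)[:, 1:]  # drop self

    rng = np.random.default_rng(seed)
    base = rng.integers(0, n_min, size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random(size=n_new)
    x_base = X_min[base]
    x_nn = X_min[neighbors[base, pick]]
    X_new = x_base + u[:, None] * (x_nn - x_base)

    features = pd.concat(
        [
            dataset.features.reset_index(drop=True),
            pd.DataFrame(X_new, columns=dataset.features.columns),
        ],
        ignore_index=True,
    )
    labels = np.concatenate([dataset.labels, np.full(n_new, minority, dtype=int)])
    provenance = np.concatenate(
        [dataset.provenance, np.array([SYNTHETIC] * n_new, dtype=object)]
    )
    return LabeledDataset(features, labels, provenance)
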