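"""Feature-vector container shared by all encoders."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, named real-valued feature components."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if len(self.names) != values.shape[0]:
            raise ValueError("names and values lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite feature values")

    def __len__(self) -> int:
        return len(self.names)

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    @staticmethod
    def concat(parts: Sequence["FeatureVector"]) -> "FeatureVector":
        if not parts:
            raise ValueError("cannot concatenate an empty list of feature vectors")
        names = tuple(n for p in parts for n in p.names)
        values = np.concatenate([p.values for p in parts])
        return FeatureVector(names, values)


def feature_frame(
    names: Iterable[str], rows: Iterable[FeatureVector]
) -> pd.DataFrame:
    """Stack per-sequence feature vectors into a DataFrame (rows = sequences)."""
    rows = list(rows)
    index = list(names)
    if not rows:
        raise ValueError("no feature vectors to stack")
    cols = rows[0].names
    for fv in rows:
        if fv.names != cols:
            raise ValueError("inconsistent feature names across rows")
    return pd.DataFrame(
        np.vstack([fv.values for fv in rows]), index=index, columns=list(cols)
    )
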