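"""Shared embedding container used by the three feature-extraction modules."""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError

__all__ = ["EmbeddingSource", "EmbeddingMatrix", "write_embedding", "read_embedding"]


class EmbeddingSource(str, Enum):
    sae = "sae"
    gat = "gat"
    nmf_u = "nmf_u"
    nmf_v = "nmf_v"


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Entities x d real embedding matrix tied to an ordered id list."""

    values: np.ndarray
    ids: tuple[str, ...]
    source: EmbeddingSource

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "source", EmbeddingSource(self.source))
        if values.ndim != 2 or values.shape[0] != len(self.ids):
            raise DimensionError(
                f"embedding shape {values.shape} inconsistent with {len(self.ids)} ids"
            )
        if not np.isfinite(values).all():
            raise DimensionError("embedding contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.values.shape[1]


def write_embedding(embedding: EmbeddingMatrix, path: str | Path) -> None:
    df = pd.DataFrame(embedding.values, index=list(embedding.ids))
    df.to_csv(path, float_format="%.17g")


def read_embedding(path: str | Path, source: EmbeddingSource | str) -> EmbeddingMatrix:
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    return EmbeddingMatrix(
        values=df.to_numpy(dtype=np.float64),
        ids=tuple(str(i) for i in df.index),
        source=EmbeddingSource(source),
    )
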