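"""Expression matrix container shared across the pipeline.

A thin wrapper around a features x samples :class:`pandas.DataFrame` that
carries a scale tag so that operations can refuse inputs on the wrong scale
(for example upper-quantile normalization is only defined on RPM input).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: Scales an ExpressionMatrix may carry.  Transitions happen only through
#: the quantification / normalization operations.
SCALES = ("raw-count", "RPM", "RPKM", "log2", "log2-UQ")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with a transformation-state tag."""

    data: pd.DataFrame
    scale: str = "raw-count"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.scale in ("raw-count", "RPM", "RPKM") and (self.data.values < 0).any():
            raise ValueError(f"negative values are not allowed on the {self.scale} scale")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(feature_ids)], self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)

    def to_tsv(self, path: str | Path, feature_col: str = "feature_id") -> None:
        out = self.data.copy()
        out.index.name = feature_col
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, scale: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, scale)
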