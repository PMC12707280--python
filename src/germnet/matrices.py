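"""Typed feature-by-sample tables and their TSV round-trips.

Two thin wrappers around :class:`pandas.DataFrame` are used throughout the
package: :class:`CountMatrix` for non-negative integer read counts and
:class:`AbundanceMatrix` for real-valued transformed data.  Both carry a tag
(the feature kind, or the transform that produced the values) so downstream
stages can check they were handed the right thing.

Rows are features, columns are samples.  On disk the convention is a TSV
whose first column holds feature ids and whose header row holds sample ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FEATURE_KINDS = ("plant_gene", "microbial_gene", "pathway", "taxon")
TRANSFORMS = ("relative", "clr", "median_ratio")


def _validate_table(data: pd.DataFrame) -> None:
    if data.shape[0] < 1 or data.shape[1] < 1:
        raise ValueError("matrix must have at least one feature and one sample")
    if data.index.has_duplicates:
        raise ValueError("feature ids must be unique")
    if data.columns.has_duplicates:
        raise ValueError("sample ids must be unique")


@dataclass
class CountMatrix:
    """Non-negative integer feature x sample table with a feature-kind tag."""

    data: pd.DataFrame
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}; expected one of {FEATURE_KINDS}")
        _validate_table(self.data)
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if (values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str) -> "CountMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=data, kind=kind)


@dataclass
class AbundanceMatrix:
    """Real-valued feature x sample table tagged with the transform applied."""

    data: pd.DataFrame
    transform: str

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        _validate_table(self.data)
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValueError("abundance values must be finite")
        if self.transform == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("relative-abundance columns must sum to 1")
        elif self.transform == "clr":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 0.0, atol=1e-8):
                raise ValueError("clr columns must sum to 0")

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, transform: str) -> "AbundanceMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=data, transform=transform)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata CSV indexed by sample id."""
    return pd.read_csv(path, index_col=0)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a two-column gene -> pathway mapping TSV."""
    ann = pd.read_csv(path, sep="\t")
    if ann.shape[1] < 2:
        raise ValueError("annotation mapping must have two columns (gene id, pathway id)")
    ann.columns = ["gene_id", "pathway_id", *ann.columns[2:]]
    return ann[["gene_id", "pathway_id"]]
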