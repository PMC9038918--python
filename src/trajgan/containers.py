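"""Core in-memory containers shared across the pipeline.

Expression data moves through three declared scales:

``rpkm``
    Reads per kilobase of transcript per million mapped reads; non-negative.
``log2norm``
    Offset log2 counts-per-million (the deterministic core of a voom-style
    transform), the scale on which augmentation and trend baselines operate.
``unit``
    Per-gene min-max scaled values, nominally in [0, 1]; the scale the GAN
    is trained on.

Matrices are oriented genes x samples throughout, mirroring the TSV files
the pipeline reads and writes (first column gene ids, header row sample ids).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALES = ("rpkm", "log2norm", "unit")


@dataclass
class ExpressionMatrix:
    """A genes x samples real-valued matrix with declared scale provenance.

    Parameters
    ----------
    data
        DataFrame indexed by gene id with sample ids as columns.
    scale
        One of :data:`SCALES`; records how the values were produced.
    """

    data: pd.DataFrame
    scale: str = field(default="log2norm")

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if self.scale == "rpkm" and values.size and values.min() < 0:
            raise ValueError("rpkm scale requires non-negative values")
        if self.scale == "unit" and values.size:
            lo, hi = values.min(), values.max()
            if lo < -1e-9 or hi > 1 + 1e-9:
                # out-of-range unit values are legal (e.g. scaling data the
                # scaler was not fitted on) but worth surfacing
                logger.warning(
                    "unit-scale matrix has values outside [0, 1]: min=%.4g max=%.4g",
                    lo,
                    hi,
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.data.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        return ExpressionMatrix(self.data[list(sample_ids)], self.scale)


def read_matrix_tsv(path: str | Path, scale: str) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids) into a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, scale)


def write_matrix_tsv(matrix: ExpressionMatrix | pd.DataFrame, path: str | Path) -> None:
    df = matrix.data if isinstance(matrix, ExpressionMatrix) else matrix
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read an integer gene x sample count matrix, validating non-negativity."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative entries")
    return df
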