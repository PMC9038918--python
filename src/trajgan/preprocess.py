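"""Count normalization, expression filtering and min-max scaling.

The preprocessing chain is::

    counts --RPKM--> filter (RPKM >= 1 in >= 80% of samples per group)
    counts --offset log2-CPM--> log2norm matrix (retained genes)
    log2norm --per-gene min-max--> unit matrix in [0, 1] for GAN training

RPKM (reads per kilobase per million mapped reads) is used only for
filtering; training values are offset log-CPM, ``log2((c + 0.5) / (lib + 1)
* 1e6)`` — the deterministic core of a voom-style transform (the precision
weights voom additionally estimates are never used downstream here).

Min-max scaling is per gene (feature-wise) and invertible; constant genes
map to 0 on the unit scale and back to their constant on inversion.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


def compute_rpkm(counts: pd.DataFrame, lengths: pd.Series | pd.DataFrame) -> ExpressionMatrix:
    """Length- and depth-normalize counts to RPKM.

    ``RPKM_gs = count_gs / (libsize_s / 1e6) / (length_g / 1e3)`` with
    ``libsize_s`` the column sum of the count matrix.

    Parameters
    ----------
    counts
        Integer genes x samples matrix.
    lengths
        Transcript length in bp per gene: either a Series indexed by gene id
        or a gene table with ``gene_id`` and ``length_bp`` columns.
    """
    if isinstance(lengths, pd.DataFrame):
        lengths = lengths.set_index("gene_id")["length_bp"]
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"missing gene lengths for {missing}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    libsize = counts.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    rpkm = counts.div(libsize / 1e6, axis=1).div(lengths / 1e3, axis=0)
    return ExpressionMatrix(rpkm, "rpkm")


def filter_genes(
    expr: ExpressionMatrix,
    groups: dict[tuple[str, str], list[str]],
    rpkm_min: float = 1.0,
    frac: float = 0.8,
    mode: str = "all",
) -> list[str]:
    """Select genes expressed above ``rpkm_min`` in enough samples per group.

    A gene passes a group when at least ``ceil(frac * n_group)`` of its
    samples have RPKM >= ``rpkm_min``. With ``mode="all"`` (default, the
    stricter reading of a per-group rule) the gene must pass every group;
    ``mode="any"`` requires one group. Output preserves input gene order.
    """
    if expr.scale != "rpkm":
        raise ValueError("filter_genes expects an rpkm-scale matrix")
    if not 0 < frac <= 1:
        raise ValueError("frac must lie in (0, 1]")
    if mode not in ("all", "any"):
        raise ValueError('mode must be "all" or "any"')
    if not groups:
        raise ValueError("empty group map")
    passes = []
    for key, members in groups.items():
        if not members:
            raise ValueError(f"empty group {key}")
        sub = expr.data[members].to_numpy()
        required = math.ceil(frac * len(members) - 1e-9)
        passes.append((sub >= rpkm_min).sum(axis=1) >= required)
    stacked = np.column_stack(passes)
    keep = stacked.all(axis=1) if mode == "all" else stacked.any(axis=1)
    return [g for g, k in zip(expr.gene_ids, keep) if k]


def normalize_log(counts: pd.DataFrame, retained: list[str] | None = None) -> ExpressionMatrix:
    """Offset log2-CPM transform of counts, restricted to retained genes.

    ``value_gs = log2((count_gs + 0.5) / (libsize_s + 1) * 1e6)`` with the
    library size computed on the full input matrix before gene restriction.
    """
    if retained is not None:
        if len(retained) == 0:
            raise ValueError("empty retained gene list")
        missing = [g for g in retained if g not in counts.index]
        if missing:
            raise ValueError(f"retained genes absent from counts: {missing[:5]}")
    libsize = counts.sum(axis=0)
    sub = counts if retained is None else counts.loc[list(retained)]
    values = np.log2((sub + 0.5).div(libsize + 1.0, axis=1) * 1e6)
    return ExpressionMatrix(values, "log2norm")


@dataclass
class ScalerParams:
    """Per-gene min/max fitted on a log2norm training matrix."""

    per_gene_min: pd.Series
    per_gene_max: pd.Series

    def __post_init__(self) -> None:
        if not self.per_gene_min.index.equals(self.per_gene_max.index):
            raise ValueError("min and max must share a gene index")
        if (self.per_gene_max < self.per_gene_min).any():
            raise ValueError("per-gene max must be >= min")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.per_gene_min.index)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"min": self.per_gene_min, "max": self.per_gene_max}
        ).to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScalerParams":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df["min"], df["max"])


def minmax_fit(expr: ExpressionMatrix) -> ScalerParams:
    """Fit per-gene min/max on a log2norm matrix (>= 2 samples)."""
    if expr.n_samples < 2:
        raise ValueError("min-max fit requires at least 2 samples")
    return ScalerParams(expr.data.min(axis=1), expr.data.max(axis=1))


def _aligned(params: ScalerParams, gene_ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [g for g in gene_ids if g not in params.per_gene_min.index]
    if missing:
        raise KeyError(f"scaler params missing genes: {missing[:5]}")
    mins = params.per_gene_min.reindex(gene_ids).to_numpy()
    maxs = params.per_gene_max.reindex(gene_ids).to_numpy()
    return mins, maxs


def minmax_apply(expr: ExpressionMatrix, params: ScalerParams) -> ExpressionMatrix:
    """Scale a log2norm matrix to the unit interval per gene.

    ``u = (v - min_g) / (max_g - min_g)``. Constant genes (max == min) map
    to 0. No clamping: values outside the fitted range leave [0, 1] and are
    flagged by the container with a warning.
    """
    mins, maxs = _aligned(params, expr.gene_ids)
    span = maxs - mins
    safe = np.where(span > 0, span, 1.0)
    unit = (expr.data.to_numpy() - mins[:, None]) / safe[:, None]
    unit[span == 0, :] = 0.0
    return ExpressionMatrix(
        pd.DataFrame(unit, index=expr.data.index, columns=expr.data.columns),
        "unit",
    )


def minmax_invert(expr: ExpressionMatrix, params: ScalerParams) -> ExpressionMatrix:
    """Invert unit-scale values back to log2norm; constant genes recover
    their fitted constant."""
    mins, maxs = _aligned(params, expr.gene_ids)
    span = maxs - mins
    values = expr.data.to_numpy() * span[:, None] + mins[:, None]
    return ExpressionMatrix(
        pd.DataFrame(values, index=expr.data.index, columns=expr.data.columns),
        "log2norm",
    )
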