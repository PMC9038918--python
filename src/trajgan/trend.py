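"""Interval trend statistics and gene-gene coregulation from trajectories.

The 100-point pseudo-time axis is split into early / mid / late thirds
(points 1-33, 34-66, 67-100 under the default half-open partition; an
overlapping variant with shared endpoints 34 and 67 is available). Per
interval the expression summary is the geometric mean on the linear scale
— equivalently ``2 ** (arithmetic mean of the log2 values)`` — and the
Log2FC trend is the log2 ratio of that summary to a per-gene baseline
(default: the geometric mean of the real control-condition samples).
A gene counts as differentially expressed in an interval when its Log2FC
exceeds 0.2 (an upregulation rule; a symmetric absolute-value option
exists).

Coregulation between two gene sets is the Pearson correlation of their
100-point trajectories on the log2norm scale, annotated with which genes
are upregulated and which pairs have both members DE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .gan import pearson_rows
from .preprocess import ScalerParams, minmax_invert
from .trajectory import N_TIMEPOINTS, Trajectory

logger = logging.getLogger(__name__)

DE_THRESHOLD = 0.2
INTERVALS = ("early", "mid", "late")


@dataclass
class IntervalPartition:
    """1-based time-point indices of the early/mid/late intervals."""

    early: tuple[int, ...]
    mid: tuple[int, ...]
    late: tuple[int, ...]

    def __post_init__(self) -> None:
        covered = set(self.early) | set(self.mid) | set(self.late)
        if covered != set(range(1, N_TIMEPOINTS + 1)):
            raise ValueError(f"partition must cover time points 1..{N_TIMEPOINTS}")

    def as_dict(self) -> dict[str, tuple[int, ...]]:
        return {"early": self.early, "mid": self.mid, "late": self.late}


def default_partition(overlapping: bool = False) -> IntervalPartition:
    """Early/mid/late thirds of 1..100.

    The published interval bounds (1-34, 34-67, 67-100) share their
    endpoints; the default half-open reading [1,34), [34,67), [67,100]
    keeps the intervals disjoint (sizes 33/33/34). ``overlapping=True``
    restores the literal shared-endpoint reading.
    """
    if overlapping:
        return IntervalPartition(
            tuple(range(1, 35)), tuple(range(34, 68)), tuple(range(67, 101))
        )
    return IntervalPartition(
        tuple(range(1, 34)), tuple(range(34, 67)), tuple(range(67, 101))
    )


def interval_summary(
    traj: Trajectory,
    scaler: ScalerParams,
    partition: IntervalPartition | None = None,
) -> pd.DataFrame:
    """Linear-scale geometric-mean expression per gene per interval.

    The unit-scale trajectory is inverted to log2norm through the scaler;
    the geometric mean of the linear values ``2**v`` over an interval is
    computed as ``2 ** mean(v)``, which is strictly positive by
    construction.
    """
    if partition is None:
        partition = default_partition()
    log2 = minmax_invert(ExpressionMatrix(traj.values, "unit"), scaler).data
    out = {}
    for name, points in partition.as_dict().items():
        cols = [f"T{i}" for i in points]
        out[name] = np.exp2(log2[cols].mean(axis=1))
    return pd.DataFrame(out, index=log2.index)


def sn_baseline(expr: ExpressionMatrix, sn_sample_ids: list[str]) -> pd.Series:
    """Per-gene baseline: linear-scale geometric mean of the real control
    (SN) samples, from their log2norm values."""
    if expr.scale != "log2norm":
        raise ValueError("baseline expects a log2norm matrix")
    if not sn_sample_ids:
        raise ValueError("no control samples given")
    return np.exp2(expr.data[list(sn_sample_ids)].mean(axis=1))


def log2fc_trend(
    summaries: pd.DataFrame,
    baseline: pd.Series,
    de_threshold: float = DE_THRESHOLD,
    absolute: bool = False,
) -> pd.DataFrame:
    """Per-gene Log2FC trend table with DE flags.

    ``log2fc_interval = log2(summary_interval / baseline)``; the DE flag is
    ``log2fc > de_threshold`` (or ``|log2fc| > de_threshold`` with
    ``absolute=True``).
    """
    baseline = baseline.reindex(summaries.index)
    if baseline.isna().any():
        raise ValueError("baseline missing genes present in summaries")
    if (baseline <= 0).any():
        raise ValueError("baseline must be strictly positive on the linear scale")
    table = pd.DataFrame(index=summaries.index)
    for name in INTERVALS:
        fc = np.log2(summaries[name] / baseline)
        table[f"log2fc_{name}"] = fc
        table[f"de_{name}"] = (fc.abs() if absolute else fc) > de_threshold
    return table


@dataclass
class CoregulationMatrix:
    """Pairwise trajectory correlations between two gene sets."""

    r: pd.DataFrame  # genes_a x genes_b Pearson r
    both_de: pd.DataFrame  # bool, asterisk rule: both genes DE somewhere
    upregulated_a: pd.Series  # bool per row gene: any-interval Log2FC > 0
    upregulated_b: pd.Series


def coregulation(
    traj: Trajectory,
    scaler: ScalerParams,
    trend_table: pd.DataFrame,
    genes_a: list[str],
    genes_b: list[str],
) -> CoregulationMatrix:
    """Correlate the 100-point trajectories of two gene sets.

    ``r[a, b]`` is the Pearson correlation of the log2norm trajectories of
    genes a and b; constant trajectories have undefined r, recorded as NaN
    and logged. ``both_de`` marks pairs where both genes exceed the 0.2
    Log2FC threshold in at least one interval; the upregulated masks mark
    genes with any-interval Log2FC > 0.
    """
    for gene_set, label in ((genes_a, "A"), (genes_b, "B")):
        missing = [g for g in gene_set if g not in traj.values.index]
        if missing:
            raise KeyError(f"gene set {label} absent from trajectory: {missing[:5]}")
    log2 = minmax_invert(ExpressionMatrix(traj.values, "unit"), scaler).data
    A = log2.loc[list(genes_a)].to_numpy()
    B = log2.loc[list(genes_b)].to_numpy()
    const_a = A.std(axis=1) == 0
    const_b = B.std(axis=1) == 0
    if const_a.any() or const_b.any():
        logger.warning(
            "constant trajectories (r undefined, set to NaN): %s",
            [g for g, c in zip(list(genes_a) + list(genes_b), list(const_a) + list(const_b)) if c],
        )
    r = pearson_rows(A, B)
    r[const_a, :] = np.nan
    r[:, const_b] = np.nan
    r_df = pd.DataFrame(r, index=list(genes_a), columns=list(genes_b))

    fc_cols = [f"log2fc_{name}" for name in INTERVALS]
    de_any = (trend_table[fc_cols] > DE_THRESHOLD).any(axis=1)
    up_any = (trend_table[fc_cols] > 0).any(axis=1)
    both_de = pd.DataFrame(
        np.outer(de_any.reindex(genes_a).to_numpy(), de_any.reindex(genes_b).to_numpy()),
        index=list(genes_a),
        columns=list(genes_b),
    )
    return CoregulationMatrix(
        r=r_df,
        both_de=both_de,
        upregulated_a=up_any.reindex(genes_a),
        upregulated_b=up_any.reindex(genes_b),
    )


def coregulation_long(coreg: CoregulationMatrix) -> pd.DataFrame:
    """Flatten a coregulation matrix into (gene_a, gene_b, r, both_de,
    both_up) rows for TSV export."""
    rows = []
    for a in coreg.r.index:
        for b in coreg.r.columns:
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "r": coreg.r.loc[a, b],
                    "both_de": bool(coreg.both_de.loc[a, b]),
                    "both_up": bool(coreg.upregulated_a[a] and coreg.upregulated_b[b]),
                }
            )
    return pd.DataFrame(rows)


def plot_coregulation_heatmap(coreg: CoregulationMatrix, ax=None):
    """Heatmap of the coregulation matrix: warm = positive r, cool =
    negative; asterisks mark pairs where both genes are DE."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.4 * coreg.r.shape[1], 1 + 0.4 * coreg.r.shape[0]))
    im = ax.imshow(coreg.r.to_numpy(), cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(coreg.r.shape[1]), coreg.r.columns, rotation=90)
    ax.set_yticks(range(coreg.r.shape[0]), coreg.r.index)
    for i, a in enumerate(coreg.r.index):
        for j, b in enumerate(coreg.r.columns):
            if coreg.both_de.loc[a, b]:
                ax.text(j, i, "*", ha="center", va="center")
    ax.figure.colorbar(im, ax=ax, label="Pearson r")
    return ax
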