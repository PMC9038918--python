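"""End-to-end convenience pipeline for a single tissue region.

Chains the full procedure: RPKM filtering, offset log-CPM normalization,
tenfold pairwise augmentation, per-gene min-max scaling, WGAN-GP training
on the region's control (SN) and treated (CN) samples, checkpoint-ensemble
transition curves, and the interval Log2FC trend table against the real-SN
baseline. Intended for scripted runs and tests; each stage remains
individually importable for custom workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import augment_dataset
from .containers import ExpressionMatrix
from .gan import LatentSpec, NetworkSpec, TrainConfig, train_wgan_gp
from .preprocess import (
    ScalerParams,
    compute_rpkm,
    filter_genes,
    minmax_apply,
    minmax_fit,
    normalize_log,
)
from .simulate import group_index
from .trajectory import Trajectory, ensemble_curve
from .trend import default_partition, interval_summary, log2fc_trend, sn_baseline


@dataclass
class RegionTrendResult:
    """Everything the per-region pipeline produces."""

    retained_genes: list[str]
    scaler: ScalerParams
    trajectory: Trajectory
    trend: pd.DataFrame
    loss_log: pd.DataFrame
    baseline: pd.Series


def region_trend_pipeline(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    genes: pd.DataFrame,
    region: str,
    net_spec: NetworkSpec | None = None,
    latent_spec: LatentSpec | None = None,
    train_config: TrainConfig | None = None,
    n_candidates: int = 35000,
    k: int = 10,
    rpkm_min: float = 1.0,
    frac: float = 0.8,
    seed: int = 0,
) -> RegionTrendResult:
    """Run the whole SN->CN trend analysis for one region.

    Gene filtering uses all groups of the full design; training, inversion
    and trends use only the region's SN and CN samples. ``net_spec`` /
    ``latent_spec`` / ``train_config`` default to the full-scale settings
    when omitted (override for desk-scale runs).
    """
    groups = group_index(samples)
    rpkm = compute_rpkm(counts, genes)
    retained = filter_genes(rpkm, groups, rpkm_min=rpkm_min, frac=frac)
    log2 = normalize_log(counts, retained)

    region_groups = {
        key: members
        for key, members in groups.items()
        if key[0] == region and key[1] in ("SN", "CN")
    }
    if not region_groups:
        raise ValueError(f"region {region!r} has no SN/CN samples")
    region_sample_ids = [s for members in region_groups.values() for s in members]
    region_log2 = log2.subset_samples(region_sample_ids)

    augmented, _ = augment_dataset(region_log2, region_groups)
    scaler = minmax_fit(augmented)
    unit = minmax_apply(augmented, scaler)

    if net_spec is None:
        net_spec = NetworkSpec(output_dim=len(retained))
    if latent_spec is None:
        latent_spec = LatentSpec(dim=net_spec.latent_dim)
    if train_config is None:
        train_config = TrainConfig(seed=seed)
    checkpoints, loss_log = train_wgan_gp(unit, net_spec, latent_spec, train_config)
    if not checkpoints:
        raise ValueError("train_config.checkpoint_epochs produced no checkpoints")

    unit_real = minmax_apply(region_log2, scaler)
    sn_ids = region_groups[(region, "SN")]
    cn_ids = region_groups[(region, "CN")]
    sn_profiles = unit_real.data[sn_ids].to_numpy().T
    cn_profiles = unit_real.data[cn_ids].to_numpy().T

    trajectory = ensemble_curve(
        checkpoints,
        sn_profiles,
        cn_profiles,
        n_candidates=n_candidates,
        k=k,
        seed=seed,
        gene_ids=retained,
    )
    summaries = interval_summary(trajectory, scaler, default_partition())
    baseline = sn_baseline(region_log2, sn_ids)
    trend = log2fc_trend(summaries, baseline)
    return RegionTrendResult(
        retained_genes=retained,
        scaler=scaler,
        trajectory=trajectory,
        trend=trend,
        loss_log=loss_log,
        baseline=baseline,
    )
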