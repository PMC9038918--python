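"""Synthetic bulk RNA-seq count data with planted condition effects.

Emulates the statistical structure the rest of the pipeline assumes: a
multi-region, multi-condition design with a handful of biological replicates
per (region, condition) group, overdispersed negative-binomial counts, and a
chosen subset of genes carrying a log2 fold-change shift in the chronic
condition ("CN") relative to the saline control ("SN") and all other
conditions. Ground truth (which genes carry the effect and how large it is)
is returned alongside the data so downstream recovery can be quantified.

The count law is a negative binomial parameterized by mean ``mu`` and a
single dispersion ``alpha`` shared across genes, so ``var = mu + alpha *
mu**2`` — the standard overdispersion model for bulk RNA-seq counts. Gene
lengths are drawn log-normally around a configurable mean; they only enter
the pipeline through RPKM normalization, so their exact law is immaterial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

#: Canonical brain-region labels used when ``n_regions`` is at most six.
REGION_NAMES = ("BLA", "CPU", "NAC", "PFC", "HIP", "VTA")

#: The six experimental conditions of the self-administration design.
DEFAULT_CONDITIONS = ("SN", "CN", "SC", "CS", "CC", "SS")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Attributes
    ----------
    n_genes
        Number of genes to simulate.
    n_regions
        Number of tissue regions (default 6, the study design).
    conditions
        Condition labels; must include ``"SN"`` and ``"CN"``.
    replicates_per_group
        Biological replicates per (region, condition) group; the study
        design has three to six, so values outside [3, 6] are rejected.
    n_effect_genes
        How many genes carry the planted SN->CN shift.
    effect_log2fc
        Planted shift in log2 units, applied to the CN condition only.
    baseline_mean_range
        (low, high) interval for per-gene expected counts; baselines are
        drawn log-uniformly inside it.
    dispersion
        Negative-binomial overdispersion ``alpha`` (var = mu + alpha*mu^2).
    mean_length_bp
        Mean transcript length in base pairs (log-normal draw per gene).
    seed
        Seed for the simulation RNG; identical seeds give bitwise-identical
        output.
    """

    n_genes: int
    n_regions: int = 6
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_group: int = 4
    n_effect_genes: int = 0
    effect_log2fc: float = 0.0
    baseline_mean_range: tuple[float, float] = (20.0, 2000.0)
    dispersion: float = 0.1
    mean_length_bp: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_regions <= 0:
            raise ValueError("n_genes and n_regions must be positive")
        conditions = tuple(self.conditions)
        if "SN" not in conditions or "CN" not in conditions:
            raise ValueError('conditions must include "SN" and "CN"')
        if len(set(conditions)) != len(conditions):
            raise ValueError("duplicate condition labels")
        self.conditions = conditions
        if not 3 <= self.replicates_per_group <= 6:
            raise ValueError("replicates_per_group must lie in [3, 6]")
        if not 0 <= self.n_effect_genes <= self.n_genes:
            raise ValueError("n_effect_genes must lie in [0, n_genes]")
        lo, hi = self.baseline_mean_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("baseline_mean_range must be a positive interval")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be strictly positive")
        if self.mean_length_bp <= 0:
            raise ValueError("mean_length_bp must be strictly positive")


@dataclass
class GroundTruth:
    """Planted-effect bookkeeping for recovery tests."""

    effect_genes: set[str]
    per_gene_log2fc: dict[str, float]
    group_sizes: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for gene, fc in self.per_gene_log2fc.items():
            if gene not in self.effect_genes and fc != 0.0:
                raise ValueError(f"nonzero log2fc for non-effect gene {gene}")


class SimulatedDataset(NamedTuple):
    counts: pd.DataFrame  # genes x samples, integer
    samples: pd.DataFrame  # sample_id, region, condition, replicate
    genes: pd.DataFrame  # gene_id, length_bp
    truth: GroundTruth


def _region_labels(n_regions: int) -> list[str]:
    if n_regions <= len(REGION_NAMES):
        return list(REGION_NAMES[:n_regions])
    return [f"R{i + 1}" for i in range(n_regions)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    # numpy parameterization: n successes, success prob p; mean = n(1-p)/p
    n = 1.0 / alpha
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full synthetic dataset plus its ground truth.

    Counts for gene ``g`` in sample ``s`` are negative-binomial with mean
    ``mu_g * 2**(e_g * [condition(s) == "CN"])`` where ``e_g`` is the planted
    effect (0 for non-effect genes).
    """
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i + 1:04d}" for i in range(config.n_genes)]

    lo, hi = config.baseline_mean_range
    baseline_mu = np.exp(rng.uniform(math.log(lo), math.log(hi), size=config.n_genes))

    effect_idx = rng.choice(config.n_genes, size=config.n_effect_genes, replace=False)
    effect = np.zeros(config.n_genes)
    effect[effect_idx] = config.effect_log2fc
    effect_genes = {gene_ids[i] for i in effect_idx}

    # lengths: log-normal with mean equal to mean_length_bp (sigma fixed small)
    sigma = 0.25
    lengths = rng.lognormal(
        mean=math.log(config.mean_length_bp) - sigma**2 / 2.0,
        sigma=sigma,
        size=config.n_genes,
    )
    lengths = np.maximum(np.round(lengths), 200).astype(int)

    regions = _region_labels(config.n_regions)
    sample_rows = []
    columns: dict[str, np.ndarray] = {}
    group_sizes: dict[tuple[str, str], int] = {}
    for region in regions:
        for condition in config.conditions:
            group_sizes[(region, condition)] = config.replicates_per_group
            shift = 2.0**effect if condition == "CN" else np.ones(config.n_genes)
            mu = baseline_mu * shift
            for rep in range(1, config.replicates_per_group + 1):
                sample_id = f"{region}_{condition}_r{rep}"
                sample_rows.append(
                    {
                        "sample_id": sample_id,
                        "region": region,
                        "condition": condition,
                        "replicate": rep,
                    }
                )
                columns[sample_id] = _nb_draw(rng, mu, config.dispersion)

    counts = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    samples = pd.DataFrame(sample_rows)
    genes = pd.DataFrame(
        {"gene_id": gene_ids, "length_bp": lengths}
    )
    truth = GroundTruth(
        effect_genes=effect_genes,
        per_gene_log2fc={g: float(e) for g, e in zip(gene_ids, effect)},
        group_sizes=group_sizes,
    )
    return SimulatedDataset(counts, samples, genes, truth)


def group_index(samples: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Partition sample ids by (region, condition).

    The union of the returned groups is exactly the input sample set and the
    groups are disjoint; insertion order follows first appearance.
    """
    required = {"sample_id", "region", "condition"}
    missing_cols = required - set(samples.columns)
    if missing_cols:
        raise ValueError(f"sample table missing columns: {sorted(missing_cols)}")
    if samples[["region", "condition"]].isna().any().any():
        raise ValueError("sample table has missing region/condition labels")
    groups: dict[tuple[str, str], list[str]] = {}
    for row in samples.itertuples(index=False):
        groups.setdefault((row.region, row.condition), []).append(row.sample_id)
    return groups


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Write counts, sample/gene metadata and ground truth as TSV files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dataset.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="gene_id")
    dataset.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    dataset.genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    truth_df = pd.DataFrame(
        {
            "gene_id": list(dataset.truth.per_gene_log2fc),
            "planted_log2fc": list(dataset.truth.per_gene_log2fc.values()),
        }
    )
    truth_df.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
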