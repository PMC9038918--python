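"""Latent inversion and condition-transition curves.

A trained generator G maps latents to unit-scale profiles. Real samples are
"inverted" by nearest-neighbor search: decode a large pool of candidate
latents, rank them by Pearson correlation with the real profile, and average
the top-k latents coordinate-wise. Condition-level latents (z_SN, z_CN) are
the means of the per-sample inversions; their difference is the delta vector
delta = z_CN - z_SN. Decoding z_i = z_SN + delta * i/100 for i = 0..99
yields a 100-point transition curve T1..T100 from the control toward the
treated state (the schedule deliberately stops at 0.99 * delta). Curves are
ensemble-averaged over checkpoints saved at different training epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gan import Checkpoint, LatentSpec, pearson_rows, sample_latent

logger = logging.getLogger(__name__)

N_TIMEPOINTS = 100


@dataclass
class Trajectory:
    """Genes x 100 unit-scale matrix of pseudo-time expression (T1..T100)."""

    values: pd.DataFrame
    checkpoint_ids: tuple = ()

    def __post_init__(self) -> None:
        if self.values.shape[1] != N_TIMEPOINTS:
            raise ValueError(f"trajectory must have exactly {N_TIMEPOINTS} time points")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Trajectory":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def _timepoint_columns() -> list[str]:
    return [f"T{i}" for i in range(1, N_TIMEPOINTS + 1)]


def invert_sample(
    generator,
    real_sample: np.ndarray,
    latent_spec: LatentSpec,
    n_candidates: int = 35000,
    k: int = 10,
    rng: np.random.Generator | int = 0,
    candidates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-neighbor latent inversion of one real profile.

    Draws ``n_candidates`` latents (or uses a provided pool), decodes them,
    ranks candidates by Pearson r(G(z), real) descending and returns the
    coordinate-wise mean of the top ``k`` latents together with the k
    correlation values (descending).
    """
    real = np.asarray(real_sample, dtype=float).ravel()
    if real.std() == 0:
        raise ValueError("cannot invert a constant (zero-variance) profile")
    if candidates is None:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        candidates = sample_latent(n_candidates, latent_spec, rng)
    else:
        candidates = np.atleast_2d(np.asarray(candidates, dtype=float))
    if k > candidates.shape[0]:
        raise ValueError(f"k={k} exceeds candidate pool of {candidates.shape[0]}")
    decoded = generator.decode(candidates)
    r = pearson_rows(decoded, real[None, :])[:, 0]
    order = np.argsort(-r, kind="stable")[:k]
    z_hat = candidates[order].mean(axis=0)
    return z_hat, r[order]


def condition_latent(
    generator,
    samples: np.ndarray,
    latent_spec: LatentSpec,
    n_candidates: int = 35000,
    k: int = 10,
    rng: np.random.Generator | int = 0,
    candidates: np.ndarray | None = None,
) -> np.ndarray:
    """Condition-level latent: mean of per-sample inversions.

    ``samples`` holds one profile per row. One candidate pool is drawn per
    call and shared by every sample of the condition, which makes the
    result invariant to sample order; pass ``candidates`` to reuse an
    external pool instead.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("condition has no samples")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if candidates is None:
        candidates = sample_latent(n_candidates, latent_spec, rng)
    zs = [
        invert_sample(
            generator, row, latent_spec, n_candidates, k, rng, candidates=candidates
        )[0]
        for row in samples
    ]
    return np.mean(zs, axis=0)


def transition_curve(
    generator, z_sn: np.ndarray, delta: np.ndarray, gene_ids=None
) -> Trajectory:
    """Decode the 100-point latent schedule z_i = z_SN + delta * i/100.

    Column T1 is G(z_SN) exactly (i = 0); the schedule stops one step short
    of z_CN (max mixing 0.99).
    """
    z_sn = np.asarray(z_sn, dtype=float).ravel()
    delta = np.asarray(delta, dtype=float).ravel()
    if z_sn.shape != delta.shape:
        raise ValueError("z_SN and delta dimensions differ")
    steps = np.arange(N_TIMEPOINTS) / 100.0
    zs = z_sn[None, :] + steps[:, None] * delta[None, :]
    # row-by-row decode keeps T1 bitwise equal to G(z_SN): batched matmul
    # may sum in a different order than a single-row decode
    decoded = np.vstack([generator.decode(z) for z in zs])  # (100, G)
    if gene_ids is None:
        gene_ids = [f"g{i + 1}" for i in range(decoded.shape[1])]
    values = pd.DataFrame(
        decoded.T, index=pd.Index(gene_ids, name="gene_id"), columns=_timepoint_columns()
    )
    return Trajectory(values)


def checkpoint_curve(
    checkpoint: Checkpoint,
    sn_profiles: np.ndarray,
    cn_profiles: np.ndarray,
    n_candidates: int = 35000,
    k: int = 10,
    rng: np.random.Generator | int = 0,
    gene_ids=None,
    share_candidates: bool = False,
    candidates: np.ndarray | None = None,
) -> Trajectory:
    """Invert both conditions under one checkpoint and decode the curve.

    By default each condition draws its own candidate pool from ``rng``;
    ``share_candidates=True`` uses one pool for both conditions, and an
    explicit ``candidates`` array overrides drawing entirely.
    """
    gen = checkpoint.generator()
    spec = checkpoint.latent_spec
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    pool = candidates
    if pool is None and share_candidates:
        pool = sample_latent(n_candidates, spec, rng)
    z_sn = condition_latent(gen, sn_profiles, spec, n_candidates, k, rng, candidates=pool)
    z_cn = condition_latent(gen, cn_profiles, spec, n_candidates, k, rng, candidates=pool)
    traj = transition_curve(gen, z_sn, z_cn - z_sn, gene_ids=gene_ids)
    traj.checkpoint_ids = (checkpoint.epoch,)
    return traj


def ensemble_curve(
    checkpoints: list[Checkpoint],
    sn_profiles: np.ndarray,
    cn_profiles: np.ndarray,
    n_candidates: int = 35000,
    k: int = 10,
    seed: int = 0,
    gene_ids=None,
    share_candidates: bool = False,
    shared_pool: bool = False,
    keep_members: bool = False,
) -> Trajectory | tuple[Trajectory, list[Trajectory]]:
    """Average the transition curve over several training checkpoints.

    Each checkpoint runs the full invert -> delta -> decode path with its
    own candidate draws (seeded reproducibly from ``seed``); the ensemble is
    the gene-wise, timepoint-wise arithmetic mean on the unit scale.
    ``shared_pool=True`` draws one candidate pool and reuses it for every
    checkpoint and condition (variance reduction; off by default).
    """
    if not checkpoints:
        raise ValueError("need at least one checkpoint")
    dims = {cp.net_spec.output_dim for cp in checkpoints}
    if len(dims) != 1:
        raise ValueError("checkpoints trained on mismatched gene sets")
    seeds = np.random.SeedSequence(seed).spawn(len(checkpoints) + 1)
    pool = None
    if shared_pool:
        pool = sample_latent(
            n_candidates, checkpoints[0].latent_spec, np.random.default_rng(seeds[-1])
        )
    members = [
        checkpoint_curve(
            cp,
            sn_profiles,
            cn_profiles,
            n_candidates,
            k,
            np.random.default_rng(s),
            gene_ids=gene_ids,
            share_candidates=share_candidates,
            candidates=pool,
        )
        for cp, s in zip(checkpoints, seeds[: len(checkpoints)])
    ]
    mean_values = sum(m.values for m in members) / len(members)
    ensemble = Trajectory(mean_values, tuple(cp.epoch for cp in checkpoints))
    if keep_members:
        return ensemble, members
    return ensemble
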