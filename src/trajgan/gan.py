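"""WGAN-GP training on unit-scaled expression profiles.

The critic is trained to maximize the Wasserstein surrogate
``mean critic(real) - mean critic(fake)`` subject to a soft 1-Lipschitz
constraint enforced by the gradient penalty
``lambda * mean((||grad critic(x_hat)|| - 1)^2)`` at points interpolated
uniformly between real and fake batches; the generator minimizes
``-mean critic(fake)``. Both networks are single-hidden-layer MLPs (widths
800 / 400 by default) updated with RMSprop.

Latent vectors mix Gaussian and Poisson coordinates: the first block is
standard normal, the second is Poisson(rate) standardized to zero mean and
unit variance so all coordinates live on comparable scales.

Generated profiles can be realism-filtered: a fake is kept only when its
best Pearson correlation against the real samples reaches ``r_min``
(default 0.95).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import MLPCritic, MLPGenerator, RMSProp

logger = logging.getLogger(__name__)


@dataclass
class NetworkSpec:
    """Architecture of the generator/critic pair."""

    output_dim: int
    latent_dim: int = 128
    generator_hidden: int = 800
    critic_hidden: int = 400
    init_range: tuple[float, float] = (-0.3, 0.3)

    def __post_init__(self) -> None:
        for name in ("output_dim", "latent_dim", "generator_hidden", "critic_hidden"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.init_range
        if not (lo < 0 < hi) or abs(lo + hi) > 1e-12:
            raise ValueError("init_range must be a symmetric interval around 0")


@dataclass
class LatentSpec:
    """Dimension split of the Gaussian/Poisson latent mixture."""

    dim: int
    gaussian_dims: int | None = None
    poisson_dims: int | None = None
    poisson_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.dim <= 0:
            raise ValueError("latent dim must be positive")
        if self.gaussian_dims is None and self.poisson_dims is None:
            # half/half split; Gaussian block takes the extra coordinate
            self.poisson_dims = self.dim // 2
            self.gaussian_dims = self.dim - self.poisson_dims
        elif self.gaussian_dims is None:
            self.gaussian_dims = self.dim - self.poisson_dims
        elif self.poisson_dims is None:
            self.poisson_dims = self.dim - self.gaussian_dims
        if self.gaussian_dims < 0 or self.poisson_dims < 0:
            raise ValueError("negative latent block size")
        if self.gaussian_dims + self.poisson_dims != self.dim:
            raise ValueError("gaussian_dims + poisson_dims must equal dim")
        if self.poisson_rate <= 0:
            raise ValueError("poisson_rate must be positive")


@dataclass
class TrainConfig:
    """Optimization schedule; defaults follow common WGAN-GP practice."""

    batch_size: int = 32
    critic_steps_per_gen_step: int = 5
    gp_weight: float = 10.0
    learning_rate: float = 5e-5
    total_epochs: int = 30000
    checkpoint_epochs: tuple[int, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size <= 0 or self.critic_steps_per_gen_step <= 0:
            raise ValueError("batch size and critic steps must be positive")
        if self.gp_weight <= 0 or self.learning_rate <= 0:
            raise ValueError("gp_weight and learning_rate must be positive")
        if self.total_epochs <= 0:
            raise ValueError("total_epochs must be positive")
        cps = tuple(sorted(self.checkpoint_epochs))
        if cps and (cps[0] < 1 or cps[-1] > self.total_epochs):
            raise ValueError("checkpoint_epochs must lie in [1, total_epochs]")
        self.checkpoint_epochs = cps


def config_fingerprint(net_spec: NetworkSpec, latent_spec: LatentSpec, config: TrainConfig) -> str:
    payload = json.dumps(
        [vars(net_spec), vars(latent_spec), vars(config)], sort_keys=True, default=str
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Checkpoint:
    """A reloadable snapshot of both networks at a given epoch."""

    generator_params: dict[str, np.ndarray]
    critic_params: dict[str, np.ndarray]
    epoch: int
    net_spec: NetworkSpec
    latent_spec: LatentSpec
    fingerprint: str = ""

    def generator(self) -> MLPGenerator:
        gen = MLPGenerator(
            self.net_spec.latent_dim,
            self.net_spec.generator_hidden,
            self.net_spec.output_dim,
            self.net_spec.init_range,
            np.random.default_rng(0),
        )
        gen.params = {k: v.copy() for k, v in self.generator_params.items()}
        return gen

    def critic(self) -> MLPCritic:
        critic = MLPCritic(
            self.net_spec.output_dim,
            self.net_spec.critic_hidden,
            self.net_spec.init_range,
            np.random.default_rng(0),
        )
        critic.params = {k: v.copy() for k, v in self.critic_params.items()}
        return critic

    def save(self, path: str | Path) -> None:
        arrays = {f"gen_{k}": v for k, v in self.generator_params.items()}
        arrays.update({f"crit_{k}": v for k, v in self.critic_params.items()})
        meta = json.dumps(
            {
                "epoch": self.epoch,
                "fingerprint": self.fingerprint,
                "net_spec": vars(self.net_spec),
                "latent_spec": vars(self.latent_spec),
            }
        )
        np.savez(path, _meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            gen = {k[4:]: data[k].copy() for k in data.files if k.startswith("gen_")}
            crit = {k[5:]: data[k].copy() for k in data.files if k.startswith("crit_")}
        ns = meta["net_spec"]
        ns["init_range"] = tuple(ns["init_range"])
        return cls(
            generator_params=gen,
            critic_params=crit,
            epoch=meta["epoch"],
            net_spec=NetworkSpec(**ns),
            latent_spec=LatentSpec(**meta["latent_spec"]),
            fingerprint=meta["fingerprint"],
        )


def sample_latent(n: int, spec: LatentSpec, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ``n`` latent rows: standard-normal block, then standardized
    Poisson block ``(k - rate) / sqrt(rate)``."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    z = np.empty((n, spec.dim))
    z[:, : spec.gaussian_dims] = rng.standard_normal((n, spec.gaussian_dims))
    if spec.poisson_dims:
        k = rng.poisson(spec.poisson_rate, size=(n, spec.poisson_dims))
        z[:, spec.gaussian_dims :] = (k - spec.poisson_rate) / np.sqrt(spec.poisson_rate)
    return z


def init_networks(spec: NetworkSpec, seed: int) -> tuple[MLPGenerator, MLPCritic]:
    """Fresh generator and critic with weights uniform in ``init_range``."""
    rng = np.random.default_rng(seed)
    gen = MLPGenerator(
        spec.latent_dim, spec.generator_hidden, spec.output_dim, spec.init_range, rng
    )
    critic = MLPCritic(spec.output_dim, spec.critic_hidden, spec.init_range, rng)
    return gen, critic


def gradient_penalty(critic, real_batch: np.ndarray, fake_batch: np.ndarray, rng) -> float:
    """Mean squared deviation of the critic's input-gradient norm from 1 at
    points interpolated uniformly between paired real and fake samples.

    ``critic`` needs only an ``input_grad(x)`` method returning per-sample
    gradients, so analytic critics can be plugged in directly.
    """
    real_batch = np.atleast_2d(real_batch)
    fake_batch = np.atleast_2d(fake_batch)
    if real_batch.shape != fake_batch.shape:
        raise ValueError("real and fake batches must have the same shape")
    if real_batch.shape[0] == 0:
        raise ValueError("empty batch")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    eps = rng.uniform(size=(real_batch.shape[0], 1))
    xhat = eps * real_batch + (1.0 - eps) * fake_batch
    norms = np.sqrt((critic.input_grad(xhat) ** 2).sum(axis=1))
    return float(((norms - 1.0) ** 2).mean())


def train_wgan_gp(
    training_matrix,
    net_spec: NetworkSpec,
    latent_spec: LatentSpec,
    config: TrainConfig,
) -> tuple[list[Checkpoint], pd.DataFrame]:
    """Train the pair and return checkpoints plus a per-epoch loss log.

    ``training_matrix`` is a unit-scale ExpressionMatrix (genes x samples)
    or an array of sample rows. An "epoch" is one generator update preceded
    by ``critic_steps_per_gen_step`` critic updates, each on a fresh batch.
    Training is deterministic under a fixed seed, data and platform. A
    non-finite loss aborts with the offending epoch in the message.
    """
    from .containers import ExpressionMatrix

    if isinstance(training_matrix, ExpressionMatrix):
        if training_matrix.scale != "unit":
            raise ValueError("training matrix must be unit scale")
        X = training_matrix.data.to_numpy().T.astype(float)
    else:
        X = np.atleast_2d(np.asarray(training_matrix, dtype=float))
    if X.shape[1] != net_spec.output_dim:
        raise ValueError(
            f"training data has {X.shape[1]} genes; net_spec.output_dim is {net_spec.output_dim}"
        )
    if X.shape[0] < 1:
        raise ValueError("need at least one training sample")
    if latent_spec.dim != net_spec.latent_dim:
        raise ValueError("latent_spec.dim must match net_spec.latent_dim")

    rng = np.random.default_rng(config.seed)
    gen, critic = init_networks(net_spec, seed=int(rng.integers(2**31)))
    opt_g = RMSProp(gen.params, config.learning_rate)
    opt_c = RMSProp(critic.params, config.learning_rate)

    n = X.shape[0]
    batch = min(config.batch_size, n)
    fingerprint = config_fingerprint(net_spec, latent_spec, config)
    checkpoints: list[Checkpoint] = []
    checkpoint_set = set(config.checkpoint_epochs)
    log_rows = []

    for epoch in range(1, config.total_epochs + 1):
        critic_loss = gp_value = np.nan
        for _ in range(config.critic_steps_per_gen_step):
            idx = rng.choice(n, size=batch, replace=n < batch)
            real = X[idx]
            z = sample_latent(batch, latent_spec, rng)
            fake = gen.decode(z)

            s_fake, cache_f = critic.forward(fake)
            s_real, cache_r = critic.forward(real)
            ds = np.full(batch, 1.0 / batch)
            grads = critic.backward(cache_f, ds)  # + mean s(fake)
            grads_r = critic.backward(cache_r, -ds)  # - mean s(real)
            eps = rng.uniform(size=(batch, 1))
            xhat = eps * real + (1.0 - eps) * fake
            gp_value, gp_grads = critic.gp_value_and_grads(xhat)
            for k in grads:
                grads[k] += grads_r[k] + config.gp_weight * gp_grads[k]
            opt_c.step(critic.params, grads)
            critic_loss = float(s_fake.mean() - s_real.mean() + config.gp_weight * gp_value)

        z = sample_latent(batch, latent_spec, rng)
        fake, cache_g = gen.forward(z)
        gen_loss = float(-critic.score(fake).mean())
        dx = -critic.input_grad(fake) / batch
        opt_g.step(gen.params, gen.backward(cache_g, dx))

        if not (np.isfinite(critic_loss) and np.isfinite(gen_loss)):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: critic={critic_loss}, gen={gen_loss}"
            )
        log_rows.append(
            {"epoch": epoch, "critic_loss": critic_loss, "gen_loss": gen_loss, "gp": gp_value}
        )
        if epoch in checkpoint_set:
            checkpoints.append(
                Checkpoint(
                    generator_params={k: v.copy() for k, v in gen.params.items()},
                    critic_params={k: v.copy() for k, v in critic.params.items()},
                    epoch=epoch,
                    net_spec=net_spec,
                    latent_spec=latent_spec,
                    fingerprint=fingerprint,
                )
            )
    return checkpoints, pd.DataFrame(log_rows)


def pearson_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``A`` and every row of ``B``.

    Rows with zero variance correlate 0 with everything (logged upstream).
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((Ac**2).sum(axis=1))
    nb = np.sqrt((Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac @ Bc.T) / np.outer(na, nb)
    r[~np.isfinite(r)] = 0.0
    return r


def filter_fakes(
    fakes: np.ndarray, reals: np.ndarray, r_min: float = 0.95
) -> tuple[np.ndarray, pd.DataFrame]:
    """Keep fakes whose best Pearson r against any real sample reaches
    ``r_min``; returns the retained rows and a per-fake best-match record.

    Constant fakes (undefined r) are treated as r = 0 and logged.
    """
    fakes = np.atleast_2d(np.asarray(fakes, dtype=float))
    reals = np.atleast_2d(np.asarray(reals, dtype=float))
    if fakes.shape[1] != reals.shape[1]:
        raise ValueError("fakes and reals must share the gene set")
    n_const = int((fakes.std(axis=1) == 0).sum())
    if n_const:
        logger.warning("%d constant fake profiles; treating their r as 0", n_const)
    r = pearson_rows(fakes, reals)
    best = r.argmax(axis=1)
    best_r = r[np.arange(r.shape[0]), best]
    record = pd.DataFrame(
        {
            "fake_index": np.arange(fakes.shape[0]),
            "best_real_index": best,
            "best_r": best_r,
            "retained": best_r >= r_min,
        }
    )
    return fakes[best_r >= r_min], record
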