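"""WGAN-GP machinery: latents, initialization, penalties, training."""

import numpy as np
import pandas as pd
import pytest

from trajgan.gan import (
    Checkpoint,
    LatentSpec,
    NetworkSpec,
    TrainConfig,
    filter_fakes,
    gradient_penalty,
    init_networks,
    pearson_rows,
    sample_latent,
    train_wgan_gp,
)
from trajgan.nn import MLPCritic, MLPGenerator


class _LinearCritic:
    """Analytic critic s(x) = <w, x> for penalty tests."""

    def __init__(self, w):
        self.w = np.asarray(w, dtype=float)

    def input_grad(self, x):
        return np.tile(self.w, (np.atleast_2d(x).shape[0], 1))


class TestSampleLatent:
    def test_standardized_moments(self):
        spec = LatentSpec(dim=64, gaussian_dims=32, poisson_dims=32, poisson_rate=1.0)
        z = sample_latent(10**5, spec, 0)
        assert z.shape == (10**5, 64)
        assert np.abs(z.mean(axis=0)).max() < 0.02
        assert 0.95 < z.var(axis=0).min() and z.var(axis=0).max() < 1.05

    def test_poisson_block_is_discrete_gaussian_is_not(self):
        spec = LatentSpec(dim=8, gaussian_dims=4, poisson_dims=4, poisson_rate=1.0)
        z = sample_latent(1000, spec, 1)
        lattice = (z[:, 4:] * 1.0 + 1.0)  # (k - 1)/1 + 1 = k, integers
        assert np.allclose(lattice, np.round(lattice))
        assert not np.allclose(z[:, :4], np.round(z[:, :4]))

    def test_deterministic_and_pure_gaussian(self):
        spec = LatentSpec(dim=6, gaussian_dims=6, poisson_dims=0)
        np.testing.assert_array_equal(
            sample_latent(50, spec, 3), sample_latent(50, spec, 3)
        )
        with pytest.raises(ValueError):
            sample_latent(0, spec, 0)

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            LatentSpec(dim=4, gaussian_dims=3, poisson_dims=3)
        with pytest.raises(ValueError):
            LatentSpec(dim=4, poisson_rate=0.0)


class TestInitNetworks:
    SPEC = NetworkSpec(output_dim=12, latent_dim=5, generator_hidden=7, critic_hidden=4)

    def test_weights_within_init_range(self):
        gen, critic = init_networks(self.SPEC, 0)
        for params in (gen.params, critic.params):
            for name, value in params.items():
                assert np.abs(value).max() <= 0.3

    def test_generator_output_in_unit_interval(self):
        gen, _ = init_networks(self.SPEC, 0)
        z = np.random.default_rng(1).normal(scale=50, size=(20, 5))
        x = gen.decode(z)
        assert x.min() > 0 and x.max() < 1

    def test_same_seed_identical_parameters(self):
        a, _ = init_networks(self.SPEC, 9)
        b, _ = init_networks(self.SPEC, 9)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])


class TestGradientPenalty:
    def _batches(self, dim=6, n=5, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(size=(n, dim)), rng.uniform(size=(n, dim))

    def test_unit_gradient_linear_critic_zero(self):
        real, fake = self._batches()
        w = np.zeros(6)
        w[0] = 1.0  # ||w|| = 1
        assert gradient_penalty(_LinearCritic(w), real, fake, 0) == pytest.approx(0.0)

    def test_constant_critic_one(self):
        real, fake = self._batches()
        assert gradient_penalty(_LinearCritic(np.zeros(6)), real, fake, 0) == pytest.approx(1.0)

    def test_gradient_norm_two_gives_one(self):
        real, fake = self._batches()
        w = np.zeros(6)
        w[0] = 2.0  # ||grad|| = 2 -> (2 - 1)^2 = 1
        assert gradient_penalty(_LinearCritic(w), real, fake, 0) == pytest.approx(1.0)

    def test_nonnegative_for_mlp_critic(self):
        real, fake = self._batches(dim=10)
        _, critic = init_networks(NetworkSpec(output_dim=10, latent_dim=4), 2)
        assert gradient_penalty(critic, real, fake, 0) >= 0.0

    def test_errors(self):
        real, fake = self._batches()
        with pytest.raises(ValueError):
            gradient_penalty(_LinearCritic(np.ones(6)), real, fake[:3], 0)
        with pytest.raises(ValueError):
            gradient_penalty(
                _LinearCritic(np.ones(6)), real[:0], fake[:0], 0
            )


class TestAnalyticGradients:
    """Hand-derived backprop vs central finite differences."""

    def _finite_diff(self, params, key, loss, eps=1e-6):
        num = np.zeros_like(params[key])
        it = np.nditer(params[key], flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            params[key][i] += eps
            up = loss()
            params[key][i] -= 2 * eps
            down = loss()
            params[key][i] += eps
            num[i] = (up - down) / (2 * eps)
        return num

    def test_critic_score_gradients(self):
        rng = np.random.default_rng(0)
        _, critic = init_networks(NetworkSpec(output_dim=7, latent_dim=3, critic_hidden=4), 1)
        x = rng.uniform(size=(8, 7))
        _, cache = critic.forward(x)
        grads = critic.backward(cache, np.full(8, 1 / 8))
        for k, g in grads.items():
            num = self._finite_diff(critic.params, k, lambda: critic.score(x).mean())
            np.testing.assert_allclose(num, g, atol=1e-7)

    def test_penalty_gradients(self):
        rng = np.random.default_rng(1)
        _, critic = init_networks(NetworkSpec(output_dim=7, latent_dim=3, critic_hidden=4), 1)
        xhat = rng.uniform(size=(8, 7))
        _, grads = critic.gp_value_and_grads(xhat)
        for k in ("V1", "v2"):
            num = self._finite_diff(
                critic.params, k, lambda: critic.gp_value_and_grads(xhat)[0]
            )
            np.testing.assert_allclose(num, grads[k], atol=1e-6)

    def test_generator_gradients_through_critic(self):
        rng = np.random.default_rng(2)
        gen, critic = init_networks(
            NetworkSpec(output_dim=7, latent_dim=5, generator_hidden=6, critic_hidden=4), 3
        )
        z = rng.standard_normal((8, 5))
        fake, cache = gen.forward(z)
        grads = gen.backward(cache, -critic.input_grad(fake) / 8)
        for k, g in grads.items():
            num = self._finite_diff(
                gen.params, k, lambda: -critic.score(gen.decode(z)).mean()
            )
            np.testing.assert_allclose(num, g, atol=1e-7)

    def test_input_grad(self):
        rng = np.random.default_rng(3)
        _, critic = init_networks(NetworkSpec(output_dim=5, latent_dim=3, critic_hidden=4), 4)
        x = rng.uniform(size=(2, 5))
        analytic = critic.input_grad(x)
        eps = 1e-6
        for b in range(2):
            for j in range(5):
                xp, xm = x.copy(), x.copy()
                xp[b, j] += eps
                xm[b, j] -= eps
                num = (critic.score(xp)[b] - critic.score(xm)[b]) / (2 * eps)
                assert num == pytest.approx(analytic[b, j], abs=1e-7)


class TestTraining:
    NET = NetworkSpec(output_dim=6, latent_dim=4, generator_hidden=8, critic_hidden=6)
    LAT = LatentSpec(dim=4)

    def test_wasserstein_loss_zero_on_identical_batches(self):
        _, critic = init_networks(self.NET, 0)
        batch = np.random.default_rng(0).uniform(size=(10, 6))
        s = critic.score(batch)
        assert s.mean() - s.mean() == 0.0  # identical real/fake, no penalty

    def test_deterministic_loss_log(self):
        X = np.random.default_rng(1).uniform(size=(12, 6))
        config = TrainConfig(
            batch_size=8, learning_rate=1e-3, total_epochs=50, checkpoint_epochs=(50,), seed=5
        )
        _, log_a = train_wgan_gp(X, self.NET, self.LAT, config)
        _, log_b = train_wgan_gp(X, self.NET, self.LAT, config)
        pd.testing.assert_frame_equal(log_a, log_b)
        assert np.isfinite(log_a[["critic_loss", "gen_loss", "gp"]].to_numpy()).all()

    def test_constant_profile_convergence(self):
        target = np.full((1, 6), 0.3)
        config = TrainConfig(
            batch_size=8, learning_rate=1e-3, total_epochs=500, checkpoint_epochs=(1, 500), seed=0
        )
        checkpoints, _ = train_wgan_gp(target, self.NET, self.LAT, config)
        z = sample_latent(100, self.LAT, 9)
        mad_start = np.abs(checkpoints[0].generator().decode(z) - target).mean()
        mad_end = np.abs(checkpoints[1].generator().decode(z) - target).mean()
        assert mad_end < mad_start

    def test_two_cluster_fakes_near_reals(self, two_cluster_data, two_cluster_gan):
        """Trained fakes should sit next to real samples in correlation."""
        gen = two_cluster_gan["checkpoints"][-1].generator()
        fakes = gen.decode(sample_latent(500, two_cluster_gan["latent"], 7))
        best = pearson_rows(fakes, two_cluster_data["X"]).max(axis=1)
        assert (best >= 0.9).mean() >= 0.9

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(total_epochs=10, checkpoint_epochs=(11,))
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


class TestCheckpoint:
    def test_save_load_decode_bitwise(self, tmp_path, two_cluster_gan):
        cp = two_cluster_gan["checkpoints"][-1]
        path = tmp_path / "cp.npz"
        cp.save(path)
        loaded = Checkpoint.load(path)
        assert loaded.epoch == cp.epoch
        assert loaded.fingerprint == cp.fingerprint
        z = sample_latent(20, two_cluster_gan["latent"], 11)
        np.testing.assert_array_equal(
            cp.generator().decode(z), loaded.generator().decode(z)
        )


class TestFilterFakes:
    def test_real_sample_retained(self):
        rng = np.random.default_rng(0)
        reals = rng.uniform(size=(5, 8))
        fakes = np.vstack([reals[2], rng.uniform(size=8)])
        kept, record = filter_fakes(fakes, reals, r_min=0.95)
        assert record.loc[0, "best_r"] == pytest.approx(1.0)
        assert record.loc[0, "retained"]

    def test_anticorrelated_rejected(self):
        rng = np.random.default_rng(1)
        reals = rng.uniform(size=(1, 8))
        flipped = 2 * reals.mean(axis=1, keepdims=True) - reals  # sign-flipped deviations
        kept, record = filter_fakes(flipped, reals, r_min=0.95)
        assert record.loc[0, "best_r"] == pytest.approx(-1.0)
        assert kept.shape[0] == 0

    def test_vacuous_threshold_keeps_all(self):
        rng = np.random.default_rng(2)
        fakes, reals = rng.uniform(size=(10, 8)), rng.uniform(size=(4, 8))
        kept, _ = filter_fakes(fakes, reals, r_min=-1.0)
        assert kept.shape[0] == 10

    def test_constant_fake_logged_as_zero(self, caplog):
        reals = np.random.default_rng(3).uniform(size=(3, 8))
        with caplog.at_level("WARNING"):
            _, record = filter_fakes(np.full((1, 8), 0.5), reals, r_min=0.95)
        assert record.loc[0, "best_r"] == 0.0
        assert "constant" in caplog.text
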