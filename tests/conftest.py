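import numpy as np
import pytest

from trajgan import (
    LatentSpec,
    NetworkSpec,
    SimulationConfig,
    TrainConfig,
    simulate_dataset,
    train_wgan_gp,
)


@pytest.fixture(scope="session")
def sim_dataset():
    """Small two-region dataset with a strong planted effect."""
    config = SimulationConfig(
        n_genes=80,
        n_regions=2,
        conditions=("SN", "CN", "SS"),
        replicates_per_group=4,
        n_effect_genes=10,
        effect_log2fc=2.0,
        dispersion=0.1,
        seed=11,
    )
    return config, simulate_dataset(config)


@pytest.fixture(scope="session")
def two_cluster_data():
    """Unit-scale profiles in two clusters around 0.2 and 0.8.

    The treated cluster shifts half of the genes by +0.6 on top of the
    control cluster's cross-gene pattern — the geometry the pipeline
    assumes: a condition effect carried by a subset of genes, leaving a
    pattern difference that correlation-based inversion can resolve.
    """
    rng = np.random.default_rng(42)
    n_genes = 20
    center_a = rng.uniform(0.05, 0.35, n_genes)
    shift = np.zeros(n_genes)
    shift[n_genes // 2 :] = 0.6
    center_b = center_a + shift
    noise = 0.02
    X = np.vstack(
        [
            np.clip(center_a + noise * rng.standard_normal((30, n_genes)), 0, 1),
            np.clip(center_b + noise * rng.standard_normal((30, n_genes)), 0, 1),
        ]
    )
    return {
        "X": X,
        "center_a": center_a,
        "center_b": center_b,
        "shifted": shift > 0,
        "n_genes": n_genes,
    }


@pytest.fixture(scope="session")
def two_cluster_gan(two_cluster_data):
    """WGAN-GP trained on the two-cluster toy data (desk scale)."""
    net = NetworkSpec(
        output_dim=two_cluster_data["n_genes"],
        latent_dim=8,
        generator_hidden=32,
        critic_hidden=16,
    )
    latent = LatentSpec(dim=8)
    config = TrainConfig(
        batch_size=16,
        learning_rate=1e-3,
        total_epochs=6000,
        checkpoint_epochs=(5500, 6000),
        seed=42,
    )
    checkpoints, loss_log = train_wgan_gp(two_cluster_data["X"], net, latent, config)
    return {
        "checkpoints": checkpoints,
        "loss_log": loss_log,
        "net": net,
        "latent": latent,
        "config": config,
    }
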