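# trajgan

Bulk RNA-seq measures a transcriptome only at the time points an experiment
sampled — typically a control state and a treated end state. `trajgan`
synthesizes the *hidden intermediate expression states* between two such
conditions by training a Wasserstein GAN with gradient penalty (WGAN-GP) on
expression profiles and walking a straight line through its latent space.
It is aimed at analysts with small replicated designs (a handful of
biological replicates per group, e.g. brain-region panels from drug
self-administration studies) who want a pseudo-temporal view of a
control → treated transition and the gene-trend statistics that fall out of
it.

## Method

1. **Normalization and filtering.** Counts are converted to RPKM for
   filtering (keep genes with RPKM ≥ 1 in ≥ 80 % of the samples of every
   (region, condition) group), then to offset log-CPM,
   `log2((c + 0.5)/(lib + 1)·10⁶)`, for everything downstream.
2. **Tenfold augmentation.** Every group of *n* replicates is expanded by
   its C(*n*, 2) unordered pairs and nine convex combinations per pair,
   `S_aug = x·S1 + (1 − x)·S2`, `x = 0.1 … 0.9` — a group of six gains
   9 × 15 = 135 profiles. A t-SNE co-clustering score quantifies that
   augmented samples stay with their source group.
3. **WGAN-GP.** After per-gene min-max scaling to [0, 1], a
   single-hidden-layer generator (800 units) and critic (400 units) are
   trained with the WGAN-GP losses and RMSprop; weights start uniform in
   [−0.3, 0.3] and latents mix standard-normal with standardized Poisson
   coordinates.
4. **Latent inversion and transition curve.** Each real sample is inverted
   by decoding a large candidate pool (35,000 by default), ranking
   candidates by Pearson r against the sample, and averaging the 10 best
   latents. Condition-level latents `z_SN`, `z_CN` are the means over each
   condition's samples; decoding `z_i = z_SN + δ·i/100` (`δ = z_CN − z_SN`,
   `i = 0 … 99`) gives a 100-point curve T1–T100, ensemble-averaged over
   checkpoints from different training epochs.
5. **Trend statistics.** The curve is split into early/mid/late thirds;
   each interval is summarized by its geometric-mean expression
   (`2^(mean log2)`) and reported as Log2FC against the real control
   samples' geometric mean. Genes with Log2FC > 0.2 in an interval are
   flagged as differentially expressed; pairwise Pearson correlation of
   trajectories gives gene–gene coregulation matrices.

A synthetic-data module generates negative-binomial count matrices with the
same design structure (regions × conditions × 3–6 replicates) and planted
log2 fold-change effects, so the whole pipeline can be exercised and its
recovery quantified without access to any private dataset.

## Worked example

Recover a planted +1 log2 condition effect end to end (desk-scale network,
~20 s on one CPU):

```python
from trajgan import (
    SimulationConfig, simulate_dataset, region_trend_pipeline,
    NetworkSpec, LatentSpec, TrainConfig,
)

config = SimulationConfig(
    n_genes=200, n_regions=1, conditions=("SN", "CN"),
    replicates_per_group=6, n_effect_genes=20, effect_log2fc=1.0,
    dispersion=0.1, seed=1,
)
dataset = simulate_dataset(config)

result = region_trend_pipeline(
    dataset.counts, dataset.samples, dataset.genes, region="BLA",
    net_spec=NetworkSpec(output_dim=200, latent_dim=32,
                         generator_hidden=64, critic_hidden=32),
    latent_spec=LatentSpec(dim=32),
    train_config=TrainConfig(batch_size=32, learning_rate=1e-3,
                             total_epochs=3000,
                             checkpoint_epochs=(2000, 2500, 3000), seed=1),
    n_candidates=3000, k=10, seed=1,
)

late = result.trend["log2fc_late"]
planted = sorted(dataset.truth.effect_genes)
null = [g for g in result.retained_genes if g not in dataset.truth.effect_genes]
print(f"planted genes recovered: {(late[planted] > 0).mean():.0%}")
print(f"median late Log2FC:      planted {late[planted].median():.3f}  null {late[null].median():.3f}")
print(result.trend.loc[planted[:3]].round(3).to_string())
```

prints

```
planted genes recovered: 100%
median late Log2FC:      planted 1.013  null -0.145
         log2fc_early  de_early  log2fc_mid  de_mid  log2fc_late  de_late
gene_id
g0018           0.153     False       0.163   False        0.621     True
g0026           0.069     False       0.783    True        1.340     True
g0036           0.274      True       0.584    True        1.199     True
```

Every planted gene ends the pseudo-time curve with a positive late-interval
Log2FC near the planted +1, rising through the early/mid/late intervals,
while unperturbed genes stay near zero. The same pipeline is scriptable
from the shell via the `trajgan` CLI (`simulate`, `preprocess`, `augment`,
`train`, `generate`, `trajectory`, `trend`, `coreg`); see `trajgan --help`.

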