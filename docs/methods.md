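# Methods

## Model and procedure

`trajgan` treats the transcriptome's transition between two conditions —
a saline control ("SN") and a chronic-treatment state ("CN") — as a path
through the latent space of a generative model trained on expression
profiles. The procedure assumes:

* expression profiles of a (region, condition) group are exchangeable
  replicates of one underlying state, so convex combinations of two
  replicates are plausible profiles of the same state (the basis of the
  tenfold pairwise augmentation);
* a WGAN-GP trained on the pooled (original + augmented) profiles of a
  region learns a latent manifold on which both conditions live;
* the straight latent segment from the control-level latent `z_SN` toward
  `z_CN = z_SN + δ` decodes to biologically meaningful intermediate
  states. This is the core modeling assumption and is not testable from
  two-time-point data itself; the package quantifies only that the
  endpoints are faithful and that planted effects are recovered.

The latent schedule is `z_i = z_SN + δ·i/100` for `i = 0 … 99`, giving
time points T1–T100. The schedule deliberately stops at `0.99·δ` — it is
kept exactly as specified rather than "corrected" to `i/99` — so T100
approaches but never equals the decoded treated state.

### Normalization

RPKM (`count / (library/10⁶) / (length/10³)`) is used only for filtering:
a gene is retained when, in **every** (region, condition) group, at least
`ceil(0.8·n)` of the group's samples have RPKM ≥ 1. The per-group rule is
read strictly ("every group"); `mode="any"` restores the lenient reading.
Training values are offset log-CPM, `log2((c + 0.5)/(lib + 1)·10⁶)` — the
deterministic core of a voom-style transform. Voom's precision weights are
not computed because nothing downstream consumes them; this keeps the
normalization reproducible without any R dependency. The library size is
the column sum of the full input count matrix, computed before gene
restriction.

### Augmentation and scaling

Augmentation operates on the log2-CPM scale *before* min-max scaling; the
order is pinned (normalize → augment → fit/apply scaler) and is harmless
to revisit because per-gene min-max scaling is affine, so scaling and
convex interpolation commute exactly (asserted to 10⁻¹⁰ in the tests).
Min-max parameters are fitted per gene on the pooled original + augmented
matrix. Constant genes map to 0 on the unit scale (not NaN) and invert
back to their constant. Applying the scaler to data outside the fitted
range is allowed to leave [0, 1]; it is flagged with a warning, never
clamped.

The t-SNE QC embedding replaces a visual inspection with a number: the
fraction of augmented samples whose nearest *original* neighbor in the
embedding shares their group label. It is reported, not thresholded —
t-SNE is stochastic, so the seed is part of the record, and the perplexity
is auto-reduced (with a warning) when fewer than `3·perplexity + 1`
samples are available.

### Networks and training

Both networks are single-hidden-layer fully connected MLPs: generator
`latent → 800 → genes` with LeakyReLU(0.2) hidden activation and a sigmoid
output (matching the [0, 1] data), critic `genes → 400 → 1` with no output
activation. Weights initialize uniform in [−0.3, 0.3]; biases start at 0.
Latent vectors split half/half into standard-normal and Poisson(1)
coordinates, the Poisson block standardized as `(k − λ)/√λ` so all
coordinates share scale. Depth beyond the stated widths, the activation
choice and the latent dimension (default 128) are package defaults — they
are not constrained by the method description the package implements.

The implementation is pure NumPy (float64) with hand-derived
backpropagation. For the gradient penalty
`λ·mean((‖∇_x̂ critic(x̂)‖₂ − 1)²)` at `x̂ = ε·x_real + (1 − ε)·x_fake`,
the parameter gradients treat the LeakyReLU activation pattern as locally
constant; since the activation's second derivative is zero almost
everywhere, this is exactly what reverse-mode autodiff computes. All
gradients (score, penalty, generator-through-critic) are verified against
central finite differences in the test suite at 10⁻⁶–10⁻⁷ absolute
tolerance.

Training hyperparameters not fixed by the method description are pinned to
WGAN-GP conventions and exposed in `TrainConfig`: penalty weight λ = 10,
5 critic steps per generator step, RMSprop (accumulator smoothing 0.99,
eps 10⁻⁸) with learning rate 5·10⁻⁵, batch size 32. One "epoch" is one
generator update preceded by the critic steps, each on a fresh random
batch. A non-finite loss aborts with the offending epoch. Checkpoints
(generator + critic parameters, epoch, config fingerprint) round-trip
through `.npz` files bitwise.

The 0.95 Pearson realism filter (`filter_fakes`) applies wherever fakes
are exported (`trajgan generate`); the inversion path does not filter its
candidate pool by default — its correlation ranking already prefers
realistic decodes — but the same function can be applied to candidates if
desired. Constant (zero-variance) profiles have undefined correlation and
are treated as r = 0 with a logged warning.

### Inversion, trajectory, trend

Inversion ranks decoded candidates by Pearson r with the real sample
(descending, stable sort for ties) and averages the top k = 10 latents.
Note a consequence of using correlation: the inversion resolves
*pattern* differences between conditions, not uniform level shifts — a
condition effect must alter the relative profile of at least some genes to
be recoverable, which is the biologically relevant case (a subset of
responsive genes).

The condition-level latent is the coordinate-wise mean of per-sample
inversions, computed per region. One candidate pool is drawn per
condition per checkpoint, shared by that condition's samples — this makes
the result invariant to sample order; `shared_pool=True` reuses one pool
across all checkpoints and conditions for variance reduction (off by
default, matching fresh-per-checkpoint draws). Per-checkpoint seeds derive
from the run seed via `SeedSequence.spawn`, so the whole
inversion → delta → decode path is deterministic given the seed and the
checkpoints. The curve decodes the schedule row by row rather than as one
batched matrix product so that T1 equals `G(z_SN)` bitwise (batched BLAS
may sum in a different order).

The early/mid/late intervals are pinned to the half-open partition
[1, 34), [34, 67), [67, 100] — sizes 33/33/34 — because the published
interval bounds share their endpoints; `overlapping=True` restores the
literal shared-endpoint reading. Interval summaries are geometric means
computed on the linear scale, as `2^(mean of log2 values)`; no pseudo-count
is needed because `2^v` is always positive (a naive geometric mean of
log-scale values, which can be negative, would be invalid). The Log2FC
baseline is the real SN samples' linear-scale geometric mean for the
region — anchoring trends to observed data rather than a decoded endpoint;
anchoring to T1 is available by passing that column's summary as baseline.
The DE flag is one-sided (`Log2FC > 0.2`, upregulation); a symmetric
absolute-value option exists. In coregulation matrices the asterisk mask
marks pairs whose *both* genes exceed 0.2 in at least one interval, and
the "colored" mask marks genes with any-interval Log2FC > 0.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes: a
regions × conditions design (conditions must include SN and CN) with 3–6
replicates per group, negative-binomial counts with mean `μ_g` drawn
log-uniformly from `baseline_mean_range` (default 20–2000 expected counts)
and a single shared dispersion α (default 0.1, `var = μ + αμ²` — a typical
bulk RNA-seq value), and a chosen subset of genes whose CN mean is shifted
by `2^effect_log2fc`. All non-CN conditions sit at baseline. Gene lengths
are log-normal around `mean_length_bp` (default 2000 bp, σ = 0.25); they
matter only through RPKM. Output is bitwise reproducible under a fixed
seed.

It deliberately does **not** model batch effects, library-preparation
biases, gene–gene correlation within a condition, region-specific
expression structure, or per-gene dispersion variation. Passing recovery
tests therefore demonstrates that the pipeline's machinery is correct and
sensitive under clean overdispersed replication — not that it is robust to
the confounders of real count data.

## Problem sizes used in tests and the acceptance script

Desk-scale settings keep the full end-to-end path cheap while preserving
every stage: 200 genes with 20 planted at +1 log2 (dispersion 0.1, six
replicates per condition, one region), latent 32, hidden 64/32, 3000
training epochs with checkpoints at 2000/2500/3000, 3000 inversion
candidates with k = 10. The two-cluster toy (20 genes, clusters around
0.2 and 0.8 with half the genes shifted) uses latent 8, hidden 32/16 and
6000 epochs in the tests (12,000 in the acceptance script's realism
measurement). Full-scale defaults (hidden 800/400, 35,000 candidates,
tens of thousands of epochs) remain the library defaults for real runs.

## Known limitations

* Linear latent interpolation is an assumption, not an inference; nothing
  guarantees intermediate decodes correspond to traversed biological
  states.
* Correlation-based inversion is blind to uniform (pattern-preserving)
  shifts and to overall scale.
* A single shared NB dispersion and independent genes make the synthetic
  benchmark easier than real data.
* The trend statistics carry no significance testing; Log2FC > 0.2 is a
  descriptive flag.
* Training is CPU-bound NumPy; full-scale epoch counts (10⁴–3·10⁴ on
  thousands of genes) are feasible but take hours, not minutes.
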