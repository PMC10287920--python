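# Methods

## The model

`snapcluster` integrates multimodal single-cell measurements by encoding all
modalities of a cell into one shared latent Gaussian. Per modality m the
encoder is deliberately shallow: a learnable point-wise scaling (one
multiplicative weight per feature, initialized at 1, no bias) lets the model
re-weight individual features cheaply, and a single fully connected layer
maps the dₘ scaled features to a modality-specific hidden representation
(default widths: 185 units for RNA and ATAC-derived gene-activity matrices,
30 for the much narrower ADT panels). Hidden representations are
concatenated and projected by one fully connected layer to the μ and
log-variance heads of a `latent_dim = 100` Gaussian; no activation is
applied on the heads. Decoders mirror the encoders (latent → per-modality
hidden → linear reconstruction); outputs are linear because inputs are
z-scored and signed.

The per-mini-batch objective is

    L = Σₘ mean_i ‖xₘᵢ − x̂ₘᵢ‖²  +  KL[N(μ, σ²) ‖ N(0, I)],

where the reconstruction term is the per-cell mean of squared residual row
norms (a `reconstruction_reduction="sum"` flag switches to the summed
variant) and the KL term is the matching per-cell mean of
½ Σⱼ (μⱼ² + σⱼ² − 1 − log σⱼ²). Because the latent space is shared, KL is
computed once per cell rather than once per modality; a
`kl_in_modality_sum` flag restores the variant in which KL is repeated
inside the modality sum, which with a shared latent simply multiplies it by
the number of modalities M.

Training uses Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), mini-batches of 64
(final partial batch kept, order reshuffled each epoch from the run seed),
and the reparameterization z = μ + exp(logvar/2)·ε with seeded ε. The
embeddings exported for clustering are the deterministic μ matrix, not
sampled z, so downstream clustering is reproducible.

The model is implemented directly on numpy arrays with analytic gradients
and a hand-written Adam step; a finite-difference test guards the backward
pass. This keeps the package dependency-light, bit-reproducible from a
seed, and fast at the problem sizes it targets.

## Snapshot ensembles

The learning rate at optimizer step t (1-based, counting mini-batch steps)
is the shifted cosine

    S(t) = S₀/2 · (cos(π · mod(t−1, ⌈T/E⌉) / ⌈T/E⌉) + 1),

with S₀ = 0.02 by default, E annealing cycles and T = E × epochs_per_cycle
× ⌈n/batch⌉ total steps once bound to a dataset. t counts optimizer steps
(not epochs) because the ⌈T/E⌉ cycle length only produces per-cycle
annealing under that reading; with one epoch per cycle and whole-data
batches the two readings coincide. At the last step of each cycle the
full-data μ embedding is harvested in evaluation mode (after the optimizer
step); the next step's learning-rate restart then kicks the model out of
that minimum. Optimizer moment estimates are carried across cycle
boundaries by default (`reset_optimizer_per_cycle` exposes the
alternative). Defaults E = 50 and epochs_per_cycle = 1 reflect where the
ensemble benefit plateaus while keeping the cost of one training run.

The conventional baseline trains E independently initialized models (one
distinct sub-seed each) at a fixed learning rate for the same number of
epochs: identical total gradient-step count, but E model builds instead of
one. Both trainers record step and model-build counters in their manifests
so that efficiency comparisons are hardware-independent.

### Activation choice

The hidden activation is tanh by default, relu optionally. With this
architecture — no normalization layers anywhere, by design — relu networks
diverge under Adam at the default S₀ = 0.02 on realistic inputs: hidden
activations grow without bound, the log-variance head saturates, and the
harvested embeddings carry no signal. tanh bounds the hidden layer and
trains stably at the same rate (training loss drops below the
predict-the-mean baseline within a few cycles). Two numerical safeguards
apply regardless of activation: the log-variance is clamped to ±15 before
exponentiation, and gradients are rescaled when their global L2 norm
exceeds `max_grad_norm` (default 100).

## Clustering and consensus

Each snapshot is partitioned independently. k-means uses 10 seeded random
starts, at most 300 Lloyd iterations and tolerance 1e−6, with k supplied by
the user (conventionally the number of annotated cell types; the package
performs no model selection). Spectral clustering builds a symmetrized
binary kNN affinity (default 30 neighbours), takes the k smallest
eigenvectors of the symmetric normalized Laplacian by dense
eigendecomposition (exact and robust at the cell counts this package
targets), row-normalizes and runs seeded k-means; more connected components
than k is an error, fewer are separated automatically by the component
indicator eigenvectors. Partitions are 1-based and compacted (labels
densely use 1..k′). External partitions (e.g. from a kernel-based method
run elsewhere) can be dropped into the partitions directory as TSV and
enter the consensus unchanged.

The consensus partition minimizes the summed, permutation-matched squared
Frobenius distance between membership matrices — equivalently, twice the
total number of aligned-label disagreements. The fixed-point iteration
alternates (i) exact optimal alignment of every base to the current
candidate via the Hungarian algorithm on the k×k contingency table and
(ii) per-cell majority vote over aligned bases, ties broken toward the
lowest class index for determinism. The objective is provably
non-increasing across iterations. Restart 1 starts from the base partition
with the lowest objective against all others; further restarts (default 5
total, max 100 iterations each) start from seeded random partitions, and
the best restart wins. On small instances the solver is validated against
exhaustive search over all kⁿ candidate labelings; with 20 restarts it
attains the global optimum in well over 90% of random instances and can
never return a better-than-optimal value (the objective is always
recomputed from the returned partition).

Permuting all class labels of every base consistently leaves the optimal
objective unchanged; the returned partition is then identical up to
relabeling whenever the optimum is unique (with tied optima the solver may
legitimately return a different minimizer).

## Evaluation metrics

ARI is computed from the four pair counts over C(n,2) cell pairs,

    ARI = 2(N₀₀N₁₁ − N₀₁N₁₀) / [(N₀₀+N₀₁)(N₀₁+N₁₁) + (N₀₀+N₁₀)(N₁₀+N₁₁)],

which agrees with the standard Hubert–Arabie contingency form to machine
precision (tested against an independent implementation). When the
denominator is zero the value is defined as 1 if the partitions are
identical up to relabeling and 0 otherwise. NMI uses log₂ mutual
information and entropies; the default normalization is 2I/(H(U)+H(V)) so
identical partitions score 1, and the single-I variant I/(H(U)+H(V))
(which scores 0.5 on identical partitions) is available as
`variant="as_printed"`. Two trivial single-class partitions score 1 by
convention.

Major/minor evaluation splits reference types at the median per-type count
(≥ median → major) and recomputes ARI/NMI on each cell subset using the
original cluster ids restricted to that subset — no re-clustering, so the
subset scores measure how the global partition treats abundant vs rare
types. An empty minor set (all types equally sized) is omitted from the
report.

## Preprocessing

Features observed in strictly fewer than 1% of cells are dropped (strict
"<": a feature at exactly the threshold is kept); the comparison is
feature-prevalence across cells, with an optional, off-by-default
`min_features_per_cell` filter for the symmetric cell-wise reading. Cell
types annotated on fewer than 50 cells are removed consistently across all
modalities. Each modality is then z-scored per feature with the sample
(n−1) standard deviation; zero-variance columns map to all-zeros rather
than being dropped so feature dimensions stay predictable for the encoders.

## Synthetic data

The generator emulates the *normalized* scale the model actually consumes,
not raw counts: each modality is standard Gaussian noise in which a
fraction of features (default 10%) carries cell-type-specific mean shifts
drawn as `separation` × N(0,1), with all modalities sharing one cell-type
assignment. Optional dropout zeroes entries independently. The
"tea-seq-like" preset (RNA 2000 / ADT 40 / ATAC 2000 features, 9 types by
default) mirrors the shape of trimodal PBMC data at desk scale. Skewed
abundances follow geometric decay pⱼ ∝ imbalance⁻ʲ. A split-signal mode
(`modality_type_groups`) assigns each modality a coarsening of the type
labels so that no single modality can resolve every type contrast but
their union can — the situation in which modality integration demonstrably
helps.

What the generator does **not** emulate: count distributions
(negative-binomial overdispersion, library-size variation), batch effects,
doublets, feature–feature correlation structure, or the extreme sparsity
of real ATAC data. Passing tests therefore demonstrate that the machinery
is correct and that the method behaves as designed when its assumptions
hold; they do not certify performance on real data.

## Problem sizes and reproducibility

Bundled end-to-end checks run at desk scale — e.g. 500 cells × 5 types ×
3 modalities (2000/40/2000 features) with ensemble sizes 1–50, or 400
cells with split signal at 300/40/300 features — chosen so the full suite
and the reproduction script complete in minutes on one CPU. Every source
of randomness (simulation, initialization, shuffling, reparameterization
noise, clustering, consensus restarts) derives from explicit seeds; stage
sub-seeds are stable hashes of (master seed, stage name, index), so adding
a stage never perturbs earlier ones. Model parameters train in float32;
the gradient finite-difference check runs in float64 via the configurable
model dtype.

## Known limitations

- The VAE assumes z-scored Gaussian-like inputs; raw counts need external
  normalization first.
- Decoder likelihoods are Gaussian only (no negative-binomial/Bernoulli
  heads), so the model is not a generative model of counts.
- k must be supplied; there is no automatic estimation of the number of
  types.
- The spectral backend uses a dense eigendecomposition, quadratic in cell
  count — fine up to a few thousand cells, not for atlas-scale data.
- Conventional-ensemble members train sequentially; there is no
  parallelism.
- relu training requires a smaller initial learning rate than the default
  0.02 (see "Activation choice").
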