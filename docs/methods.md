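# Methods

`glsdbn` implements a sparse deep belief network for two-class
classification of brain FDG-PET scans (Parkinson's disease vs. normal
control), together with the preprocessing, synthetic-data and evaluation
machinery needed to exercise it end to end without clinical data.

## Model

### GLS-RBM

The building block is a Bernoulli-Bernoulli restricted Boltzmann machine
with visible units `v ∈ [0,1]^{n_v}`, hidden units `h ∈ {0,1}^{n_h}`,
energy `E(v,h) = −aᵀv − bᵀh − vᵀWh`, and logistic conditionals in both
directions. Pretraining minimizes

```
F = F_unsup + τ · F_sparse,
F_sparse = λ · F_lasso + sign · φ · F_cauchy,
```

where `F_unsup` is the batch-averaged negative log-likelihood and the
penalty is evaluated on the data-clamped hidden activation probabilities
`p_j = p(h_j = 1 | v)`:

- **Overlapping group lasso.** Hidden units are laid out in `I` contiguous
  index blocks of equal size `g`, consecutive blocks sharing `o = α·g`
  units (`α` = overlap rate). `F_lasso` is the batch-averaged sum of
  Euclidean norms of `p` restricted to each group (the L2,1 mixed norm);
  shared units contribute to every group containing them. The mixed norm
  drives entire groups of activations toward zero while leaving a few
  groups active — group-level sparsity matching the assumption that
  disease signal concentrates in a few coordinated feature blocks.
- **Cauchy penalty.** `F_cauchy` averages the Cauchy density
  `(1/π)·γ/((p−μ)² + γ²)` over units, with scale `γ` and location `μ`.
  With `cauchy_sign = −1` (default) the objective *maximizes* the density,
  attracting activations to `μ`; `μ = 0.025` therefore acts as an explicit
  near-zero activation target. The `+1` option minimizes the density
  value itself, which repels activations from `μ` and in our experiments
  consistently *lowers* hidden-layer sparseness below the penalty-free
  baseline; it is kept as an escape hatch for comparison, but attraction
  is the only reading under which the penalty does what a sparsity
  penalty is for.

The likelihood gradient is approximated by contrastive divergence (CD-k,
default k = 1): hidden states are Bernoulli-sampled along the Gibbs chain,
probabilities are used for the statistics and for the visible
reconstruction. The penalty gradient reaches `W` and the hidden bias `b`
through the exact per-sample chain rule `∂F/∂W_ij = Σ_l (∂F/∂p_j^{(l)}) ·
p_j^{(l)}(1−p_j^{(l)}) · v_i^{(l)}`; the visible bias is driven by the
likelihood term only. A factored variant that multiplies two batch
averages exists behind a flag for comparison; it is not the exact gradient
(a permanent finite-difference test arbitrates) and is never used by the
trainer. At a group with exactly zero norm the minimum-norm subgradient
(zero) is used.

### Stacking and fine-tuning

A DBN is built greedily: each RBM trains on the previous layer's hidden
activation probabilities with earlier layers frozen. A two-node softmax
head (NC = node 0, PD = node 1) is attached and the whole network is
fine-tuned by mini-batch gradient descent on the mean cross-entropy. The
PD node's softmax probability is the subject's **RiskScore** — bounded in
[0,1] and usable as a quantitative marker; the pre-softmax activation is
available via `raw_logit=True`.

### Preprocessing

Volumes are min-max normalized to [0,1], reduced to feature vectors by a
boolean brain mask (C-order voxel linearization, stable across I/O
round-trips), then embedded by locally linear embedding: k-nearest
neighbors (ties broken by lower sample index), constrained reconstruction
weights solved from the local Gram matrix with ridge `1e-3·trace(G)/k`,
and the bottom non-constant eigenvectors of `(I−W)ᵀ(I−W)` as coordinates.
Out-of-sample points are embedded by re-solving the constrained weights
against the training points (a point coinciding with a training point
takes all the weight — the zero-regularization limit); a transductive mode
refits the embedding on train + test jointly. Embedded coordinates are
min-max rescaled per feature to [0,1] before entering the RBM, whose
conditionals assume unit-interval inputs.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| hidden sizes | 500, 500, 500 | three stacked GLS-RBMs |
| τ, λ, φ | 1, 1, 1 | penalty weights (overall, lasso, Cauchy) |
| γ, μ | 1, 0.025 | Cauchy scale and location |
| `cauchy_sign` | −1 | attract activations toward μ |
| groups I, overlap α | 10, 0.2 | relaxed contiguous layout |
| learning rate | 1e-4 | both pretraining and fine-tuning |
| epochs | 50 / 300 | pretraining / fine-tuning sweeps |
| batch size | 10 | reshuffled every epoch |
| LLE k, D | 10, 350 | neighbors, embedding dimension |
| splits | 80/20 × 50 | stratified repeated validation splits |

The number of groups `I` for 500 hidden units is not pinned down by the
source configuration; 10 groups of ≈61 units with ≈12-unit overlaps is
the package default. The strict layout requires `g = n/(I−(I−1)α)` and
`α·g` to be integers and reports the nearest feasible unit counts when
they are not; the relaxed layout (default) rounds block boundaries and
guarantees coverage.

Two initialization choices matter and were settled empirically on the
synthetic benchmark:

- **Layer weights** default to the sigmoid-normalized uniform half-width
  `4·sqrt(6/(fan_in+fan_out))`. A fixed small half-width (e.g. 0.01)
  attenuates the class signal roughly fourfold per sigmoid layer; after
  three layers the top-layer class separation drops to ~1e-5 and no head
  can recover it at learning rate 1e-4. The normalized scale keeps signal
  variance roughly constant through the stack.
- **The softmax head starts at zero.** With a random small-uniform head,
  the accumulated gradient signal (order 1e-4 after 300 epochs at lr
  1e-4) is masked by the random projection, producing arbitrary —
  sometimes inverted — score rankings. Zero initialization is standard
  for output layers and makes the learned direction exactly the
  accumulated class-difference signal.

## Synthetic data

`generate_group_features` emulates the situation after manifold reduction
of regional hypometabolism: NC rows are baseline Gaussian (noise sd 1);
PD rows subtract `effect × severity` (effect 1.0 sd by default) on the
features of a few active contiguous groups (3 of 10 by default), with a
per-subject severity multiplier uniform on [0.5, 1.5] (0 for NC) that
doubles as the UPDRS/H&Y-like covariate to recover. Features are min-max
rescaled to [0,1]. `generate_toy_volumes` plants multiplicative intensity
reductions (`1 − effect·severity`) in regions of a smooth ellipsoidal
"brain" to exercise the NIfTI/mask path. The generators' planted effect
sizes are themselves contract-tested (Monte-Carlo), so downstream
recovery tests measure the method rather than the fixture.

What the generator does **not** emulate: PET physics, spatially
correlated scanner noise, partial-volume effects, site effects between
cohorts, or class-imbalanced sampling. Passing benchmarks therefore show
that the implementation learns planted group-sparse structure and grades
severity monotonically — not that it reaches any particular accuracy on
clinical scans.

## Benchmark problem sizes

The standard benchmark trains on 200 and tests on 100 subjects (150 per
class generated, stratified split) with 350 features, across 5 generator
seeds, at the default architecture; the test suite uses a reduced
256-unit-wide stack and smaller fixtures for its end-to-end checks. The
sparsity comparison trains single 500-unit RBMs for the default 50 epochs
and reports mean per-sample Hoyer sparseness
`(√n − ‖p‖₁/‖p‖₂)/(√n − 1)` of hidden activations, averaged within then
across batches. The Hoyer measure uses the `√n` normalization — the form
that is 0 for a uniform vector and 1 for a one-hot vector.

## Numerical choices

- Neighbor ties in LLE resolve to the lower sample index (stable sort);
  embeddings are computed by dense symmetric eigendecomposition, which is
  deterministic.
- Group norms below 1e-300 are treated as zero (subgradient 0).
- Fine-tuning clamps nothing: probabilities stay in (0,1) by construction;
  training aborts with the epoch/batch index if parameters go non-finite.
- All randomness flows from user seeds through `numpy.random.Generator`;
  layer seeds and the fine-tuning stream are derived by fixed documented
  offsets, so every pipeline run is bit-reproducible.
- Undefined evaluation ratios (sensitivity without positives, specificity
  without negatives) are reported as NaN, never silently 0. ROC/AUC uses
  the threshold sweep with the Mann-Whitney tie-half convention; the
  group-difference test on RiskScores is Welch's t.

## Known limitations

- At the default learning rate and epoch budget the networks stay in a
  near-linear regime: scores cluster around 0.5 and classification relies
  on the learned ranking. This matches the bounded [0.3–0.7] score ranges
  the pipeline reports, but means decision thresholds far from 0.5 are
  not meaningful at these settings.
- Strict group layouts are infeasible for many (n, I, α) combinations
  (including 500 units at α = 0.2 for most small I); the relaxed layout is
  the practical default.
- The transductive LLE mode leaks test data into the embedding; it exists
  for parity with pipelines that embed all cohorts jointly and should not
  be used for honest out-of-cohort evaluation.
- Penalties of other sparse-DBN variants (quadratic, rate-distortion,
  normal, Laplace) are not implemented; the penalty interface (value +
  gradient with respect to activations) admits them as plugins.
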