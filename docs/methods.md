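# Methods

## Model

Each gene's transcription is described by the two-species splicing ODE

    du/dt = alpha - beta u,        ds/dt = beta u - gamma s,

with per-gene transcription rate `alpha`, splicing rate `beta` and
degradation rate `gamma`. A gene passes through four transcriptional
states: induction (k=1, `alpha > 0` from `(u, s) = (0, 0)`), the induction
steady state (k=2, the `t -> inf` limit `(alpha/beta, alpha/gamma)`),
repression (k=3, `alpha = 0` starting from the switch point at the
gene-specific switching time `t_s`), and the repression steady state (k=4,
`(0, 0)`). The closed-form solutions of both branches are implemented in
`spatialvelo.kinetics` and verified against Runge–Kutta integration; the
global time scale is fixed at `t_max = 20` so latent times are comparable
across genes. RNA velocity is the instantaneous spliced derivative
`v = beta u - gamma s`.

An optional time-dependent transcription-rate mode
(`alpha(t) = alpha1 - (alpha1 - alpha0) e^{-lambda_alpha t}` during
induction) is provided; the default is the constant-rate mode, which is the
one that agrees exactly with the closed forms and for which the ODE
equivalence tests hold. How the extra parameters should be learned is not
specified anywhere we could follow, so the time-dependent mode is exposed
but not part of the training path.

Each cell `n` carries a latent state `z_n` (dimension d=10) that is the sum
of two encodings:

* `z_VAE` — a reparameterised sample from an amortised Gaussian posterior
  produced by an MLP over the concatenated min-max-scaled unspliced and
  spliced profile (2 hidden layers of 128 ELU units; the log-variance is
  squashed through `5 * tanh` to keep variances in `(e^-5, e^5)`);
* `z_GAT` — a one-layer, four-head graph-attention encoding of `z_VAE` over
  the combined cell graph (within-batch spatial kNN edges plus cross-batch
  optimal-transport mutual-nearest-neighbour edges, k=15 each, with
  self-loops). Edge weights multiply the exponentiated attention scores, so
  `w_mnn = 0` or `w_spatial = 0` reproduce the graph ablations exactly.

Downstream of `z`: a state network produces per-cell-per-gene Dirichlet
concentrations over the four states (softplus link, prior
`Dirichlet(0.25, 0.25, 0.25, 0.25)`); two state-specific time networks
produce `rho` in (0,1) placing each cell-gene on the induction branch
(`t = rho1 * t_s`) or repression branch (`t = t_s + rho3 (t_max - t_s)`);
the steady states sit at `t_s` and `t_max` by convention so expectations
over all four states are well defined. Observations are modelled per
cell-gene as four-component Gaussian mixtures around the kinetic means with
per-gene noise scales and per-state variance factors `c = (1, 1, 1, 0.1)` —
the repression steady state is deliberately tight so that silent genes are
not absorbed by wide components.

The expectation over the state simplex inside the likelihood uses the
analytic Dirichlet mean as mixture weights (the exact
`E_q(pi)[log p]` has no closed form; the mean plug-in is the
variance-reduced choice and is used consistently at training and inference
time). Hard state assignments (argmax) are only ever taken at inference.

## Training

The loss is `L = L_elbo + lambda L_switch + lambda L_batch` with
`lambda = 2`:

* `L_elbo` — negative ELBO: expected negative mixture log-likelihood, plus
  the closed-form Normal KL of `q(z)` against `N(0, I)`, plus the
  closed-form Dirichlet KL of the state posterior against the prior,
  averaged per cell.
* `L_switch` — squared distance between the switch point
  `(u(t_s), s(t_s))` on the induction branch and the per-gene median of the
  scaled expression. This anchors the switch in the phase portrait.
* `L_batch` — sum over unordered batch pairs of the squared MMD (Gaussian
  kernel, biased V-statistic) between the batches' latent vectors;
  bandwidth from the median pairwise-distance heuristic per step unless
  fixed; at most 256 cells per batch enter each estimate.

Optimisation is Adam (lr 1e-3, decoupled weight decay 1e-4, gradient-norm
clipping at 10) on full-batch gradients: the graph attention needs the
whole graph per pass, and at the problem sizes this package targets a full
pass is cheaper than minibatching. The default epoch budget is 2000;
the recovery experiments below use 300.

Two initialisation choices matter:

* per-gene `gamma` starts at the steady-state ratio of the scaled moments
  (`beta` starts at 1), the standard steady-state initialisation;
* an orientation warm-up: for the first 30% of epochs the state posterior
  is additionally pulled (weight 2, decaying linearly to 0) towards the
  steady-state-line heuristic — cells above `u = ratio * s` are induction,
  below are repression. The four-state mixture has a near-symmetry (swap
  the branches and the roles of `beta` and `gamma`) that otherwise makes
  the global time direction an arbitrary basin choice; the heuristic
  encodes the physical asymmetry (unspliced responds before spliced) and
  the decaying weight hands control back to the likelihood.

Everything is driven by one seed; fixed seed means bit-identical runs.

The model and training loop are implemented on a small reverse-mode
automatic-differentiation tape over NumPy arrays
(`spatialvelo._autodiff`): dense float64, broadcasting-aware arithmetic,
matmul, the usual activations, `gammaln`/`digamma` for the Dirichlet KL,
and gather/scatter/segment-softmax for the attention layer. Gradients are
validated against central finite differences in the test suite.

## Preprocessing

Stage order: shared-count gene filter (keep genes with
`sum_cells min(S, U) >= 20`) → per-cell normalisation of each layer to the
median total → `log1p` → top-2000 dispersion-ranked HVGs (on spliced; the
choice of spliced-only is deliberate and flagged here) → PCA (30
components) + 30-NN graph → neighbour moments (mean of self plus
neighbours; uncentred second moments on request) → per-gene min-max scaling
of the moments to [0,1] (constant columns map to 0; per-gene minima and
ranges, and the ranges on the de-logged linear scale, are stored for
inverse mappings) → steady-state velocity-gene filter.

The steady-state filter fits `u ~ ratio * s` through the origin on the
cells in the union of the top and bottom 5% of `u + s` and keeps genes with
`ratio > 0` and `R^2 >= 0.2`. R² is evaluated on **all** cells: evaluating
it on the selected extreme cells only would reward any gene whose `u` and
`s` merely co-vary with their total (selection on `u + s` induces that
correlation), and the filter would stop filtering.

## Rate units

The model is fitted in min-max-scaled log space. Scaled-space `gamma/beta`
ratios cluster near 1 for plateau-reaching genes (the min-max gains absorb
the ratio), so fitted ratios are mapped back to data units through the
stored per-gene gains: the scaled space is reached from (normalised) counts
by `log1p` followed by min-max, and the per-gene gain of that chain is the
gene's dynamic range on the linear scale; from `ds/dt = beta u - gamma s`,
rescaling `u` and `s` by gains `g_u`, `g_s` multiplies `beta` by
`g_u / g_s` and leaves `gamma` unchanged, so
`(gamma/beta)_data = (gamma/beta)_scaled * g_u / g_s`.

## Posterior summaries

State probabilities, latent times and velocities are Monte-Carlo
expectations over `q(z | u, s)` (default 25 samples; the inner expectation
over the simplex is the analytic Dirichlet mean). Latent times mix the four
per-state times with the state probabilities and always lie in
`[0, t_max]`. Velocity is reported in the scaled likelihood space by
default, or multiplied by the per-gene spliced range for the
original-scale export. Per-cell uncertainty is the differential entropy of
the diagonal-Gaussian latent posterior,
`h(z) = 1/2 log((2 pi e)^d det Sigma)`.

## Evaluation metrics

For an ordered cell-type pair (A, B), boundary cells are A-cells with at
least one B-cell among their 30 nearest neighbours; three neighbourhood
graphs are supported (expression kNN on 30 PCs, within-batch spatial kNN,
cross-batch OT-MNN). Confidence is mean velocity-cosine agreement with
B-neighbours; transition averages row-normalised probabilities
`exp(cos(S_c' - S_c, V_c) / sigma)` (sigma default 0.1; normalisation over
all cells `c' != c`, with a flag to restrict it to the neighbour set);
direction compares PCA displacements with the
transition-probability-weighted velocity embedding. Aggregation over a
transition ground-truth list: confidence averages the correct pairs;
transition and direction also include the negated scores of the reversed
(incorrect) pairs. Velocity coherence averages, over 100 sampled cells and
batch pairs, the cosine between per-batch MNN-averaged velocities; because
MNN edges are cross-batch, each cell represents its own batch, making the
two-batch score the own-velocity-vs-cross-batch-MNN-average comparison.

Because the transition normalisation runs over all cells, transition scores
scale like 1/N and are informative in sign and ordering rather than
magnitude.

## Synthetic data

The generator draws per-gene rates log-uniformly (`alpha` in [1, 10],
`beta` in [0.2, 1.5], `gamma` in [0.05, 0.8]; pairs with
`|beta - gamma|` below guard are nudged) and switching times uniformly in
[0.35, 0.7] of `t_max`, assigns each cell a true time along one shared
trajectory whose consecutive time windows are the cell types, evaluates the
noiseless dynamics with the package's own closed forms, and adds Gaussian
noise with per-gene scale 0.1 of the steady-state abundance. Two realism
features are essential: besides the dynamic genes, twice as many
*background* genes sit at their induction steady state in every cell
(velocity 0), so per-cell totals reflect library size rather than the
dynamic program — without them, normalising to the median total erases the
trajectory itself; and a per-cell lognormal library factor (sd 0.2) gives
the normalisation real technical variation to remove. Batch effects are
multiplicative per-batch per-gene lognormal factors (sd 0.3; batch 0 is the
reference). Cell types are Gaussian spatial blobs per batch (sd 10 in a
100-unit field) so the spatial kNN graph carries type signal; a gradient
layout is available.

What the generator does **not** emulate: count noise (observations are
Gaussian around the kinetic means, not Poisson/NB), sparsity and dropout,
multiple lineages or branching trajectories, multiple-rate-kinetics genes,
spatially varying microenvironment effects on expression, and segmentation
artifacts of real spatial platforms. Passing tests therefore show the
pipeline is self-consistent and identifiable under its own model class, not
that it handles every pathology of real tissue data.

## Problem sizes used by tests and the acceptance script

Parameter-recovery runs use the generator defaults — 2 batches x 500
cells, 30 dynamic + 60 background genes, 300 epochs, three seeds; recovery
is measured as Spearman correlation of fitted vs true `gamma/beta` over the
retained genes (data units, as above) and of inferred vs true latent time,
the latter over the retained *dynamic* genes, since background genes have
no true time to recover. Ablation experiments use 2 x 200 cells and 150
epochs. The communication permutation test is calibrated over 100 random
relabellings of a 25-cell grid with 50 permutations each. Oracle
comparisons (ODE integration, brute-force MMD and score implementations)
run on instances of at most 10 cells or 100 parameter sets.

## Numerical choices

* The spliced closed form divides by `gamma - beta`; it is evaluated as
  `e^{-beta tau} expm1(-(gamma-beta) tau) / (gamma-beta)`, which has a
  removable singularity at `gamma = beta` and correct derivatives there
  (an exactly zero difference is nudged to 1e-12).
* Velocity at the two steady states returns exact zeros (the balance holds
  identically).
* Min-max scaling maps constant columns to 0; their stored range is 1 so
  inverse mappings are no-ops.
* Optimal transport: exact assignment-based transport for equal batch
  sizes (the uniform-marginal optimum is a permutation), Sinkhorn
  (regularisation 0.05 of the mean cost, on 30 PCs) otherwise.
* Ties everywhere break towards the lower cell index (stable sorts).
* `recombine` computes the corrected unspliced matrix as `M - S` so that
  conservation holds to the last unit of precision.
* Training aborts on a non-finite loss with the offending components in
  the message; gradient clipping at norm 10 is the first line of defence.

## Known limitations

* The global time direction is identified only through the
  steady-state-line warm-up; on data where most genes genuinely violate
  the u-leads-s asymmetry (e.g. dominated by multiple-rate-kinetics genes)
  the orientation can still flip.
* Scaled-space kinetic parameters are identifiable only up to the per-gene
  scaling gains; data-unit rates are reconstructed through the stored
  ranges and inherit their noise.
* With clean expression signal (low observation noise), adding spatial
  edges to the graph can slightly smooth over fine-grained time structure;
  the spatial graph earns its keep when expression is noisy — see the
  ablation quantities reported by the acceptance script.
* Full-batch training keeps memory linear in cells x genes; datasets far
  beyond ~10^4 cells would need the minibatch path this package does not
  implement.
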