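# Methods

## Model

`smcc` fits a generative mixture to an attributed, partially labeled,
undirected network. Each node `x_i` carries nonnegative counts
`n(x_i, w_j)` over `M` attribute words; the `K` functional classes play
the role of the mixture's latent variables, so the two parameter tables
are `P(w_j | c_k)` (M×K, column-stochastic) and `P(c_k | x_i)` (N×K,
row-stochastic). The fitted objective is

    O  =  L − α R − β H
    L  =  Σ_i Σ_j n(x_i, w_j) log Σ_k P(w_j|c_k) P(c_k|x_i)
    R  =  Σ_{i,s} D(z_i, z_s) E_is          (ordered pairs; each edge twice)
    H  =  Σ_{k,l} D(r_k, r_l) F_kl          (ordered class pairs)

with `D(p, q) = ½[KL(p‖q) + KL(q‖p)]` in natural log, `z_i` the i-th row
of `P(c|x)`, `r_k` its k-th column, `E` the (possibly weighted) network
and `F` the label-affinity matrix: cosine similarity of the per-class
indicator columns over the labeled nodes (unit Euclidean normalization;
classes without labeled positives get a zero row/column and `F_kk = 1`).

Two deliberate readings of the penalty terms:

* **Row distributions in `R`** are floored at `eps` and renormalized
  before the divergence, since label clamping introduces exact zeros that
  would otherwise make the KL infinite.
* **Columns `r_k` in `H` are used raw** (floored at `eps` but *not*
  renormalized). They are profiles over instances, not probability
  distributions; the penalty is applied to the written form of the
  objective. Renormalizing them first would be an equally defensible
  variant but changes the gradient scale by the column mass.

Annotated nodes are *clamped*: their rows of `P(c|x)` are fixed at the
uniform distribution over their known labels (`1/l_x` on each of the
`l_x` positives), applied at initialization and re-applied after every
M-step. Supervision thus enters the EM both through the likelihood (via
`P(w|c)`) and through the regularizers (via smoothness against clamped
neighbors).

## EM fitting

* **Initialization.** `P(w|c)` columns are the labeled co-occurrence
  frequencies of each word with each class, with additive smoothing `1/M`
  (guards unseen words and classes with no labeled positives, which fall
  back to uniform columns). Unlabeled `P(c|x)` rows start at the labeled
  class-prior distribution; labeled rows are clamped.
* **E-step.** Standard Bayes posterior `P(c_k | x_i, w_j)`. The N×M×K
  tensor is never materialized: only cells with `n(x_i, w_j) > 0` are
  touched, through a sparse ratio matrix `S_ij = n_ij / Σ_k
  P(w_j|c_k)P(c_k|x_i)` from which both M-step sufficient statistics are
  two sparse-dense products.
* **M-step for `P(w|c)`.** Posterior-weighted word frequencies per class
  (textbook pLSA). Empty classes keep their previous column.
* **M-step for `P(c|x)`.** Stationarity of the Lagrangian under the
  `log x ≈ 1 − 1/x` approximation yields the linear system
  `(Ω + α(D−B) + β(U−R)) y = Z` over the class-major stacked vector `y`
  (`y = [y_1; …; y_K]`, `y_k` over nodes):
  `Ω` is diagonal with the per-node total counts `ρ_i` repeated per class
  (an exact identity — asserted at build time); `α(D−B) = α · I_K ⊗ L_E`
  with `L_E` the graph Laplacian of the (weighted) network; `β(U−R) =
  β · L_F ⊗ I_N` with `L_F` the Laplacian of the label affinity, mixing
  the K entries of each node. Both Kronecker blocks are positive
  semidefinite, so the system matrix is symmetric positive definite
  whenever every node has positive total counts. It is solved by
  conjugate gradients warm-started from the previous iterate
  (`rtol 1e-12`, direct sparse solve as fallback); isolated nodes with
  all-zero count rows — the only genuinely singular case — keep their
  previous row. The solution is not guaranteed nonnegative by the log
  approximation, so rows are floored at `eps` and renormalized, then the
  labeled rows re-clamped. With `α = β = 0` the system is diagonal and
  the update reduces exactly to the pLSA M-step — this limit is tested
  against an independently coded, loop-based pLSA EM.
* **Convergence.** Relative change of `O` below `tol = 1e-4` (default),
  `max_iter = 50`. The approximate M-step does not guarantee monotone
  `O`; in practice regularized fits on the synthetic test bed converge in
  roughly 10–25 iterations. The *unregularized* pLSA limit has a long
  flat likelihood tail and can plateau just above the threshold within 50
  iterations; convergence is therefore asserted for regularized fits.

Numerical choices: natural log everywhere; `eps = 1e-12` floors in the
likelihood, divergences and the M-step output; zero-mixture likelihood
cells floored and logged; all tie-breaks (ranking, kNN, gap search) by
stable node/class order for determinism. The EM itself contains no
randomness.

## Prediction

`predict_labels` sorts each node's probabilities in decreasing order,
finds the largest gap between successive values, thresholds at the gap's
midpoint and returns the labels above it — the relevant set is never
empty (the top label always clears the threshold; an all-equal row falls
back to the first class). Exact float ties in the gap search resolve to
the highest-scoring gap. `instance_similarity` reports the cosine of two
nodes' class-probability vectors in [0, 1], usable for screening putative
interaction partners.

## Latent graphs and the ensemble

* `ppi`: the observed network, unchanged.
* `rwr`: even-step random walk with restart. The two-step count matrix
  `E·E` is column-normalized to a transition matrix and the visiting mass
  `Σ_{t=1..T} restart·(1−restart)^t · P̂^t` accumulated (defaults
  `restart = 0.1`, `T = 10`). The result is symmetrized as `(R + Rᵀ)/2`
  because the network regularizer assumes a symmetric relation. Even-step
  walks favor triangle-closing direct neighbors and well-connected
  level-2 neighbors, and provably assign zero weight across a
  bipartition.
* `predsim`: one-vs-rest probabilistic classifiers (default: linear
  logistic regression with `C = 1.0`; any object with a
  `train`/`predict_confidences` contract can be substituted, e.g. a
  probability-calibrated SVM) are trained on the labeled nodes' counts;
  per-node confidence vectors are unit-normalized and their cosine
  similarities sparsified to a binary symmetric kNN graph (`k = 10`
  default; edge iff either endpoint is in the other's neighbor list).
  Degenerate one-vs-rest problems (no labeled positives/negatives) yield
  constant confidences equal to the labeled prior.

The default base classifier is logistic regression rather than a
Platt-scaled SVM because probability calibration by internal
cross-validation is ill-defined with the handful of labeled positives per
class that the 3–10% labeling regime produces; both are linear
probabilistic models with the same penalty scale.

EGM-SMCC fits one GM-SMCC per latent graph (each network regularizer
using that graph) and averages the probability tables elementwise;
thresholding happens once, on the average. Components that fail to
converge are excluded (error if none converge). An `average-graphs` mode
instead averages the weight matrices and fits a single model. Weighted
graphs enter the regularizer and Laplacian as-is — the edge weight scales
the pairwise divergence.

## Synthetic data generator

The generator produces the conditions the model assumes, with measurable
contracts:

* **Labels**: a Gaussian copula thresholded at the marginal
  `p = cardinality_mean / K`; the `label_correlation` table is the target
  pairwise *cosine co-occurrence* of the label columns — the same measure
  the model's affinity `F` uses. Per-pair latent correlations are solved
  from the bivariate normal orthant probability (deterministic
  quadrature + Brent root-finding) and then corrected by a short
  fixed-point loop against an internal fixed-seed Monte Carlo draw,
  because forcing all-zero rows to one label (every node must carry ≥ 1
  function) attenuates the observed co-occurrence. A Pearson-correlation
  contract was rejected: conditioning on non-empty label sets caps
  achievable Pearson correlation far below useful targets. A
  `single_label` mode assigns the arg-max latent class one-hot.
* **Features**: each class prefers a contiguous block of `M/K` words;
  profile weight `1 + feature_signal · K` on the block, mixed across a
  node's labels, sampled as a multinomial of a Poisson(30) total.
  `feature_signal = 0` gives identical class profiles (no signal).
* **Edges**: `N · mean_degree / 2` distinct pairs drawn from the
  shared-label pool with probability `homophily`, else from the
  non-shared pool, giving measured homophily within sampling error of the
  parameter.
* **Masking**: `round(label_ratio · N)` nodes (≥ 1) keep their labels.

Defaults — `N = 300`, `K = 6`, `M = 40`, `homophily = 0.9`,
`label_ratio = 0.05`, `mean_degree = 6`, `cardinality_mean = 1.5`,
`feature_signal = 0.3` — define the standard test bed. `mean_degree = 6`
keeps the network comfortably above the percolation threshold so that
smoothing experiments measure propagation rather than fragmentation;
`feature_signal = 0.3` places the feature-only baseline near 0.78
accuracy at 5% labels, the operating point reported for feature-only
linear classifiers on the yeast benchmark this test bed emulates, leaving
headroom for the network term to act.

What the generator does *not* emulate: scale-free degree distributions,
hub proteins, correlated attribute noise, hierarchical (ontology-style)
label structure, and systematically biased annotation (labeled nodes are
sampled uniformly). Passing tests therefore demonstrate correctness of
the machinery and the direction of the regularizer effects under the
model's own assumptions, not performance on any particular real PPI
dataset.

## Evaluation metrics

Computed on the unlabeled (test) nodes: **coverage** (mean 0-based depth
of the lowest-ranked true label; ties by class order), **ranking loss**
(mean fraction of positive–negative pairs with `score(c⁺) ≤ score(c⁻)`;
ties count as reversals; rows without negatives are skipped, as the
normalization is undefined for them), **macro-F1** (per-label F1 averaged
over labels, 0 when `p + r = 0`) and single-label **accuracy** (top-1).
Both ranking metrics are invariant under strictly monotone score
transforms and are tested against brute-force enumeration oracles.

## Problem sizes

The default experiment battery — ten seeds × (unregularized +
three single-graph + ensemble + two multi-label fits) at `N = 300` — was
chosen as the smallest configuration at which the binomial sign test on
the network-regularizer benefit has adequate power; it completes in tens
of seconds.

## Known limitations

* Monotone improvement of `O` is not guaranteed (approximate M-step);
  only empirical convergence is asserted.
* The label regularizer's effect is modest unless label co-occurrence is
  strong and features weak; with saturated features both regularizers are
  inert by construction.
* `P(c|x)` rows for nodes with zero counts and no edges are unidentified
  and keep their initialization.
* The RWR graph is dense; at `N` much beyond 10⁴ the per-iteration solve
  would need sparsification of `R` (not implemented).
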