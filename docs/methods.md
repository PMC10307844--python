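# Methods

This note documents the model implemented by `mkm`, the conventions chosen
where the method leaves room, and what the synthetic benchmark can and cannot
establish.

## Model

A patient record with M non-negative encoded predictors, scaled into [0, 1]
and normalized to sum to one, is treated as the probability distribution p_i
of a dummy random variable A over a sample space Ω = {α_1, …, α_M}. The
feature vector of patient i is the truncated moment sequence

    m_ik = E[A^k] = Σ_j α_j^k p_ij ,   k = 0, …, M′−1,

computed for the whole cohort as **M** = P·𝕄, where 𝕄 is the M×M′
Vandermonde matrix with entries α_j^k. For pairwise-distinct α and M′ = M,
𝕄 is invertible (det 𝕄 = Π_{k<l}(α_l − α_k)), so the full moment vector
determines the distribution uniquely — the discrete version of the Hausdorff
moment problem. Truncation at M′ ≪ M is where the dimensionality reduction
happens; the zeroth moment is identically 1 and is retained so that M′ equals
the number of emitted feature columns.

The sample space is not arbitrary: α is the importance-weight vector of
(Block) HSIC Lasso, the non-negative ℓ1-penalized regression of the label's
centered Gram matrix on the per-predictor centered Gram matrices. Predictors
that carry label signal receive positive weight and therefore dominate every
moment; predictors with α_j = 0 are annihilated by all moments of order ≥ 1.

## Preprocessing conventions

* Min-max scaling is fitted on training rows only; held-out values outside
  the fitted range are clamped into [0, 1]. Fitting on all rows would leak
  test-set extremes into the transform.
* A constant column scales to 0 (not 0.5): constants are label-independent,
  and mapping them to zero removes their mass from the normalized
  distribution.
* An all-zero row cannot be normalized; it becomes the uniform distribution
  1/M with a warning, so the cohort size is preserved.
* Missing entries are imputed with the training-column mean before scaling.
* At transform time an unseen category yields an all-zero one-hot group by
  default (configurable to an error).

## HSIC Lasso conventions

The underlying references leave the kernels and penalty unspecified; the
defaults here are the canonical choices of the kernel feature-selection
literature, all exposed in `GramConfig`:

* Gaussian feature kernel, bandwidth 1 applied to z-scored columns;
  normalized delta kernel for class labels (1/n_c for a same-class pair).
* Block estimator: samples are shuffled (recorded seed) into blocks of
  B = 20; each block is centered with its own Γ_B. The estimator averages
  over `n_partitions = 3` independent shuffles, which is part of the block
  estimator's definition and shrinks its variance toward the full N×N
  estimator. With B ≥ N all partitions collapse to the full index set and
  the block solver equals the full solver exactly.
* Each stacked, vectorized centered Gram is rescaled to unit Frobenius norm,
  making λ scale-free.
* Solver: cyclic coordinate descent with non-negative soft-thresholding over
  a working set pre-screened by the marginal statistics c_j = ⟨K̄⁽ʲ⁾, L̄⟩,
  followed by a KKT sweep over all features (violators are added and the
  problem re-solved); tolerance 1e-6 on the objective decrease, at most 1000
  sweeps, best iterate returned with a warning on non-convergence.
* λ is either given or found by bisection so that the support has
  approximately a requested number of nonzero weights; the request defaults
  to the moment order used downstream. Above λ_max = max_j c_j the solution
  is identically zero (the KKT threshold).

### Redundancy and the importance *ranking*

The lasso support is not a relevance ranking. Causal predictors are mutually
correlated through the label, so their Gram matrices are partially redundant:
once the strongest ones are selected, a weakly informative predictor can have
a non-positive partial correlation with the residual and receive exactly zero
weight *at every penalty level* (verified against an exact non-negative
least-squares solve of the λ → 0 limit). For any "top-k features" statement,
`ImportanceWeights.ranking()` therefore orders features by weight first and
breaks the (many) ties at zero by the marginal statistic c_j. This tie-break
is reporting-only; it never feeds back into the solver or the moment kernel.

## Moment kernel conventions

* α is rescaled to [0, 1] by dividing by its maximum before powering
  (configurable). This is an invertible relabeling of Ω that prevents
  overflow of high powers and makes every row's moment sequence
  non-increasing in k — a useful invariant for testing.
* Ties in α (the many zeros of a sparse solution) are permitted for the
  forward, truncated map; only full-order inversion demands distinct α.
* Moment orders larger than M are allowed for the forward map (they are just
  higher powers); inversion requires a square kernel and M ≤ 12, beyond
  which the Vandermonde system is too ill-conditioned to trust.
* The moment order can be fixed or chosen by stratified cross-validated AUC
  over a candidate set, with ties broken toward the smaller order.

## Classifiers

* **LR** — unpenalized logistic regression with observation weights
  inversely proportional to class frequency (optional ridge for degenerate
  separable inputs).
* **NN** — multilayer perceptron, 10 hidden layers of width 20 by default;
  class imbalance is handled by seeded random oversampling of the minority
  class, which matches a class-weighted loss in expectation.
* **GBM** — RUSBoost, implemented in-repo: each round undersamples the
  majority class (uniformly, without replacement) to the minority count,
  fits a depth-10 tree with the current boosting weights, and applies the
  AdaBoost update β = ε/(1−ε) from the weighted error on the *full*
  training set; a failed round (ε ≥ 0.5) resets weights to uniform and
  contributes nothing to the log(1/β)-weighted ensemble score. Defaults:
  50 trees of depth 10.
* Features are z-scored inside the LR/NN harness with training statistics.
  Moment features can live on a ~1e-4 scale (probabilities spread over
  thousands of predictors), which stalls gradient solvers at their gradient
  tolerance; standardization is an optimizer aid and leaves the decision
  function unchanged in exact arithmetic.
* Reported accuracy thresholds scores at 0.5. Scores are positive-class
  probabilities; identical spec and seed give identical scores.

## Evaluation protocol

All stateful stages (imputation means, scaler, α, kernel, classifier) are
fitted on the training split only and frozen before held-out rows are
transformed. The reported AUC (Mann–Whitney probability, ties ½) is the mean
over n seeded bootstrap resamples of the test set with the fitted scores
frozen; the CI is the 95% percentile interval of those resamples. Full
re-generation/re-fit repeats are available through the scaling harness, which
also logs wall-clock time (informational only — hardware-dependent).

## The synthetic generator, and what a green test establishes

The generator emulates a screening-style cohort: N patients, M predictors of
which only a few are causal. Causal predictor i is Normal(0.3·i, 1) under the
negative class and Normal(0.7·i, 1) under the positive class; all other
predictors are standard normal, independent of the label. Optional
corruptions: additive Gaussian noise at a linear signal-to-noise ratio
(variance = feature variance / SNR), and full-column masking of the k
strongest causal predictors followed by mean imputation (an entrywise-masking
variant is available via configuration). Class balance defaults to ½.

What it does **not** emulate: mixed numeric/categorical records, correlated
predictors, informative missingness, covariate shift between train and test.
A green pipeline test therefore establishes internal correctness (selection
finds planted signal, moments preserve it, no leakage), not clinical
transportability.

One consequence worth stating explicitly: the five causal features give a
between-class Mahalanobis separation d′ = 0.4·√55 ≈ 2.97, so *no* classifier
can exceed a population AUC of Φ(d′/√2) ≈ 0.982 on clean data, and once the
three strongest causal columns are fully destroyed the ceiling drops to
Φ(√0.8/√2) ≈ 0.736. The benchmark's absolute AUCs must be read against these
ceilings; a leakage-free pipeline on this generator sits near them, and the
interesting claims are the relative ones (moments vs. raw features, graded
degradation under corruption), which the acceptance tests assert.

## Known limitations

* HSIC Gram construction is O(N·B) memory per feature but still streams all
  features per KKT sweep; very wide tables (M ≫ 10⁴) would need the screen
  pool tuned.
* The moment features are linear images of the probability rows; signal that
  survives only in interactions between predictors is invisible to them.
* Full-order moment inversion is a diagnostic, not a production path —
  Vandermonde conditioning limits it to a dozen sample-space points.
* The importance weights inherit the lasso's redundancy behaviour described
  above; the weakest member of a correlated causal group may be reported
  with zero weight.
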