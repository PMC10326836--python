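# Methods

## Model

`phylosym` models the evolution of microbiota composition across a clade of
host species. Let `n` be the number of sampled host species, related by a
rooted, ultrametric, bifurcating time-tree, and `p` the number of microbial
taxa (typically bacterial orders or phyla). The log absolute abundance
matrix `logX` (hosts x taxa) is assumed to follow a multivariate Brownian
motion along the host tree: starting from root values `logX0`, each branch
of length `t` adds a MVN(0, t*R) increment, where the p x p symmetric
positive-definite matrix `R` collects per-unit-time variances (evolutionary
rates of each taxon's abundance) and covariances (evolutionary integration
between taxa).

Phylosymbiosis — the tendency of closely related hosts to carry similar
microbiota — is parameterized by Pagel's lambda: terminal branches are
extended by `(1 - lambda)` of the total tree depth while internal branches
are compressed to keep the depth constant. Equivalently, off-diagonal
entries of the Brownian covariance `C` (shared root-to-MRCA path lengths)
are scaled by `lambda` while the diagonal is untouched. `lambda = 1` means
the untransformed tree explains the data (strong phylosymbiosis);
`lambda = 0` is a star phylogeny (none).

Sequencing-based surveys observe only relative abundances
`Z_ij = X_ij / Y_i` with `Y_i = sum_j X_ij`. The per-host totals are
therefore latent. Fixing the root total to 1 pins the root state to the
simplex vector `Z0` (the ancestral composition) and identifies the latent
log totals `logYtilde_i = log(Y_i / Y_0)`, through
`logX_ij = logZ_ij + logYtilde_i`. Rows of `logX` are matrix-normal with
mean `1 * logZ0'`, row covariance `C_lambda` and column covariance `R`.

## Inference

The joint posterior of `(lambda, Z0, R, logYtilde)` is explored in two
exact stages:

1. **Analytic marginalization of the latent totals.** Given
   `(lambda, Z0, R)` the model is linear-Gaussian in `logYtilde`, whose
   prior is N(0, tau^2) i.i.d. (tau = 5). The observed `logZ` then has a
   Gaussian marginal with covariance
   `C_lambda (x) R + tau^2 I_n (x) J_p`. For an ultrametric tree,
   `C_lambda = lambda*C + (1 - lambda)*T*I`, so a single eigendecomposition
   `C = U D U'` block-diagonalizes this covariance for every lambda: after
   rotating the data rows by `U'`, row `i` is an independent p-variate
   Gaussian with covariance `d_i(lambda)*R + tau^2*J`. One likelihood
   evaluation costs O(n p^3) and vectorizes over parameter draws. The
   data-dependent Jacobian of the change of variables from `logX` to
   `(Z, logYtilde)` is constant in the parameters and dropped.

2. **Ensemble MCMC on the reduced posterior.** The remaining parameters
   (some tens of dimensions) are sampled with an affine-invariant ensemble
   sampler (emcee) using differential-evolution moves, initialized from a
   Laplace approximation around the posterior mode (found by L-BFGS with
   analytic gradients of the marginal likelihood chained through the
   constraining transforms; gradient code is verified against finite
   differences in the test suite). Walkers are treated as chains for
   rank-normalized split R-hat and ESS (arviz); the fit warns when
   R-hat > 1.01 or ESS < 200. `logYtilde` draws are recovered *exactly*:
   its full conditional given each retained draw is Gaussian with a
   closed form in the same eigenbasis, so retained draws are samples from
   the true joint posterior.

Defaults are 4,000 ensemble iterations with a 2,000-iteration warmup. The
test suite and the acceptance script use 2,000 iterations (800 warmup) and
problem sizes n in {50, 100}, p in {5, 10} with 5-20 replicates per
condition — sizes chosen so the full suite completes on a single CPU while
every check retains clear statistical resolution; the full study design
(8,000 simulated datasets) is available through `run_grid`/the `grid` CLI.

### Priors

The model itself does not dictate priors; these are package choices:

- `lambda ~ Uniform(0, 1)` (the transform is only defined there), sampled
  on the logit scale.
- `Z0` via an additive-log-ratio vector (last taxon as reference) with a
  flat prior on the unconstrained scale; this keeps `sum(Z0) = 1` exactly.
- `R = diag(sigma) * Omega * diag(sigma)`; `sigma_j ~ HalfNormal(2.5)` on
  the depth-rescaled tree, `Omega ~ LKJ(1)` (uniform over correlation
  matrices) through its Cholesky factor. This guarantees SPD draws.
- `logYtilde_i ~ Normal(0, 5)` i.i.d. — weak regularization of the latent
  scale, which the data only weakly identify along the all-taxa direction.

The tree is rescaled to unit depth before inference for numerical
conditioning; reported `R` (and `sigma`) are transformed back to the input
tree's time units. Lambda and `Z0` are unaffected by this rescaling.

### Significance

- **Covariances**: an entry of `R` is called significant when its central
  95% credible interval excludes 0.
- **Phylosymbiosis**: lambda is positive by construction, so a credible
  interval against 0 is uninformative; significance uses permutations
  instead. Host species are shuffled (optionally only within groups of
  hosts sharing the same diet / realm / flying ability, to ask whether
  trait conservatism alone explains the signal), the model is refitted to
  each shuffled dataset, and the one-sided add-one p-value
  `(1 + #{null >= observed}) / (1 + n_perm)` is reported; `p <= 0.05`
  corresponds to the observed lambda exceeding at least 95% of the null
  values. The default estimator for observed and null lambda alike is the
  posterior mode of the marginalized posterior (fast; null fits warm-start
  from the observed mode), with `estimator="mcmc"` switching to posterior
  means from full ensemble runs. Because observed and null values are
  computed identically, the exchange under the null is preserved either
  way; the mode was chosen as the default because a 100-permutation test
  then costs seconds rather than hours.

## Simulator

`simulate_microbiota` draws branch-wise Brownian increments on the
lambda-transformed tree (rather than sampling tip states from `C (x) R`),
so true internal-node states are recorded and reconstruction accuracy can
be measured. Host trees come from a pure-birth (Yule) process seeded
deterministically; after the n-th lineage appears one further exponential
waiting time is added so terminal branches are non-degenerate. Study
conditions follow the simulation design the package is built around:
n in {20, 50, 100, 250}, p in {3, 5, 10, 15}, root log abundances uniform
on [-4, 0] then normalized to the simplex, rate matrices with eigenvalues
1/4, lambda in {1, 0.75, 0.5, 0.25, 0}, 100 replicates per cell.

One subtlety: conjugating `diag(1/4, ..., 1/4)` by a random orthogonal
matrix yields exactly `I/4` — equal eigenvalues admit no off-diagonal
structure. `random_spd` therefore defaults to that literal construction
(used for lambda/Z0 recovery and null calibration, where a diagonal truth
is in fact convenient) and offers `spectrum="random"` (eigenvalues drawn
from Gamma(2, 1), rescaled to mean 1/4) when covariance recovery is the
point of the experiment.

What the simulator deliberately omits: read-count/sequencing noise,
compositional zeros from detection limits (available behind an optional
`floor` argument, off by default), taxon gain/loss dynamics, and
non-constant `R` along the tree. Passing tests on simulated data therefore
show correctness of the inference machinery under the model's own
assumptions, not robustness to metabarcoding artefacts.

## Ancestral reconstruction

Conditional on point estimates (posterior means), internal-node states are
the Brownian conditional expectations on the lambda-transformed tree:
`logX_hat(nodes) = logZ0 + V_nt V_tt^-1 (logX(tips) - logZ0)`, where the
`V` blocks are shared-path covariances including internal nodes. Because
`R` enters the node/tip joint covariance as a common Kronecker factor, it
cancels from the conditional mean — the GLS weights depend on the tree
alone, applied per taxon. Node compositions are the renormalized
exponentials of the estimated log abundances (reconstruction lives on the
log scale; displayed pies live on the simplex). Conditioning on the
posterior-mean `logYtilde` (rather than integrating over it) matches how
the root composition itself is reported; the GLS can be repeated over
posterior draws to propagate uncertainty.

## Downstream analyses

- **Ordination**: PCA of centered-log-ratio-transformed extant
  compositions; ancestral compositions are CLR-transformed and projected
  passively (no influence on the axes).
- **Ancestral diet signal**: Euclidean distance on the first five
  (unscaled) PC axes between the projected ancestor and the centroid of
  each diet class (plants / fruits / invertebrates / meat).
- **Integration**: taxa are clustered by greedy modularity maximization on
  the graph whose edge weights are the positive covariances of `R`
  (negative covariances and the diagonal carry no edges).
- **Mantel baseline**: Pearson correlation between patristic distances
  (untransformed tree) and Bray-Curtis dissimilarities, with a one-sided
  permutation p-value — the correlative test the model-based permutation
  test is benchmarked against.
- **Adequacy**: datasets are re-simulated from the fitted parameters and
  projected into the empirical CLR-PCA space; the report gives, per PC,
  the fraction of empirical scores inside the simulated scores' 2.5-97.5%
  envelope (an operationalization of the visual overlap check).

## Data preparation

`prepare_table` reproduces the empirical preprocessing: drop species with
fewer than 2 samples, average samples per species (a one-random-sample
variant exists for robustness checks), keep taxa exceeding 1% of the total
abundance across retained species, floor absent taxa at 0.001% (1e-5), and
renormalize rows to the simplex. Flooring without renormalization is
exposed in the prep report for comparison, but the returned table is
always simplex-valid because the model requires it. Tables and trees are
reconciled strictly by species name, never by position.

## Numerical choices and edge cases

- Ultrametricity tolerance: 1e-6 relative to tree depth; polytomies are
  rejected by default, or resolved to zero-length bifurcations on request.
- `lambda` is sampled on the closed interval's interior via the logit
  scale; `C` at `lambda = 0` is diagonal and remains valid.
- Non-PD covariances anywhere raise with an explicit message; the GLS tip
  covariance can be jittered (1e-10) by explicit opt-in for trees with
  near-duplicate tips.
- Posterior-mean `R` is projected to the nearest SPD matrix (eigenvalue
  clip) in the rare case the mean of SPD draws is indefinite.
- Permutation p-values use the add-one rule and can never be exactly 0.
- All stochastic entry points take seeds; MCMC runs are bit-reproducible
  for a fixed seed and configuration.

## Known limitations

- No drift/trend term: abundances fluctuate around the root state; clades
  with directional change (early bursts, sustained trends) violate the
  model.
- `R` is constant along the tree.
- The latent-scale prior (`tau = 5`) weakly informs total abundances; data
  cannot identify a global abundance scale, only relative totals.
- **Common-mode covariance is prior-driven.** Because only relative
  abundances are observed, the data identify essentially the row/column-
  centered projection `P R P` (with `P = I - J/p`) of the rate matrix; the
  components of `R` along the all-taxa direction are informed mainly by the
  `logYtilde` prior. Concretely, a single planted covariance `R_12 = c` in
  an otherwise diagonal `R` retains only `c(1 - 2/p) + (2c + tr-terms)/p^2`
  of its magnitude after centering — at p=5 roughly 40% — and the remaining
  common-mode uncertainty widens the credible interval accordingly.
  Detection of *individual* absolute covariances from compositional data is
  therefore conservative, and more so for small p; significance calls are
  best interpreted as statements about the centered covariance structure.
  Tightening the latent-scale prior sharpens these calls but substitutes
  prior information for data; the default deliberately does not.
- The ensemble sampler mixes more slowly than gradient-based HMC on large
  `p`; for `p` beyond ~15, expect long runs (convergence warnings will
  say so).
- Ancestral reconstructions inherit all biases of relative-abundance
  profiling (rRNA copy number, primer bias), which the model does not see.
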