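# Methods

## The model

A latent space item response model (LSIRM) describes binary responses
`Y_pi` of person `p` on item `i` as

    P(Y_pi = 1) = sigma(theta_p + beta_i - gamma * d(w_i, z_p)),

where `sigma` is the logistic function, `theta_p` and `beta_i` are person
and item intercepts (a Rasch model), `z_p, w_i` are coordinates in a shared
D-dimensional Euclidean space, `d` is the Euclidean distance, and
`gamma > 0` weights the distance term.  Proximity of a person to an item
raises the response probability beyond what the intercepts explain, so the
map exposes person-item, item-item and person-person interactions that a
plain Rasch model treats as noise.

Under joint maximum likelihood (JML) all parameters are fixed effects and
the likelihood contains no integrals.  Two parameters lose their identity in
this regime and are deliberately absent from the fitted model:

* `gamma` is absorbed into the scale of the coordinate estimates (fitting
  always uses `gamma = 1`; the generator accepts any value);
* the latent scale itself, for the same reason.

### Regularized estimators

Unregularized JML is ill-posed here (a person answering everything
positively sends their intercept to infinity), so two regularized variants
are provided:

* **pJML** maximizes the joint Bernoulli log-likelihood minus
  `(lambda/2) * (sum theta^2 + sum beta^2 + sum z^2 + sum w^2)`.
  `lambda = 1` (the default, used everywhere in the shipped experiments)
  makes the regularization equivalent to standard normal priors in the
  joint-modal (MAP) sense.
* **cJML** maximizes the unpenalized likelihood subject to
  `||(theta_p, z_p)|| <= C_person` and `||(beta_i, w_i)|| <= C_item`,
  the joint-modal analogue of uniform ball priors.  Defaults
  `C_person = 2 sqrt(D+1)`, `C_item = 5 sqrt(D+1)` follow the
  `5 sqrt(dim)`-style bounds used for constrained multidimensional IRT with
  the dimension taken as D+1 (intercept plus coordinates); the implied
  per-coordinate prior variance `C^2/(D+3)` exceeds 1 for both, i.e. the
  constraints are weaker than the pJML penalty.  Both constants are
  configurable; they are stand-ins, chosen once, not fitted.

Because cJML is only weakly regularized, it shows essentially no shrinkage
of the coordinate scale, while pJML contracts it noticeably whenever the
latent distances push the logistic into its flat tails.  This is why the
distance-weight absorption experiment (below) is carried by cJML.

### Identification: echelon rotation

Distances are invariant under common rotation, reflection and translation
of all coordinates.  Location is anchored by the penalty (pJML) or the
origin-centered balls (cJML); rotation is removed by the echelon
constraint: the first D-1 item rows of W are upper-triangular-zero (item 1
loads only on dimension 1, item 2 on dimensions 1-2, ...), giving
D(D-1)/2 hard zeros that are excluded from the free parameter set during
optimization.  Reflections are fixed by requiring a nonnegative diagonal
`W[d, d] >= 0`.  A standalone `echelon_rotate` utility (sequential Givens
rotations, LQ-style) brings externally produced solutions — e.g. MCMC
posterior means — to the same orientation for comparison, and
`align_to_reference` (orthogonal Procrustes) aligns replicate fits for
bootstrap aggregation and recovery scoring.  Anchor items default to the
first D-1 data columns and are configurable; results can depend on this
choice and no attempt is made to optimize it.

## Optimization

Block coordinate ascent with backtracking line search; the objective trace
is non-decreasing by construction.  pJML updates theta, beta, Z, W
sequentially; cJML alternates a person block (all `(theta_p, z_p)` rows)
and an item block (all `(beta_i, w_i)` rows), projecting each row back
onto its ball after the gradient step.  Three numerical choices matter and
were made after observing that the plain recipe (small random starts, raw
gradient steps) left two-dimensional fits in poor local optima — far enough
below the reachable optimum to corrupt downstream model comparison:

1. **Diagonal curvature preconditioning.**  Gradient steps are scaled by
   the inverse Bernoulli information `sum p(1-p)` accumulated per person /
   per item (plus `lambda`).  This equalizes progress across persons of
   very different response counts; the natural step multiplier is then 1.0
   (`step_init`), halved up to 10 times on backtracking and grown by 1.3
   (capped at 4) after clean accepts.
2. **Spectral initialization** (`init="svd"`, the default).  Crude logits
   of the responses are double-centered to seed the intercepts; the leading
   singular vectors of the residual, shrunk by 0.3, seed the coordinates.
   Deterministic, so equal options imply bit-equal fits.  `init="random"`
   (i.i.d. N(0, 0.1^2)) remains available and is seeded.
3. **Dimension annealing** (`anneal_dims=2` by default).  Distance
   embeddings optimized directly in low dimension suffer from barrier-type
   local optima (points cannot pass each other).  The fitter first
   optimizes briefly in D+2 dimensions, then repeatedly projects the joint
   configuration onto its leading principal subspace, re-identifies, and
   re-optimizes one dimension lower.  On test problems (N=2000, 24 items,
   strong distance weight) this recovers the objective attained from a
   truth-initialized fit to within ~0.2 log-likelihood units, where direct
   fitting stalls ~70 units short.

cJML additionally warm-starts from the pJML solution by default: its
alternating projected ascent reaches markedly higher constrained
likelihoods when continued from the penalized optimum than from any cold
start tried.

Convergence: relative objective change below `rel_tol` (default 1e-6,
maximum 2000 iterations).  Probabilities inside the reference
log-likelihood are clamped at 1e-12; the optimizer itself uses the
softplus form, which needs no clamping.  A zero person-item distance uses
the zero subgradient.  Missing responses simply drop out of the likelihood
(missing at random); rows or columns with no observations are rejected
before fitting.

## Ordinal responses

Ordered responses in `0..C_j-1` (category counts may differ by item) follow
a sequential / continuation-ratio model: category boundary `c` is passed
with probability `sigma(theta_p + b_jc - d(w_j, z_p))` given boundary
`c-1` was passed.  Estimation expands each item into `C'_j - 1` cumulative
binary dummy items — dummy `c` is 1 if the response reached category `c`,
0 if it stopped at `c-1`, and missing if the process stopped earlier — and
fits the binary model with all dummies of an item tied to a single `w_j`
(their gradient contributions are summed).  The expanded-binary likelihood
is identical to the sequential likelihood, which a dedicated oracle
implementation verifies to 1e-10.  The lowest observed category is the
reference; categories never observed are collapsed out with a logged
notice.  No monotonicity is imposed on estimated thresholds (each boundary
is separately identified); a post-fit flag records whether they came out
ordered.

## Dimension selection by cell-wise cross-validation

Folds partition the observed (person, item) *cells*, not rows: K folds of
near-equal size (remainder cells to the first folds), drawn once per run
and shared across all candidate dimensions.  For each candidate D and fold,
the model is refit with the fold's cells masked and the held-out cells are
scored by three "unnormalized" metrics (smaller is better, values add over
folds): UCE (misclassifications at a 0.5 threshold, ties classified as 1),
URE (`n_k * (1 - AUC)` with midrank AUC; single-class folds count 0.5 with
a warning), and RSS.  Each metric selects the argmin total, ties broken
toward the smaller dimension.

## Synthetic data

The generator emulates the deductive-reasoning-inspired design: item
intercepts are a random permutation of an equally spaced grid on [-2, 2];
the first item-coordinate dimension decreases from 2 to -2 in equal steps;
remaining item coordinates are N(0, 1); person intercepts N(0, 1); person
coordinates bivariate normal with unit variances and correlation 0.3; a
24-item parameter block is tiled for item counts that are multiples of 24.
The distance weight is `gamma` (1 by default; 1.7 reproduces the base
study conditions, where the latent space has a strong grip on the data).
Constants not pinned anywhere were chosen once as unremarkable values
producing non-degenerate response distributions, and are all configurable.

What the generator does *not* emulate: guessing/slipping, local item
dependence beyond the latent space, systematically missing data, person
clusters.  Passing recovery tests therefore demonstrate internal
consistency of estimator and generator, not robustness on real data.

Recovery scoring rescales each replicate's estimates to the truth's
standard deviation (separating shrinkage, reported as the SD's mean bias
against its expectation — `gamma * SD(truth)` for coordinates — from
positional error, reported as MAB/VAR/MSE after alignment and division of
coordinates by `gamma`).

## Bootstrap uncertainty

Persons are resampled with replacement (the item design stays fixed, as in
the illustrations the procedure serves); each replicate is refit with
identical options, echelon-rotated, and Procrustes-aligned to the point
estimate so orientation indeterminacy cannot inflate spread.  Item-side
SDs across aligned replicates are the standard errors; for D=2 each item
gets a confidence ellipse from its empirical 2x2 covariance scaled by the
chi-square(2) quantile.  Echelon-fixed coordinates are reported with SE 0
and a "constrained" flag (their ellipse degenerates to a line).
Person-level SEs are not reported: row resampling breaks the person
correspondence.  Replicates whose refit fails are dropped and counted;
more than 20% failures abort.

## Problem sizes in the shipped experiments

The replicated experiments (test suite and `scripts/acceptance.py`) use:
selection studies with 50 replications at N=500 and 30 at N=2000 (J=24,
K=10, candidates {1,2,3}, pJML, distance weight 1.7); absorption check with
one N=2000, J=96 dataset.  Fits inside replication loops use
`max_iter=300`, `rel_tol=1e-5`, `anneal_dims=1`; spot checks with the
stricter library defaults left the selection outcomes unchanged.

## Known limitations

* The person-intercept and distance effects are partially confounded:
  even truth-initialized fits cap the person-intercept recovery
  correlation near 0.87 on the default N=1000/J=48 design.
* pJML's coordinate shrinkage grows with the latent scale (saturated
  logistic tails carry little gradient, so the penalty wins); at distance
  weight 1.7 the absorbed scale is recovered at ~0.8 of its value by pJML
  but fully by cJML.
* In the larger-sample selection design (N=2000, J=24) the D=3 model's
  held-out performance ties D=2's about half the time under this
  generator's constants, even at oracle-quality optimization; errors remain
  exclusively overselections.
* Consistency of regularized JML for this nonlinear, high-rank distance
  model is an open theoretical question; nothing here depends on it.
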