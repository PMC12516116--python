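# Methods

## Models

**2PL measurement model.** Binary responses `y_ij` (persons i = 1..n,
items j = 1..p) follow independent Bernoulli draws given the latent trait,
with `logit P(y_ij = 1 | z) = alpha_0j + alpha_1j z`.  Items are assumed
conditionally independent given a unidimensional trait, and the item
response function is taken as correctly specified: the tests here target
the *latent density*, and will also pick up IRF misfit if it is present.

**SNP latent density.** `h(z) = P_L(z)^2 phi(z)` with `P_L` a polynomial
of degree L in {0, 1, 2} and `phi` the standard normal density.  The
coefficients are parameterized by L angles, each in (-pi/2, pi/2]:

* L = 1: `a0 = sin(phi1)`, `a1 = cos(phi1)`.
* L = 2: `a1 = cos(phi1) sin(phi2)`, `a2 = cos(phi1) cos(phi2) / sqrt(2)`,
  `a0 = sin(phi1) - a2`.

With these maps `a' G a = 1` identically, where `G` is the Hankel matrix of
standard-normal moments, so `h` integrates to one for every angle vector
(a property test verifies this over random angles).  The `1/sqrt(2)`
constant in `a2` is forced by that normalization.  Setting every angle to
pi/2 returns the standard normal; an angle of exactly -pi/2 yields the same
density as +pi/2 (the polynomial flips sign, its square does not) and is
mapped to +pi/2 to keep one representative.  Moments of `h` are evaluated
in closed form through Gaussian moment identities (degree <= 6), not by
quadrature; their angle-derivatives, needed by the rescaling Jacobian, are
analytic as well.

## Estimation

**Pairwise likelihood (SNP0).** The composite log-likelihood sums log
bivariate margins over all p(p-1)/2 unordered item pairs, each margin an
integral of the two item curves against the normal density.  All pairs are
weighted equally.  Starting values are marginal-logit intercepts and unit
slopes.  Per-person scores are analytic; the bivariate cell probabilities
are computed for all pairs at once from p x Q node-probability matrices.

**SNP maximum likelihood.** The marginal likelihood integrates the
response-pattern probability against `h`, approximated by Gauss-Hermite
quadrature after the change of variable that absorbs `phi(z)` into the
weights.  The default rule uses 49 nodes; a convergence test doubles the
node count and requires the log-likelihood to move by less than 1e-6.
Optimization is by L-BFGS-B with analytic gradients **on the raw metric**,
where item parameters are calibrated to the unstandardized fitted density.
This matters: the test's Monte-Carlo behavior depends on how the
optimizer explores the likelihood from the prescribed starting values in
that metric — the quasi-likelihood in the shape angles is extremely flat
under near-normal data, and a global standard-metric search finds
spurious interior shape optima that materially change the test's null
behavior.  Starting values:

* L = 0: marginal logits / unit slopes.
* L = 1: item parameters from the L = 0 ML fit; ten phi1 starts from a
  0.1-spaced grid over (-pi/2, pi/2]; the fit with the highest likelihood
  is kept.  The estimator API picks the ten grid points deterministically
  (evenly indexed) for reproducibility; the study engine instead samples
  them per replication with a seeded generator.
* L = 2: supplied item starts (the study engine uses the generating
  values — an oracle-start device, clearly labeled as such) with
  seven phi starts: skew shapes of varying strength in both sign
  orientations plus the normal corner.  Both orientations are needed
  because `phi2 -> -phi2` mirrors the density (`z -> -z`): a single
  orientation strands the optimizer in the wrong-skew basin, and the
  likelihood surface has orientation-separated local optima.

After optimization the estimates are rescaled to the standard-normal
metric (`alpha_0 + alpha_1 E(Z)`, `alpha_1 sqrt(V(Z))` with E, V the
fitted latent moments), and per-person scores are expressed on that metric
through the analytic Jacobian of the rescaling map (including its
moment-derivative terms), so the two estimators are directly comparable.

**Sandwich matrices.** `A` is the negative Hessian of the total
log-likelihood (positive definite near an interior maximum; the sign
convention is applied consistently), obtained by symmetrized central
finite differences of the analytic gradient with step `1e-5 *
max(1, |theta_i|)`; `B` is the cross-product of per-person scores; the
PL-by-ML cross-product matrix `R` is assembled from the two stored score
matrices.  Convergence of a fit requires optimizer success and a
per-person score-sum below 1e-3 (fits with an angle within 1e-6 of pi/2
are accepted on optimizer success alone, as the normal sub-case).

## The Hausman test

The difference vector `d` stacks intercept and slope differences
(rescaled SNP ML minus PL), dimension 2p.  Its covariance estimate is

```
S = Atf Bml Atf' + Apl^-1 Bpl Apl^-1' - Atf R' Apl^-1' - Apl^-1 R Atf'
```

with `Atf` the first 2p rows of the inverse ML A-matrix (dropping the L
angle rows).  `d` and `S` are kept on matched, person-summed scales, so
the null distribution of `GHT = d'd` is the weighted chi-square
`sum(lambda_l * delta_l^2)` with weights the eigenvalues of `S`; any
common rescaling of both (e.g. the sqrt-n convention) leaves the p-value
unchanged.  `S` can be indefinite in finite samples: eigenvalues below
`1e-10 * max|lambda|` (including all negatives) are discarded and the
discarded count is recorded.  The surviving eigenvalues give the
moment-matching scale `a = sum(l^2)/sum(l)` and degrees of freedom
`b = (sum l)^2 / sum(l^2)`; by construction `a*chi2_b` matches the first
two moments of the weighted sum exactly.  The full form `d' S^-1 d`
(chi-square, 2p dof) is provided but requires a well-conditioned `S`.

## Reference statistics

* **LR**: `2 (loglik_SNPL - loglik_SNP0)`, both full-ML fits, chi-square
  with L dof; small negatives (within 1e-6) are clamped, larger ones raise
  (they indicate an under-optimized larger model).
* **Summed-score Pearson statistic**: model-implied total-score
  probabilities by the Lord-Wingersky recursion over the quadrature grid
  (exact up to quadrature error; a 2^p enumeration oracle checks it for
  small p); dof p - 2, so at least 3 items are required.
* **M2**: univariate and bivariate residuals (margins ordered univariate
  first, then pairs j < k lexicographically), weight matrix
  `Xi^-1 - Xi^-1 D (D' Xi^-1 D)^-1 D' Xi^-1` with `Xi` the multinomial
  margin covariance (joint success probabilities of margin-set unions,
  by quadrature) and `D` the analytic Jacobian of the margins in the
  fitted parameters; dof p(p+1)/2 - k.  The moment-adjusted variant of the
  summed-score statistic is deliberately not implemented.
* **AIC / BIC / HQ** with k = 2p + L.

## Monte-Carlo study engine

Latent-trait scenarios (mixture components written N(mean, sd); the
second argument is a standard deviation throughout.  Scenario C is often
quoted with variance 2.37, which matches a *variance* reading of its
".25" component, while scenario B's quoted 1.38 matches the sd reading;
the sd convention is applied uniformly and the discrepancy documented
rather than resolved):

| scenario | trait distribution | mean | variance |
|---|---|---|---|
| A | N(0, 1) | 0 | 1 |
| B | .7 N(-1, .7) + .3 N(1, .8) | -.40 | 1.38 |
| C | .1 N(-2, .25) + .9 N(2, 1) | 1.6 | 2.35 |
| D | SN(loc -2.5, scale 2, shape 5) | -.93 | 1.55 |
| E | SN(loc -2.5, scale 2, shape 10) | -.91 | 1.48 |

Item banks draw intercepts from Uniform(-.8, 1.12) and slopes from
Uniform(.5, 1.5), once per study (fixed across replications; per-replication
redraw available).  Each replication simulates responses, fits the models
required by the requested tests (GHT1 needs PL + SNP0-ML + SNP1-ML; GHT2
needs PL + SNP2-ML with oracle starts; LR/score/M2 tests need SNP0-ML),
and records statistics, p-values and rejections at each nominal level.
Replications with a non-converged fit or a degenerate covariance are
excluded from the valid count for the affected statistic only.  Rejection
rates come with the nominal-variance confidence band
`z * sqrt(alpha(1-alpha)/Nv)` and, for power use, the Wald band
`z * sqrt(p(1-p)/Nv)`.  Selection percentages count replications where a
criterion is strictly smaller for the larger model.  All randomness flows
from one base seed through spawned child sequences (bank, then one child
per replication), so results are independent of execution order and
exactly reproducible; replications run sequentially.

**Problem sizes.** The package's default study cells are 10 items with
n = 500-1000 and 100-300 replications (the acceptance script uses 150-300
per cell; the test suite 80-150).  These give binomial standard errors of
2-5 points on the rates being checked, which is the resolution at which
the comparisons are made.  The 20-item and n = 5000 cells run through the
same engine via configuration but are intentionally not part of the
default runs; their behavior is covered instead by property checks
(p-value uniformity under the null, power monotone in n and in departure
severity, parameter recovery at n = 5000).

## What the generator does and does not emulate

The synthetic module reproduces the study conditions exactly: independent
binary responses from logistic IRFs, unidimensional traits, complete data,
item parameters in moderate ranges.  It does not emulate multidimensional
traits, local item dependence, guessing behavior, missing responses, or
the extreme slopes (> 3) seen in some real questionnaire data — settings
in which all of the tests implemented here are known to degrade.  Passing tests therefore certify the implementation under the
stated sampling conditions, not robustness to those violations.

## Known limitations

* The Hausman test's null calibration is sensitive to how the SNP fit
  treats shallow noise optima in the shape angles.  Under near-normal data
  the quasi-likelihood is almost flat in phi, with spurious interior
  optima whose gains are fractions of a log-likelihood unit; whenever the
  multi-start selection lands on one, the rescaled item estimates move
  away from the pairwise estimates by more than the difference covariance
  (a local, sandwich-based estimate) can account for, and the test
  over-rejects.  The more thoroughly the optimizer explores, the more
  often this happens: with the default multi-start the empirical Type I
  error at the 5% level sits around .08-.15 for 10 items and n = 1000-5000
  rather than at the nominal level, varying with the item bank.  Users
  wanting strict Type I control should corroborate a marginal GHT
  rejection with the likelihood-ratio test or with information criteria,
  which are insensitive to this mechanism at conventional thresholds.
* The SNP2 fit is sensitive to starting values; outside the study engine
  (which uses oracle starts) it starts from the SNP0-ML fit and the two
  mirrored skew starts, which is robust but not guaranteed global.
* The shape angles are very weakly identified under near-normal data;
  fitted angles should not be interpreted, only the implied density and
  the rescaled item parameters.
* The generalized-residual test R(z)/RB and the moment-adjusted
  summed-score variant are out of scope; polytomous items, missing data
  and degree L >= 3 are not supported.
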