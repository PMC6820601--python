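# Methods

`fieldspatial` analyses agricultural field trials with explicitly spatial
plot effects and (optionally) genomic information, and ships the simulator
that generates the data its case studies run on. This note records the
models, the priors, the numerical choices, and what the synthetic data do
and do not represent.

## Observation model

Phenotypes are Gaussian around a linear predictor,

    y(s_i) | eta(s_i), sigma2_e ~ N(eta(s_i), sigma2_e),
    eta(s_i) = beta_0 + w_i beta + g_j + x(s_i),

with fixed effects (intercept or trial-specific intercepts, plus covariates
such as planting density), a genetic effect `g_j` for the line in plot `i`,
and a spatial plot effect `x`. All effects are Gaussian, so the latent
field has an exact Gaussian conditional posterior given the
hyperparameters; the package is a Gaussian-likelihood specialization of
the integrated-nested-Laplace scheme in which the only approximation is
the numerical treatment of the low-dimensional hyperparameter posterior.

### Genetic effects

Three parameterizations:

* iid line effects `n_j ~ N(0, sigma2_n)` — genetic independence;
* a genomic relationship (VanRaden) effect `a ~ N(0, A sigma2_a)` with
  `A = Z Z' / k`, `Z` the column-centred dosage matrix and
  `k = 2 sum_l q_l (1 - q_l)`;
* marker-component effects: `Z` is compressed by SVD to the leading
  principal components (`Z* = Z V[:, :p*]`, with `p*` either fixed or the
  smallest count explaining a requested share — default 95% — of the
  variation in `Z`), and `a = Z* u*` with iid `u*`. The marker and GRM
  forms are equivalent reparameterizations when `sigma2_a = k sigma2_u`
  and the full component set is kept; this equivalence is tested.

Markers fixed by selection carry no information and break the VanRaden
scaling, so `polymorphic_mask` drops them before the GRM is formed;
prediction cohorts are centred with the *training* allele frequencies and
rotated with the training `V`. Non-genotyped lines can be appended to `A`
as an identity block with zero cross-relationship.

### Spatial effects

* **Row+column**: `x_i = r_row(i) + c_col(i)` with independent Gaussian row
  and column effects (two variances).
* **AR1 x AR1**: the covariance of the plot-effect vector is
  `sigma2_x * R_r ⊗ R_c` with unit-marginal AR1 correlation factors in the
  row and column lattice directions; the precision is the Kronecker product
  of tridiagonal AR1 precisions. The model operates on integer lags and
  ignores physical spacing. The inverse-gamma variance prior sits on the
  *marginal* plot variance, matching the convention under which the
  autocorrelation prior is stated.
* **Matern field**: a stationary Gaussian random field with Matern
  covariance (smoothness nu = 1 throughout; exposed as a parameter for
  tests only), parameterized by `(log kappa, log tau)` with
  `kappa = sqrt(8 nu) / range` and the marginal variance
  `sigma2_s = Gamma(nu) / (Gamma(alpha) (4 pi)^{d/2} kappa^{2 nu} tau^2)`.
  The default computational path is the exact dense covariance (inverted
  once per hyperparameter evaluation, cached per trial group), which is
  simple and exactly testable at the package's problem sizes (<= a few
  thousand plots). A sparse SPDE finite-element backend (`fieldspatial.spde`,
  alpha = 2, lumped-mass P1 elements on a regular triangulated grid) is
  provided and equivalence-tested against the exact covariance; its default
  mesh uses spacing range/10 and a boundary extension of one range, which
  keeps interior correlations within about 0.02 of exact (a range/5 mesh
  leaves ~0.08 errors at short distances, so the coarser spacing sometimes
  suggested for such meshes is not the default here).
* Anisotropy is handled only through coordinate scaling (the simulated
  wheat fields have column spacing twice the row spacing, which the Matern
  model sees through the physical coordinates); no anisotropic covariance
  is fitted.

Multi-trial data get one spatial field per trial, independent across
trials; trials can be grouped to share spatial hyperparameters, which is
how four trials are fitted with two hyperparameter sets.

## Priors and transforms

Weak default priors on the hyperparameters:

* variances: inverse gamma, shape 1, scale 5e-5. This prior concentrates
  substantial mass at very small variances; it behaves innocuously when
  the likelihood is informative but *shrinks weakly identified variance
  components toward zero* (see "Desk scale" below).
* autocorrelations: Gaussian(0, sd 0.15) on the transform
  `z = log((1 + rho)/(1 - rho))`, putting the central 95% of rho at about
  ±0.15. (The transform is sometimes printed with the numerator and
  denominator signs flipped, which is undefined for |rho| < 1; the form
  used here is the one that reproduces the ±0.15 percentiles.)
* `(log kappa, log tau)`: independent unit-sd Gaussians, centred at the
  values implied by a range of one fifth of the field diameter and unit
  marginal variance, so the prior guess scales with the extent of the data.
* fixed effects: Gaussian with variance 1000.

All optimization happens on the unconstrained scale (log variances,
Fisher-type z, log kappa/tau) with Jacobians included in the prior terms.

## Inference

For hyperparameters theta, the marginal posterior is available in closed
form (log-determinants plus a quadratic form). `fit()`:

1. finds the mode by L-BFGS-B from a deterministic, scale-aware start
   (variances split the sample variance of y evenly; rho starts at 0; the
   Matern range starts at a quarter of the field diameter), bounded to
   [-25, 25] per coordinate, gradient tolerance 1e-6, at most 200
   iterations (non-convergence is an error, not a warning);
2. takes a central-difference Hessian (step 0.1) at the mode, eigenvalue-
   clipped to positive definiteness, for Laplace scales;
3. integrates the latent posterior over theta points: `eb` (mode plug-in),
   `grid` (3 points per dimension scaled by the Laplace sds; default up to
   4 hyperparameters) or `ccd` (mode ± axis points; default above 4), with
   weights proportional to the re-evaluated posterior;
4. reports mixture means/sds for every latent effect, Laplace-Gaussian
   intervals for hyperparameters (transformed monotonely to the natural
   scale), and log-linear interval propagation for the derived Matern
   range and variance.

Linear combinations of latent effects (line breeding values `Z* u*`,
field reconstructions) mix means over the integration points but use the
modal conditional covariance; this keeps memory linear in the number of
integration points and is accurate whenever the conditional covariance
varies slowly over the explored theta region. Any Cholesky that fails gets
one retry with a 1e-10 diagonal jitter. Models with more than 20
hyperparameters are refused (numerical integration over theta degrades;
a warning is issued above 10) — grouping trials is the intended remedy.

## Synthetic data

### Breeding programme

A wheat-like genome (21 chromosomes, equally spaced loci, 1 Morgan per
chromosome, Haldane no-interference meiosis, founder allele frequencies
uniform on [0.1, 0.9]) runs through a recurrent-selection programme:
biparental crosses among inbred parents, doubled-haploid progeny, headrow
selection into a two-location preliminary yield trial (PYT), then advanced
selection of new parents. QTL effects are Gaussian, rescaled once so the
year-1 DH cohort has genetic variance 1. The PYT plot residual variance is
anchored to plot heritability 0.25 *of that base cohort*
(`sigma2_e = sigma2_g_base (1 - h2)/h2 = 3`) and held fixed, so selection
and drift erode the realized heritability well below 0.25 over the burn-in
— this erosion, not the nominal 0.25, is what determines baseline accuracy,
and realized heritability is reported with every study run. Stage
heritabilities not pinned down by the study description were set once:
0.1 for headrows, 0.5 for the advanced stage. Year and location effects
are Gaussian with variance equal to the residual variance. The
"genotyped but not phenotyped" prediction cohort consists of extra DH
progeny of the same parental cohort in the recorded year.

Trial phenotypes are `year + location + breeding value + x + e`, with the
spatial field `x` drawn per location (independently) from either a Matern
field (range 10) or an AR1 x AR1 field (rho 0.8, a comparable ~10-unit
range) carrying 0/50/75% of the environmental variance, and `e` iid with
the remainder. Phenotypes are standardized per year across locations
before analysis (globally across trials for the multi-trial study, per
trial for single-trial fits); true breeding values are centred at the
phenotyped cohort's mean and divided by the standardization sd before
scoring, so scores are on the analysis scale.

What the generator does *not* emulate: dominance/epistasis,
genotype-by-environment interaction beyond independent location fields,
real linkage maps, or management/design artefacts (drilling, harvesting
lanes). Passing tests therefore demonstrate correct recovery under the
stated generating model, not robustness to these real-data features.

### Desk scale

The default study conditions are scaled down to run on a single CPU in
minutes, chosen once as follows and then left alone:

* programme: 50 crosses x 40 DH per year, top 200 headrows to a 20 x 10
  PYT at each of two locations, 30 parents, 10 burn-in years, genome
  21 x (100 SNP + 100 QTL), one recorded year per replicate. These sizes
  were picked so that variance erosion reaches the level the full-scale
  programme (100 x 100, 1000-line PYT, 19 burn-in years) reaches — the
  full programme's reported baseline accuracy (~0.39) implies a
  two-replicate reliability near 0.15, and the desk programme lands there
  (realized sigma2_g ~ 0.29 against sigma2_e = 3, implied baseline ~0.40).
* evaluation: 10 replicates (8 in the acceptance script, 5 in the test
  suite), empirical-Bayes hyperparameter treatment for the table fits;
  the top-capture rank window is one tenth of the cohort, preserving the
  full-scale null expectation of 1.0 captured individual.
* multi-trial: four trials of 20 x 10 plots (100 lines x 2 replicates)
  instead of 40 x 20 (400 x 2); the joint 40 x 20 fit would need ~3200
  dense latent spatial effects per hyperparameter evaluation, beyond the
  intended runtime of the dense path. Structure (grouping, joint-vs-single
  comparison) is unchanged, and full-size configurations remain available
  through the config dataclasses.

Consequences worth knowing. (1) With 200 lines and heritability ~0.1, the
likelihood for the iid genetic variance is weak and the inverse-gamma
prior can pull its mode to essentially zero. Correlation and ranking
metrics are invariant to the resulting uniform shrinkage, but CRPS then
degenerates toward mean absolute error; at the full 1000-line scale the
likelihood dominates and the collapse disappears. The marker and spatial
variances are well identified at both scales. (2) The desk field (19 x 18
units) is only about twice the spatial range, so spatial-model gains are
smaller than at full scale (e.g. Matern accuracy rises from ~0.40 to ~0.56
at 75% spatial variance, versus 0.39 to 0.57 at full scale without markers,
and to ~0.68 versus 0.74 with markers) and realized field variances
fluctuate more between replicates. The ordering of models — the study's
actual finding — is stable: AR1 x AR1 and Matern clearly beat Row+Col and
NoSpatial under spatial variation, match them without it, and NoSpatial is
insensitive to the spatial proportion.

### Nelder wheel

Ten rings, 30 spokes, inner radius 10, ring factor 1.15; the growing area
of ring `i` is `theta r_i^2 (k - 1/k)/2` and planting density its inverse.
Tree phenotypes: intercept 10 + density x 10 + Matern field (variance 0.5,
range 10) + N(0, 0.5) residual. The Matern fit uses the grid strategy
(3 hyperparameters); recovery is summarized as 95%-interval coverage of
the five generating values over seeds, and the spatial field is
reconstructed on a regular grid by Gaussian conditioning at the modal
hyperparameters (posterior sd is smallest where trees are densest).

## Evaluation

* Pearson correlation between true and estimated breeding values.
* CRPS with the Gaussian closed form
  `sigma (z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi))`, verified against
  numerical integration of the defining integral. The predictive used for
  each line is the Gaussian posterior marginal of its breeding value; CRPS
  is averaged over lines within a replicate, then over replicates.
* Top-capture: how many of the best `n_top` true lines appear in the top
  `n_rank` estimated ones ("best" = largest, a maximization trait; ties
  break by stable original order).
* Study tables report per-cell means with standard errors `sd/sqrt(n_rep)`
  and refuse incomplete replicate grids.

## Known limitations

* Dense linear algebra bounds the practical problem size (a few thousand
  latent effects per fit); the SPDE backend is equivalence-tested but not
  wired into `fit()` as the default path.
* Hyperparameter intervals are Laplace-Gaussian on the unconstrained
  scale; strongly skewed posteriors (short data ranges, small trials) are
  summarized only approximately.
* The inverse-gamma default prior's shrinkage of weak variance components
  is faithful to the reference defaults but is a known liability of those
  defaults; penalized-complexity priors would behave better and are not
  implemented.
* Non-Gaussian phenotypes (counts, scores) are out of scope.
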