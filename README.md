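# fieldspatial

Spatial mixed models and genomic prediction for agricultural field trials.

Field trials carry spatial variation — fertility, watering, soil depth —
that biases estimated genetic values when ignored, especially at
low-replication stages such as a preliminary yield trial where every line
appears once per location. `fieldspatial` fits the established spatial
models for this problem and combines them with genomic information, for
plant/tree breeders and biostatisticians analysing trial data or studying
trial design by simulation.

## The models

Phenotypes follow a Gaussian observation model

```
y(s_i) | eta(s_i), sigma2_e ~ N(eta(s_i), sigma2_e)
eta(s_i) = beta_0 + w_i' beta + g_j + x(s_i)
```

with a genetic effect `g_j` for the line in plot `i` and a spatial plot
effect `x(s_i)`:

* **NoSpatial** — `x` omitted;
* **Row+Col** — independent Gaussian row and column effects;
* **AR1 ⊗ AR1** — separable lattice covariance `sigma2_x · R_r ⊗ R_c`,
  the Kronecker product of row- and column-direction AR1 correlations;
* **Matérn** — a continuously indexed Gaussian random field,
  `C(d) = sigma2_s 2^(1-nu)/Gamma(nu) (kappa d)^nu K_nu(kappa d)` with
  `kappa = sqrt(8 nu)/rho` (range `rho` ≈ the 0.1-correlation distance),
  as an exact dense covariance or through a sparse SPDE finite-element
  approximation. Being coordinate-based, it handles irregular designs
  such as the Nelder wheel spacing trial.

Genetic effects are iid line effects, a VanRaden genomic relationship
effect (`A = ZZ'/k`, `k = 2 Σ q_l(1-q_l)`), or SVD-compressed marker
components `Z* u*`. Inference is full-Bayes for Gaussian latent models:
exact conditional posteriors of all effects plus numerical exploration
(mode, Laplace scales, grid/CCD mixing) of the hyperparameter posterior
under weak default priors. Multi-trial data are fitted jointly with
trial-specific intercepts and spatial hyperparameters grouped across
similar trials. Models are scored by the correlation between true and
estimated breeding values, the continuous ranked probability score (CRPS,
Gaussian closed form), and top-ranking capture.

A breeding-programme simulator (wheat-like genome, doubled-haploid
recurrent selection, two-location preliminary yield trials with
Matérn- or AR1⊗AR1-generated spatial variation) generates the study data;
see `docs/methods.md` for model details, priors, and the desk-scale study
conditions.

## Worked example

Fit the Nelder wheel spacing trial (300 trees, 10 planting densities in
one circular design) and recover the generating parameters:

```bash
python examples/nelder_wheel.py
```

```
tree positions: 300 (10 rings x 30 spokes)

Matern fit, 95% posterior intervals vs truth:
          intercept: truth  10.0  interval [  9.94,  10.71]  covered
     density effect: truth  10.0  interval [  7.03,  12.09]  covered
   spatial variance: truth   0.5  interval [  0.27,   0.81]  covered
      spatial range: truth  10.0  interval [  7.26,  23.04]  covered
  residual variance: truth   0.5  interval [  0.44,   0.76]  covered

NoSpatial residual variance: 1.08 (2.2x the true 0.5) -- the unmodelled spatial
field is absorbed into the residual

field reconstruction: posterior sd 0.48 inside the dense inner rings vs 0.67
beyond the outer ring
```

Every interval contains the value used to simulate the data; dropping the
spatial term roughly doubles the apparent residual variance, and the
reconstructed field is most certain where trees are planted most densely.

Other examples, one per capability: `spatial_models.py` (covariance
structures and range conventions), `breeding_programme.py` (simulator and
variance erosion under selection), `fit_lattice_trial.py` (spatial +
genomic fits on one trial — with 75% spatial variance, accuracy rises from
0.45 to 0.60 by modelling the field and to 0.68 with markers),
`multi_trial.py` (joint fit with grouped hyperparameters). A thin CLI
(`fieldspatial --help`) wraps the same functions for shell use.

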