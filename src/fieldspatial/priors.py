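"""Hyperparameter transforms and prior densities.

All hyperparameters are optimized on unconstrained scales: log variance,
the Fisher-type transform ``z = log((1+rho)/(1-rho))`` for autocorrelations,
and ``(log kappa, log tau)`` for the Matern field.  Priors follow the
weakly-informative defaults of the study system:

* variances: inverse gamma with shape 1 and (inverse) scale 5e-5 -- for the
  separable AR1 x AR1 model this prior sits on the *marginal* plot variance;
* transformed autocorrelation ``z``: Gaussian with mean 0 and sd 0.15,
  which puts the central 95% of rho at about +/-0.15;
* ``(log kappa, log tau)``: independent Gaussians with unit sd, centred so
  that the implied prior guesses scale with the size of the field (see
  :func:`matern_prior_means`).

All log-densities are expressed on the unconstrained scale and include the
change-of-variables Jacobian, so they can be summed directly into the log
posterior of the unconstrained hyperparameter vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .spatial import kappa_from_range, tau_from_sigma2

__all__ = [
    "rho_to_z",
    "z_to_rho",
    "InverseGammaVariancePrior",
    "FisherZGaussianPrior",
    "GaussianPrior",
    "Hyper",
    "matern_prior_means",
]


def rho_to_z(rho: float) -> float:
    """Unconstrained transform ``z = log((1 + rho)/(1 - rho))`` of an
    autocorrelation, a monotone bijection (-1, 1) -> R."""
    rho = float(rho)
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    return float(np.log((1.0 + rho) / (1.0 - rho)))


def z_to_rho(z: float) -> float:
    """Inverse transform ``rho = tanh(z / 2)``."""
    return float(np.tanh(np.asarray(z, dtype=float) / 2.0))


@dataclass(frozen=True)
class InverseGammaVariancePrior:
    """Inverse-gamma prior on a variance, evaluated on the log scale.

    Density ``b^a / Gamma(a) v^{-(a+1)} exp(-b/v)``; on ``t = log v`` the
    Jacobian contributes ``+log v``.
    """

    shape: float = 1.0
    scale: float = 5e-5

    def logpdf(self, t: float) -> float:
        a, b = self.shape, self.scale
        return a * np.log(b) - gammaln(a) - a * t - b * np.exp(-t)

    def logpdf_natural(self, v: np.ndarray) -> np.ndarray:
        a, b = self.shape, self.scale
        v = np.asarray(v, dtype=float)
        return a * np.log(b) - gammaln(a) - (a + 1.0) * np.log(v) - b / v


@dataclass(frozen=True)
class FisherZGaussianPrior:
    """Gaussian prior on the transformed autocorrelation ``z``."""

    mean: float = 0.0
    sd: float = 0.15

    def logpdf(self, z: float) -> float:
        return -0.5 * np.log(2.0 * np.pi * self.sd**2) - 0.5 * ((z - self.mean) / self.sd) ** 2

    def rho_quantile(self, p: float) -> float:
        from scipy.stats import norm

        return z_to_rho(norm.ppf(p, loc=self.mean, scale=self.sd))


@dataclass(frozen=True)
class GaussianPrior:
    """Gaussian prior on an already-unconstrained coordinate."""

    mean: float = 0.0
    sd: float = 1.0

    def logpdf(self, t: float) -> float:
        return -0.5 * np.log(2.0 * np.pi * self.sd**2) - 0.5 * ((t - self.mean) / self.sd) ** 2


@dataclass(frozen=True)
class Hyper:
    """One hyperparameter: unconstrained coordinate, prior and bookkeeping.

    ``kind`` drives both the natural-scale transform and the initialization
    rule used by the optimizer: ``variance`` (t = log v), ``rho`` (Fisher z),
    ``log_kappa`` / ``log_tau`` (Matern).  ``group`` tags spatial
    hyperparameters with their trial group; ``diameter`` carries the field
    extent used for scale-aware initialization of the Matern parameters.
    """

    name: str
    kind: str
    prior: object
    group: str | None = None
    diameter: float | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def to_natural(self, t: float) -> float:
        if self.kind == "rho":
            return z_to_rho(t)
        return float(np.exp(t))

    def from_natural(self, v: float) -> float:
        if self.kind == "rho":
            return rho_to_z(v)
        if v <= 0:
            raise ValueError(f"{self.name} must be positive")
        return float(np.log(v))

    def logpdf(self, t: float) -> float:
        return float(self.prior.logpdf(t))


def matern_prior_means(diameter: float, nu: float = 1.0) -> tuple[float, float]:
    """Field-size-aware centres for the (log kappa, log tau) prior.

    The prior guess is a range of one fifth of the field diameter and unit
    marginal variance, so a weak default prior automatically scales to the
    extent of the data rather than to fixed units.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    kappa0 = kappa_from_range(diameter / 5.0, nu)
    tau0 = tau_from_sigma2(1.0, kappa0, nu)
    return float(np.log(kappa0)), float(np.log(tau0))
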