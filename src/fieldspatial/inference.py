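"""Inference for Gaussian latent models with a small hyperparameter vector.

Because every model here has a Gaussian likelihood, the latent field
(fixed, genetic and spatial effects) has an *exact* Gaussian conditional
posterior given the hyperparameters theta: with prior precision ``Q(theta)``
(block-diagonal over effect blocks), observation matrix ``A`` and noise
variance ``sigma2_e``,

    Q_post = Q + A^T A / sigma2_e,     mu = Q_post^{-1} A^T y / sigma2_e,

and the marginal log-posterior of theta is available in closed form
(log-determinants plus a quadratic form) up to a constant:

    log p(theta | y) = -n/2 log(2 pi sigma2_e) + 1/2 log|Q|
                       - 1/2 log|Q_post| - 1/2 (y^T y / sigma2_e - b^T mu)
                       + log p(theta),

with ``b = A^T y / sigma2_e`` and the prior evaluated on the unconstrained
scale (Jacobians included).  Inference therefore reduces to exploring the
low-dimensional theta posterior: a quasi-Newton search for the mode,
a finite-difference Hessian for Laplace scale, and (optionally) a small
grid or axis-point set of integration points whose normalized weights mix
the conditional latent posteriors.  This is the Gaussian-likelihood
specialization of the nested-Laplace scheme: the "inner" approximation is
exact, so all approximation error lives in the hyperparameter integration.

Strategies: ``"eb"`` plugs in the mode; ``"grid"`` uses a tensor grid of 3
points per dimension scaled by the Laplace standard deviations; ``"ccd"``
uses the mode plus two axis points per dimension.  The default picks
``grid`` for up to 4 hyperparameters and ``ccd`` above.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize

from .model import AssembledModel
from .spatial import chol_psd

__all__ = [
    "FitResult",
    "joint_precision",
    "latent_posterior",
    "log_marginal_post",
    "fit",
    "predict_lines",
]

_GRID_STEP = 1.0  # grid spacing in Laplace-sd units
_CCD_STEP = 1.2


# ---------------------------------------------------------------------------
# evaluator


class _Evaluator:
    """Caches data-dependent quantities for repeated theta evaluations."""

    def __init__(self, model: AssembledModel, y: np.ndarray):
        y = np.asarray(y, dtype=float)
        if len(y) != model.n_obs:
            raise ValueError("y length does not match the model")
        self.model = model
        self.y = y
        a = sp.hstack([b.design for b in model.blocks], format="csr")
        self.a = a
        self.ata = (a.T @ a).toarray()
        self.aty = np.asarray(a.T @ y).ravel()
        self.yty = float(y @ y)
        self.n = len(y)
        self.n_latent = model.n_latent
        self.slices = model.block_slices()
        self.jitter_count = 0

    def theta_natural(self, t: np.ndarray) -> dict[str, float]:
        return {h.name: h.to_natural(ti) for h, ti in zip(self.model.hypers, t)}

    def _prior_precision(self, theta: dict) -> tuple[np.ndarray, float]:
        q = np.zeros((self.n_latent, self.n_latent))
        logdet = 0.0
        for b in self.model.blocks:
            sl = self.slices[b.name]
            mat, ld = b.precision(theta)
            q[sl, sl] = mat.toarray() if sp.issparse(mat) else mat
            logdet += ld
        return q, logdet

    def _posterior_factor(self, theta: dict):
        sigma2_e = theta["var_e"]
        q, logdet_q = self._prior_precision(theta)
        q_post = q + self.ata / sigma2_e
        try:
            lower = chol_psd(q_post)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"posterior precision not positive definite at theta={theta}"
            ) from exc
        logdet_post = 2.0 * float(np.sum(np.log(np.diag(lower))))
        return sigma2_e, logdet_q, lower, logdet_post

    def log_post(self, t: np.ndarray) -> float:
        lprior = sum(h.logpdf(ti) for h, ti in zip(self.model.hypers, t))
        if not np.isfinite(lprior) or lprior < -1e8:
            raise FloatingPointError(f"prior density underflow at t={t}")
        theta = self.theta_natural(t)
        sigma2_e, logdet_q, lower, logdet_post = self._posterior_factor(theta)
        b = self.aty / sigma2_e
        mu = cho_solve((lower, True), b)
        llik = (
            -0.5 * self.n * np.log(2.0 * np.pi * sigma2_e)
            + 0.5 * logdet_q
            - 0.5 * logdet_post
            - 0.5 * (self.yty / sigma2_e - b @ mu)
        )
        val = llik + lprior
        if not np.isfinite(val):
            raise FloatingPointError(f"non-finite log posterior at theta={theta}")
        return float(val)

    def neg_log_post(self, t: np.ndarray) -> float:
        # large finite penalty lets the line search back away from regions
        # where the factorization overflows or the prior underflows
        try:
            return -self.log_post(t)
        except (np.linalg.LinAlgError, FloatingPointError):
            return 1e12 + float(np.sum(t**2))

    def latent(self, t: np.ndarray, want_cov: bool = False):
        theta = self.theta_natural(t)
        sigma2_e, _, lower, _ = self._posterior_factor(theta)
        mu = cho_solve((lower, True), self.aty / sigma2_e)
        inv_l = solve_triangular(lower, np.eye(self.n_latent), lower=True)
        cov = inv_l.T @ inv_l
        var = np.diag(cov).copy()
        return (mu, var, cov) if want_cov else (mu, var, None)


# ---------------------------------------------------------------------------
# public low-level API


def joint_precision(model: AssembledModel, theta: dict[str, float]):
    """Prior precision of the latent field (dense), its log-determinant and
    the observation matrix, at natural-scale hyperparameters ``theta``."""
    _check_theta(model, theta)
    ev = _Evaluator(model, model.y_default)
    q, logdet = ev._prior_precision(theta)
    return q, logdet, ev.a


def latent_posterior(model: AssembledModel, y: np.ndarray, theta: dict[str, float]):
    """Exact conditional posterior of the latent field at fixed theta:
    ``(mean, marginal sd)``."""
    _check_theta(model, theta)
    ev = _Evaluator(model, y)
    t = np.array([h.from_natural(theta[h.name]) for h in model.hypers])
    mu, var, _ = ev.latent(t)
    return mu, np.sqrt(var)


def log_marginal_post(model: AssembledModel, y: np.ndarray, theta: dict[str, float]) -> float:
    """Log posterior density of theta given y, up to an additive constant."""
    _check_theta(model, theta)
    ev = _Evaluator(model, y)
    t = np.array([h.from_natural(theta[h.name]) for h in model.hypers])
    return ev.log_post(t)


def _check_theta(model: AssembledModel, theta: dict) -> None:
    missing = [h.name for h in model.hypers if h.name not in theta]
    if missing:
        raise ValueError(f"theta missing hyperparameters {missing}")


# ---------------------------------------------------------------------------
# fitting


def _initial_point(model: AssembledModel, y: np.ndarray) -> np.ndarray:
    """Deterministic, scale-aware start: variances split the sample variance
    of y evenly; autocorrelations start at 0; the Matern range starts at a
    quarter of the field diameter with matching variance share."""
    var_y = float(np.var(y))
    if var_y <= 0:
        raise ValueError("response has zero variance")
    n_var = sum(1 for h in model.hypers if h.kind == "variance")
    n_var += sum(1 for h in model.hypers if h.kind == "log_tau")  # matern variance share
    v0 = var_y / max(n_var, 1)
    out = np.empty(len(model.hypers))
    kappa0 = {}
    for i, h in enumerate(model.hypers):
        if h.kind == "variance":
            out[i] = np.log(v0)
        elif h.kind == "rho":
            out[i] = 0.0
        elif h.kind == "log_kappa":
            from .spatial import kappa_from_range

            k0 = kappa_from_range(h.diameter / 4.0)
            kappa0[h.group] = k0
            out[i] = np.log(k0)
        elif h.kind == "log_tau":
            from .spatial import tau_from_sigma2

            out[i] = np.log(tau_from_sigma2(v0, kappa0[h.group]))
        else:  # pragma: no cover
            raise ValueError(f"unknown hyper kind {h.kind}")
    return out


def _hessian(f, x0: np.ndarray, step: float = 0.1) -> np.ndarray:
    """Central-difference Hessian of ``f`` at ``x0``."""
    d = len(x0)
    h = np.full(d, step)
    hess = np.empty((d, d))
    f0 = f(x0)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        fpp = f(x0 + ei)
        fmm = f(x0 - ei)
        hess[i, i] = (fpp - 2.0 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            fij = f(x0 + ei + ej) - f(x0 + ei - ej) - f(x0 - ei + ej) + f(x0 - ei - ej)
            hess[i, j] = hess[j, i] = fij / (4.0 * h[i] * h[j])
    return hess


def _make_pd(hess: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh(hess)
    vals = np.maximum(vals, floor * max(1.0, float(np.max(np.abs(vals)))))
    return (vecs * vals) @ vecs.T


def _integration_points(mode: np.ndarray, sd: np.ndarray, strategy: str) -> np.ndarray:
    d = len(mode)
    if strategy == "eb":
        return mode[None, :]
    if strategy == "grid":
        from itertools import product

        offsets = np.array(list(product((-1.0, 0.0, 1.0), repeat=d)))
        return mode[None, :] + _GRID_STEP * offsets * sd[None, :]
    if strategy == "ccd":
        pts = [mode]
        for i in range(d):
            for s in (-1.0, 1.0):
                p = mode.copy()
                p[i] += s * _CCD_STEP * sd[i]
                pts.append(p)
        return np.array(pts)
    raise ValueError("strategy must be 'eb', 'grid' or 'ccd'")


@dataclass
class FitResult:
    """Posterior summaries of a fitted Gaussian latent model."""

    model: AssembledModel
    strategy: str
    theta_mode_unc: np.ndarray
    theta_cov_unc: np.ndarray
    lp_mode: float
    n_iter: int
    n_eval: int
    weights: np.ndarray
    points: np.ndarray  # (n_points, dim) unconstrained
    point_means: np.ndarray  # (n_points, n_latent)
    point_vars: np.ndarray
    latent_mean: np.ndarray
    latent_sd: np.ndarray
    cov_mode: np.ndarray = field(repr=False)
    hyper_summary: pd.DataFrame = field(default=None, repr=False)

    # -- hyperparameters ---------------------------------------------------

    @property
    def theta_mode(self) -> dict[str, float]:
        return {
            h.name: h.to_natural(t)
            for h, t in zip(self.model.hypers, self.theta_mode_unc)
        }

    def hyper_interval(self, name: str, level: float = 0.95) -> tuple[float, float]:
        """Equal-tailed posterior interval on the natural scale (Laplace
        Gaussian on the unconstrained scale, transformed monotonely)."""
        from scipy.stats import norm

        idx = self.model.hyper_names.index(name)
        h = self.model.hypers[idx]
        sd = np.sqrt(self.theta_cov_unc[idx, idx])
        zq = norm.ppf(0.5 + level / 2.0)
        lo = h.to_natural(self.theta_mode_unc[idx] - zq * sd)
        hi = h.to_natural(self.theta_mode_unc[idx] + zq * sd)
        return (lo, hi)

    def matern_interval(self, which: str, group: str = "g0", level: float = 0.95):
        """Interval for a derived Matern quantity: ``which`` is ``"range"``
        or ``"sigma2_s"``; both are log-linear in (log kappa, log tau)."""
        from scipy.stats import norm

        names = self.model.hyper_names
        ik = names.index(f"log_kappa:{group}")
        it = names.index(f"log_tau:{group}")
        if which == "range":
            coef = {ik: -1.0}
            const = 0.5 * np.log(8.0)
        elif which == "sigma2_s":
            coef = {ik: -2.0, it: -2.0}
            const = -np.log(4.0 * np.pi)
        else:
            raise ValueError("which must be 'range' or 'sigma2_s'")
        mean = const + sum(c * self.theta_mode_unc[i] for i, c in coef.items())
        var = 0.0
        for i, ci in coef.items():
            for j, cj in coef.items():
                var += ci * cj * self.theta_cov_unc[i, j]
        sd = np.sqrt(var)
        zq = norm.ppf(0.5 + level / 2.0)
        return float(np.exp(mean)), (float(np.exp(mean - zq * sd)), float(np.exp(mean + zq * sd)))

    # -- latent field ------------------------------------------------------

    def block_mean(self, name: str) -> np.ndarray:
        return self.latent_mean[self.model.block_slices()[name]]

    def block_sd(self, name: str) -> np.ndarray:
        return self.latent_sd[self.model.block_slices()[name]]

    def latent_interval(self, name: str, index: int = 0, level: float = 0.95):
        from scipy.stats import norm

        sl = self.model.block_slices()[name]
        m = self.latent_mean[sl][index]
        s = self.latent_sd[sl][index]
        zq = norm.ppf(0.5 + level / 2.0)
        return (m - zq * s, m + zq * s)

    def linear_combination(self, name: str, coef: np.ndarray):
        """Posterior mean and sd of ``coef @ u_block`` for each row of
        ``coef``.  Means mix over the integration points; the covariance
        uses the modal conditional (documented approximation)."""
        sl = self.model.block_slices()[name]
        coef = np.atleast_2d(np.asarray(coef, dtype=float))
        if coef.shape[1] != sl.stop - sl.start:
            raise ValueError(
                f"coefficient width {coef.shape[1]} does not match block "
                f"{name!r} of size {sl.stop - sl.start}"
            )
        proj = self.point_means[:, sl] @ coef.T  # (points, rows)
        mean = self.weights @ proj
        var_mode = np.einsum("ij,jk,ik->i", coef, self.cov_mode[sl, sl], coef)
        second = self.weights @ (proj**2) + var_mode
        var = np.maximum(second - mean**2, 0.0)
        return mean, np.sqrt(var)

    def breeding_values(self, line_ids: np.ndarray):
        """Posterior mean and sd of the breeding value for the given lines:
        the marker component if present, else the GRM / iid line effect."""
        names = [b.name for b in self.model.blocks]
        if "markers" in names:
            z = self.model.genomics.rows_for(np.asarray(line_ids), "z_star")
            return self.linear_combination("markers", z)
        for name in ("genetic_add", "genetic_iid"):
            if name in names:
                block = self.model.block(name)
                lookup = {lid: i for i, lid in enumerate(block.labels)}
                idx = np.array([lookup[l] for l in line_ids])
                coef = np.zeros((len(idx), block.size))
                coef[np.arange(len(idx)), idx] = 1.0
                return self.linear_combination(name, coef)
        raise ValueError("model has no genetic effect")

    def fitted(self):
        """Predictive mean and sd of the linear predictor per observation."""
        a = sp.hstack([b.design for b in self.model.blocks], format="csr")
        proj = self.point_means @ a.T.toarray()
        mean = self.weights @ proj
        var_mode = np.asarray(((a @ self.cov_mode) * a.toarray()).sum(axis=1)).ravel()
        var = np.maximum(self.weights @ (proj**2) + var_mode - mean**2, 0.0)
        return mean, np.sqrt(var)


def fit(
    model: AssembledModel,
    y: np.ndarray | None = None,
    strategy: str | None = None,
    *,
    max_iter: int = 200,
    hess_step: float = 0.1,
) -> FitResult:
    """Fit the model: find the hyperparameter mode, Laplace scales, and mix
    the exact conditional latent posteriors over the integration points."""
    if y is None:
        y = model.y_default
    y = np.asarray(y, dtype=float)
    ev = _Evaluator(model, y)
    dim = len(model.hypers)
    if strategy is None:
        strategy = "grid" if dim <= 4 else "ccd"

    x0 = _initial_point(model, y)
    res = minimize(
        ev.neg_log_post,
        x0,
        method="L-BFGS-B",
        bounds=[(-25.0, 25.0)] * dim,
        options={"maxiter": max_iter, "gtol": 1e-6, "eps": 1e-5},
    )
    if res.status == 1:  # iteration limit
        raise RuntimeError(
            f"hyperparameter optimization did not converge in {max_iter} "
            f"iterations: {res.message}\nlast point: {ev.theta_natural(res.x)}"
        )
    mode = res.x
    hess = _make_pd(_hessian(ev.neg_log_post, mode, step=hess_step))
    theta_cov = np.linalg.inv(hess)
    sd = np.sqrt(np.diag(theta_cov))

    points = _integration_points(mode, sd, strategy)
    lps = np.array(
        [res.fun * -1.0 if np.allclose(p, mode) else ev.log_post(p) for p in points]
    )
    w = np.exp(lps - lps.max())
    w /= w.sum()

    means = np.empty((len(points), model.n_latent))
    variances = np.empty_like(means)
    cov_mode = None
    mode_idx = int(np.argmin(np.abs(points - mode).sum(axis=1)))
    for i, p in enumerate(points):
        want_cov = i == mode_idx
        mu, var, cov = ev.latent(p, want_cov=want_cov)
        means[i] = mu
        variances[i] = var
        if want_cov:
            cov_mode = cov
    latent_mean = w @ means
    latent_second = w @ (variances + means**2)
    latent_sd = np.sqrt(np.maximum(latent_second - latent_mean**2, 0.0))

    out = FitResult(
        model=model,
        strategy=strategy,
        theta_mode_unc=mode,
        theta_cov_unc=theta_cov,
        lp_mode=float(-res.fun),
        n_iter=int(res.nit),
        n_eval=int(res.nfev),
        weights=w,
        points=points,
        point_means=means,
        point_vars=variances,
        latent_mean=latent_mean,
        latent_sd=latent_sd,
        cov_mode=cov_mode,
    )
    out.hyper_summary = _hyper_summary(out)
    return out


def _hyper_summary(fitres: FitResult) -> pd.DataFrame:
    rows = []
    for i, h in enumerate(fitres.model.hypers):
        t = fitres.theta_mode_unc[i]
        s = float(np.sqrt(fitres.theta_cov_unc[i, i]))
        lo, hi = fitres.hyper_interval(h.name)
        nat = h.to_natural(t)
        if h.kind == "rho":
            deriv = (1.0 - nat**2) / 2.0
        else:
            deriv = nat
        rows.append(
            {
                "name": h.name,
                "kind": h.kind,
                "estimate": nat,
                "sd": abs(deriv) * s,
                "q025": lo,
                "q975": hi,
            }
        )
    groups = {h.group for h in fitres.model.hypers if h.kind == "log_kappa"}
    for g in sorted(x for x in groups if x is not None):
        for which in ("range", "sigma2_s"):
            est, (lo, hi) = fitres.matern_interval(which, group=g)
            rows.append(
                {
                    "name": f"{which}:{g}",
                    "kind": "derived",
                    "estimate": est,
                    "sd": np.nan,
                    "q025": lo,
                    "q975": hi,
                }
            )
    return pd.DataFrame(rows)


def predict_lines(fitres: FitResult, z_star_new: np.ndarray):
    """Predict breeding values for genotyped, unphenotyped lines from the
    fitted marker effects: mean ``Z*_new u*`` with matching posterior sd."""
    if "markers" not in [b.name for b in fitres.model.blocks]:
        raise ValueError("predict_lines requires a fitted marker model")
    z_star_new = np.atleast_2d(np.asarray(z_star_new, dtype=float))
    return fitres.linear_combination("markers", z_star_new)
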