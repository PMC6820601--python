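"""Spatial covariance structures for field trials.

Three spatial models are supported for the plot effect of a trial:

* independent row and column effects,
* the separable first-order autoregressive model (AR1 x AR1), whose
  covariance is the Kronecker product of two AR1 correlation matrices, and
* a stationary Gaussian random field with Matern covariance, either as an
  exact dense covariance (the default at desk scale) or through the SPDE
  finite-element approximation (:mod:`fieldspatial.spde`).

The module also builds the Nelder wheel spacing-trial geometry used in
tree breeding, where trees sit at ring/spoke intersections and each ring
corresponds to one planting density.

Conventions
-----------
The Matern range parameter ``rho`` is the distance at which the correlation
has decayed to roughly 0.1, with scale parameter ``kappa = sqrt(8 nu)/rho``.
For the AR1 model the analogous range is ``log(0.1)/log(rho)`` lag units.
Row/column models operate on integer lattice lags; the Matern model uses
physical coordinates (for the simulated wheat fields the column spacing is
twice the row spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cholesky as _dense_chol
from scipy.special import gamma as _gamma, kv as _kv

__all__ = [
    "FieldLayout",
    "MaternParams",
    "AR1Params",
    "NelderDesign",
    "kappa_from_range",
    "range_from_kappa",
    "sigma2_from_spde",
    "tau_from_sigma2",
    "matern_correlation",
    "matern_cov",
    "ar1_precision",
    "ar1_corr_precision",
    "ar1_cov",
    "ar1xar1_cov",
    "ar1xar1_precision",
    "ar1_range",
    "chol_psd",
    "sample_field",
    "nelder_layout",
]

#: diagonal jitter added when a Cholesky factorization of a nominally PSD
#: matrix fails for numerical reasons
CHOL_JITTER = 1e-10


# ---------------------------------------------------------------------------
# layouts


@dataclass(frozen=True)
class FieldLayout:
    """Plot positions of a single trial.

    ``row``/``col`` are 1-based lattice indices (row-major plot order);
    ``coords`` are physical coordinates in field units.  For non-lattice
    designs (Nelder wheel) ``row``/``col`` degenerate to a plot counter.
    """

    trial_id: str
    row: np.ndarray
    col: np.ndarray
    coords: np.ndarray  # (n, 2)
    extra: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite plot coordinates")
        n = len(coords)
        if len(self.row) != n or len(self.col) != n:
            raise ValueError("row/col/coords length mismatch")
        seen = {tuple(c) for c in coords.round(12).tolist()}
        if len(seen) != n:
            raise ValueError(f"duplicate plot coordinates in trial {self.trial_id!r}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "row", np.asarray(self.row, dtype=int))
        object.__setattr__(self, "col", np.asarray(self.col, dtype=int))

    @property
    def n_plots(self) -> int:
        return len(self.coords)

    @property
    def n_rows(self) -> int:
        return int(self.row.max())

    @property
    def n_cols(self) -> int:
        return int(self.col.max())

    @classmethod
    def lattice(
        cls,
        n_rows: int,
        n_cols: int,
        *,
        trial_id: str = "trial",
        row_spacing: float = 1.0,
        col_spacing: float = 2.0,
    ) -> "FieldLayout":
        """Regular ``n_rows x n_cols`` lattice, row-major plot order.

        The default spacing follows the simulated wheat fields: the distance
        between columns is twice the distance between rows.
        """
        if n_rows < 1 or n_cols < 1:
            raise ValueError("grid size must be at least 1 x 1")
        rows, cols = np.meshgrid(
            np.arange(1, n_rows + 1), np.arange(1, n_cols + 1), indexing="ij"
        )
        rows = rows.ravel()
        cols = cols.ravel()
        coords = np.column_stack(
            [(rows - 1) * row_spacing, (cols - 1) * col_spacing]
        ).astype(float)
        return cls(trial_id=trial_id, row=rows, col=cols, coords=coords)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "row": self.row,
                "col": self.col,
                "x_coord": self.coords[:, 0],
                "y_coord": self.coords[:, 1],
            }
        )
        if self.extra is not None:
            out = pd.concat([out, self.extra.reset_index(drop=True)], axis=1)
        return out


# ---------------------------------------------------------------------------
# Matern


def kappa_from_range(range_: float, nu: float = 1.0) -> float:
    """Scale parameter ``kappa = sqrt(8 nu)/rho`` of the Matern covariance."""
    if range_ <= 0 or nu <= 0:
        raise ValueError("range and nu must be positive")
    return float(np.sqrt(8.0 * nu) / range_)


def range_from_kappa(kappa: float, nu: float = 1.0) -> float:
    """Inverse of :func:`kappa_from_range`."""
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    return float(np.sqrt(8.0 * nu) / kappa)


def sigma2_from_spde(kappa: float, tau: float, nu: float = 1.0, d: int = 2) -> float:
    """Marginal variance implied by the SPDE parameters (kappa, tau).

    ``sigma_s^2 = Gamma(nu) / (Gamma(alpha) (4 pi)^{d/2} kappa^{2 nu} tau^2)``
    with ``alpha = nu + d/2``.
    """
    if kappa <= 0 or tau <= 0 or nu <= 0:
        raise ValueError("kappa, tau and nu must be positive")
    alpha = nu + d / 2.0
    return float(
        _gamma(nu) / (_gamma(alpha) * (4.0 * np.pi) ** (d / 2.0) * kappa ** (2.0 * nu) * tau**2)
    )


def tau_from_sigma2(sigma2: float, kappa: float, nu: float = 1.0, d: int = 2) -> float:
    """Value of ``tau`` giving marginal variance ``sigma2`` at scale ``kappa``."""
    if sigma2 <= 0 or kappa <= 0 or nu <= 0:
        raise ValueError("sigma2, kappa and nu must be positive")
    alpha = nu + d / 2.0
    return float(
        np.sqrt(
            _gamma(nu) / (_gamma(alpha) * (4.0 * np.pi) ** (d / 2.0) * kappa ** (2.0 * nu) * sigma2)
        )
    )


@dataclass(frozen=True)
class MaternParams:
    """Matern field hyperparameters.

    ``range_`` is the ~0.1-correlation distance; ``kappa`` and ``tau`` are
    the equivalent SPDE parameters.
    """

    sigma2: float = 1.0
    range_: float = 10.0
    nu: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma2 <= 0 or self.range_ <= 0 or self.nu <= 0:
            raise ValueError("MaternParams fields must be positive")

    @property
    def kappa(self) -> float:
        return kappa_from_range(self.range_, self.nu)

    @property
    def tau(self) -> float:
        return tau_from_sigma2(self.sigma2, self.kappa, self.nu)

    @classmethod
    def from_spde(cls, kappa: float, tau: float, nu: float = 1.0) -> "MaternParams":
        return cls(
            sigma2=sigma2_from_spde(kappa, tau, nu),
            range_=range_from_kappa(kappa, nu),
            nu=nu,
        )


def matern_correlation(dist: np.ndarray, kappa: float, nu: float = 1.0) -> np.ndarray:
    """Matern correlation ``2^{1-nu}/Gamma(nu) (kappa d)^nu K_nu(kappa d)``.

    Defined by continuity as 1 at distance zero.
    """
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    d = np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite distances")
    x = kappa * d
    out = np.ones_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = (2.0 ** (1.0 - nu) / _gamma(nu)) * xp**nu * _kv(nu, xp)
    return out


def matern_cov(coords: np.ndarray, params: MaternParams) -> np.ndarray:
    """Dense Matern covariance matrix over the given coordinates."""
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    c = params.sigma2 * matern_correlation(dist, params.kappa, params.nu)
    return 0.5 * (c + c.T)


# ---------------------------------------------------------------------------
# AR1 and AR1 x AR1


@dataclass(frozen=True)
class AR1Params:
    """Separable AR1 x AR1 hyperparameters.

    ``variance`` is the marginal plot variance (the quantity carrying the
    inverse-gamma prior); the implied innovation variance in, say, the row
    direction is ``variance * (1 - rho_r**2)`` per conditional step.
    """

    rho_r: float = 0.8
    rho_c: float = 0.8
    variance: float = 1.0

    def __post_init__(self) -> None:
        if not (abs(self.rho_r) < 1 and abs(self.rho_c) < 1):
            raise ValueError("|rho| must be < 1")
        if self.variance <= 0:
            raise ValueError("variance must be positive")


def _check_rho(rho: float) -> None:
    if not abs(rho) < 1:
        raise ValueError(f"|rho| must be < 1, got {rho}")


def ar1_precision(n: int, rho: float, sigma2_innov: float = 1.0) -> sp.csc_matrix:
    """Tridiagonal precision of a stationary AR1 with innovation variance
    ``sigma2_innov`` (marginal variance ``sigma2_innov / (1 - rho^2)``)."""
    _check_rho(rho)
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma2_innov <= 0:
        raise ValueError("sigma2_innov must be positive")
    main = np.full(n, 1.0 + rho**2)
    main[0] = main[-1] = 1.0
    off = np.full(n - 1, -rho)
    q = sp.diags([off, main, off], offsets=[-1, 0, 1], format="csc")
    return (q / sigma2_innov).tocsc()


def ar1_corr_precision(n: int, rho: float) -> sp.csc_matrix:
    """Precision of the unit-marginal-variance AR1 (correlation matrix
    ``rho^{|i-j|}``)."""
    return ar1_precision(n, rho, sigma2_innov=1.0 - rho**2)


def ar1_cov(n: int, rho: float, sigma2_innov: float = 1.0) -> np.ndarray:
    """Dense AR1 covariance ``sigma2_innov/(1-rho^2) * rho^{|i-j|}``."""
    _check_rho(rho)
    lags = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return sigma2_innov / (1.0 - rho**2) * rho**lags


def ar1xar1_cov(n_rows: int, n_cols: int, params: AR1Params) -> np.ndarray:
    """Dense separable covariance ``variance * R_r (x) R_c`` with unit-marginal
    AR1 correlation factors; plots ordered row-major."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid size must be at least 1 x 1")
    rr = ar1_cov(n_rows, params.rho_r, 1.0 - params.rho_r**2)
    rc = ar1_cov(n_cols, params.rho_c, 1.0 - params.rho_c**2)
    return params.variance * np.kron(rr, rc)


def ar1xar1_precision(
    n_rows: int, n_cols: int, params: AR1Params
) -> tuple[sp.csc_matrix, float]:
    """Sparse Kronecker precision of the AR1 x AR1 model and its log-determinant.

    The precision is ``kron(Q_r, Q_c) / variance`` with ``Q`` the
    unit-marginal AR1 precisions; ``logdet`` is analytic from
    ``det(R) = (1 - rho^2)^{n-1}`` for a unit-marginal AR1 correlation.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid size must be at least 1 x 1")
    qr = ar1_corr_precision(n_rows, params.rho_r)
    qc = ar1_corr_precision(n_cols, params.rho_c)
    q = sp.kron(qr, qc, format="csc") / params.variance
    n = n_rows * n_cols
    logdet = (
        -n_cols * (n_rows - 1) * np.log(1.0 - params.rho_r**2)
        - n_rows * (n_cols - 1) * np.log(1.0 - params.rho_c**2)
        - n * np.log(params.variance)
    )
    return q.tocsc(), float(logdet)


def ar1_range(rho: float) -> float:
    """Lag distance at which the AR1 correlation drops to 0.1.

    ``rho = 0.8`` gives about 10.3 units, the value quoted as "a range of 10"
    for the simulated wheat fields.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    return float(np.log(0.1) / np.log(rho))


# ---------------------------------------------------------------------------
# sampling


def chol_psd(mat: np.ndarray, jitter: float = CHOL_JITTER) -> np.ndarray:
    """Lower Cholesky factor with a single retry after adding ``jitter`` to
    the diagonal; raises with the smallest eigenvalue on failure."""
    mat = np.asarray(mat, dtype=float)
    try:
        return _dense_chol(mat, lower=True)
    except np.linalg.LinAlgError:
        pass
    try:
        return _dense_chol(mat + jitter * np.eye(len(mat)), lower=True)
    except np.linalg.LinAlgError as exc:
        lam = float(np.linalg.eigvalsh(mat)[0])
        raise np.linalg.LinAlgError(
            f"matrix not positive definite (smallest eigenvalue {lam:.3e})"
        ) from exc


def sample_field(
    *,
    cov: np.ndarray | None = None,
    precision: np.ndarray | sp.spmatrix | None = None,
    n_samples: int = 1,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw zero-mean Gaussian fields from a covariance or a precision matrix.

    Returns an ``(n_samples, n)`` array.  Exactly one of ``cov``/``precision``
    must be given.  Draws are reproducible given an integer seed or Generator.
    """
    if (cov is None) == (precision is None):
        raise ValueError("give exactly one of cov or precision")
    rng = np.random.default_rng(rng)
    if cov is not None:
        n = len(cov)
        lower = chol_psd(cov)
        z = rng.standard_normal((n, n_samples))
        draws = (lower @ z).T
    else:
        q = precision.toarray() if sp.issparse(precision) else np.asarray(precision)
        n = len(q)
        lower = chol_psd(q)
        z = rng.standard_normal((n, n_samples))
        # x = L^{-T} z has covariance Q^{-1}
        from scipy.linalg import solve_triangular

        draws = solve_triangular(lower, z, lower=True, trans="T").T
    return draws


# ---------------------------------------------------------------------------
# Nelder wheel


@dataclass(frozen=True)
class NelderDesign:
    """Nelder wheel spacing-trial design.

    Trees are planted at the intersections of ``n_spokes`` rays and
    ``n_rings`` concentric rings; ring radii grow geometrically by the factor
    ``k``, so each ring realizes one planting density.  The growing area of a
    tree in ring ``i`` is ``theta * r_i^2 * (k - 1/k) / 2`` with
    ``theta = 2 pi / n_spokes``; planting density is its inverse.
    """

    n_rings: int = 10
    n_spokes: int = 30
    r1: float = 10.0
    k: float = 1.15

    def __post_init__(self) -> None:
        if self.k <= 1:
            raise ValueError("ring factor k must exceed 1 (rings must expand)")
        if self.n_rings < 1 or self.n_spokes < 3 or self.r1 <= 0:
            raise ValueError("invalid Nelder design parameters")

    @property
    def theta(self) -> float:
        return 2.0 * np.pi / self.n_spokes

    @property
    def radii(self) -> np.ndarray:
        return self.r1 * self.k ** np.arange(self.n_rings)

    @property
    def growing_areas(self) -> np.ndarray:
        return self.theta * self.radii**2 * (self.k - 1.0 / self.k) / 2.0

    @property
    def densities(self) -> np.ndarray:
        return 1.0 / self.growing_areas


def nelder_layout(design: NelderDesign = NelderDesign(), *, trial_id: str = "nelder") -> FieldLayout:
    """Tree positions, growing areas and densities of a Nelder wheel.

    The returned layout carries ``ring``, ``spoke``, ``growing_area`` and
    ``density`` columns in ``extra``; ``row``/``col`` are set to ring/spoke.
    """
    radii = design.radii
    angles = design.theta * np.arange(design.n_spokes)
    ring, spoke = np.meshgrid(
        np.arange(1, design.n_rings + 1), np.arange(1, design.n_spokes + 1), indexing="ij"
    )
    ring = ring.ravel()
    spoke = spoke.ravel()
    r = radii[ring - 1]
    a = angles[spoke - 1]
    coords = np.column_stack([r * np.cos(a), r * np.sin(a)])
    extra = pd.DataFrame(
        {
            "ring": ring,
            "spoke": spoke,
            "growing_area": design.growing_areas[ring - 1],
            "density": design.densities[ring - 1],
        }
    )
    return FieldLayout(trial_id=trial_id, row=ring, col=spoke, coords=coords, extra=extra)
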