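"""Assembly of the latent Gaussian model from data and a model choice.

The observation model is ``y(s_i) | eta(s_i), sigma2_e ~ N(eta(s_i),
sigma2_e)`` with linear predictor

    eta(s_i) = beta_0 + w_i beta + g_j + x(s_i),

where ``g_j`` is the genetic effect of the line in plot ``i`` (iid line
effects, a GRM effect, marker-component effects, or markers plus an iid
residual genetic effect) and ``x`` the spatial effect (none, independent
row+column effects, separable AR1 x AR1, or a Matern field).  Multi-trial
data get one spatial field per trial, independent across trials, with
hyperparameters shared within user-defined trial groups; fixed effects can
be a common intercept plus covariates or trial-specific intercepts.

:func:`assemble` is pure: the same inputs yield the same structure, and
``AssembledModel.describe()`` gives a hashable summary of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genomics import GenomicData
from .priors import (
    FisherZGaussianPrior,
    GaussianPrior,
    Hyper,
    InverseGammaVariancePrior,
    matern_prior_means,
)
from .spatial import (
    AR1Params,
    FieldLayout,
    MaternParams,
    ar1xar1_precision,
    chol_psd,
    matern_cov,
    sigma2_from_spde,
)

__all__ = ["ModelSpec", "LatentBlock", "AssembledModel", "assemble"]

SPATIAL_MODELS = ("none", "rowcol", "ar1xar1", "matern")
GENETIC_MODELS = ("none", "iid", "grm", "markers", "markers_iid")

MAX_HYPERS = 20
WARN_HYPERS = 10


@dataclass(frozen=True)
class ModelSpec:
    """Choice of spatial model, genetic model, fixed effects and grouping."""

    spatial: str = "matern"
    genetic: str = "iid"
    intercept_per_trial: bool = False
    covariates: tuple[str, ...] = ()
    spatial_groups: tuple[tuple[str, ...], ...] | None = None
    fixed_prior_var: float = 1000.0

    def __post_init__(self) -> None:
        if self.spatial not in SPATIAL_MODELS:
            raise ValueError(f"spatial must be one of {SPATIAL_MODELS}")
        if self.genetic not in GENETIC_MODELS:
            raise ValueError(f"genetic must be one of {GENETIC_MODELS}")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        if self.spatial_groups is not None:
            object.__setattr__(
                self,
                "spatial_groups",
                tuple(tuple(g) for g in self.spatial_groups),
            )


@dataclass
class LatentBlock:
    """One block of the latent field: labels, observation design, and a
    precision builder ``precision(theta) -> (matrix, logdet)``."""

    name: str
    labels: list
    design: sp.csr_matrix
    hypers: tuple[str, ...]
    precision: object  # callable

    @property
    def size(self) -> int:
        return len(self.labels)


@dataclass
class AssembledModel:
    spec: ModelSpec
    blocks: list[LatentBlock]
    hypers: list[Hyper]
    n_obs: int
    y_default: np.ndarray
    obs_info: pd.DataFrame = field(repr=False)
    genomics: GenomicData | None = field(default=None, repr=False)

    @property
    def n_latent(self) -> int:
        return sum(b.size for b in self.blocks)

    @property
    def hyper_names(self) -> list[str]:
        return [h.name for h in self.hypers]

    def block(self, name: str) -> LatentBlock:
        for b in self.blocks:
            if b.name == name:
                return b
        raise KeyError(name)

    def block_slices(self) -> dict[str, slice]:
        out = {}
        start = 0
        for b in self.blocks:
            out[b.name] = slice(start, start + b.size)
            start += b.size
        return out

    def describe(self) -> str:
        parts = [
            f"spatial={self.spec.spatial}",
            f"genetic={self.spec.genetic}",
            f"n_obs={self.n_obs}",
        ]
        parts += [f"block:{b.name}:{b.size}:{','.join(map(str, b.hypers))}" for b in self.blocks]
        parts += [f"hyper:{h.name}:{h.kind}:{h.group}" for h in self.hypers]
        return "|".join(parts)


# ---------------------------------------------------------------------------
# helpers


def _incidence(indices: np.ndarray, size: int) -> sp.csr_matrix:
    n = len(indices)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), indices)), shape=(n, size)
    )


class _IidPrecision:
    def __init__(self, size: int, var_name: str):
        self.size = size
        self.var_name = var_name

    def __call__(self, theta: dict) -> tuple[sp.spmatrix, float]:
        v = theta[self.var_name]
        return sp.eye(self.size, format="csc") / v, -self.size * float(np.log(v))


class _GrmPrecision:
    """Precision sigma2_a^{-1} A^{-1}, with A factorized once."""

    def __init__(self, a: np.ndarray, var_name: str):
        lower = chol_psd(a)
        self.logdet_a = 2.0 * float(np.sum(np.log(np.diag(lower))))
        inv_l = np.linalg.inv(lower)
        self.a_inv = inv_l.T @ inv_l
        self.size = len(a)
        self.var_name = var_name

    def __call__(self, theta: dict) -> tuple[np.ndarray, float]:
        v = theta[self.var_name]
        return self.a_inv / v, -self.logdet_a - self.size * float(np.log(v))


class _Ar1xAr1Precision:
    def __init__(self, n_rows: int, n_cols: int, group: str):
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.names = (f"var_s:{group}", f"rho_r:{group}", f"rho_c:{group}")

    def __call__(self, theta: dict) -> tuple[sp.spmatrix, float]:
        v, rr, rc = (theta[n] for n in self.names)
        return ar1xar1_precision(self.n_rows, self.n_cols, AR1Params(rr, rc, v))


class _MaternPrecision:
    """Inverse of the dense Matern covariance; one factorization per distinct
    (layout, kappa, tau) shared across trials of a group."""

    _cache: dict = {}

    def __init__(self, coords: np.ndarray, group: str, nu: float = 1.0):
        self.coords = coords
        self.key = (group, coords.tobytes())
        self.names = (f"log_kappa:{group}", f"log_tau:{group}")
        self.nu = nu

    def __call__(self, theta: dict) -> tuple[np.ndarray, float]:
        kappa, tau = (theta[n] for n in self.names)
        cache_key = (self.key, float(kappa), float(tau))
        hit = _MaternPrecision._cache.get(cache_key)
        if hit is not None:
            return hit
        sigma2 = sigma2_from_spde(kappa, tau, self.nu)
        params = MaternParams(
            sigma2=sigma2, range_=np.sqrt(8.0 * self.nu) / kappa, nu=self.nu
        )
        cov = matern_cov(self.coords, params)
        lower = chol_psd(cov)
        logdet_cov = 2.0 * float(np.sum(np.log(np.diag(lower))))
        inv_l = np.linalg.inv(lower)
        q = inv_l.T @ inv_l
        result = (q, -logdet_cov)
        # keep only the most recent evaluation per layout/group
        stale = [k for k in _MaternPrecision._cache if k[0] == self.key]
        for k in stale:
            del _MaternPrecision._cache[k]
        _MaternPrecision._cache[cache_key] = result
        return result


# ---------------------------------------------------------------------------
# assembly


def _fixed_block(spec: ModelSpec, phen: pd.DataFrame, trial_ids: list) -> LatentBlock:
    cols = []
    labels = []
    if spec.intercept_per_trial:
        for t in trial_ids:
            cols.append((phen["trial_id"] == t).to_numpy(dtype=float))
            labels.append(f"intercept[{t}]")
    else:
        cols.append(np.ones(len(phen)))
        labels.append("intercept")
        if len(trial_ids) > 1:
            # fixed contrasts for the 2nd..kth trial (e.g. a location effect)
            for t in trial_ids[1:]:
                cols.append((phen["trial_id"] == t).to_numpy(dtype=float))
                labels.append(f"trial[{t}]")
    for c in spec.covariates:
        if c not in phen.columns:
            raise ValueError(f"covariate column {c!r} missing from phenotypes")
        cols.append(phen[c].to_numpy(dtype=float))
        labels.append(c)
    design = sp.csr_matrix(np.column_stack(cols))
    size = len(labels)
    var = spec.fixed_prior_var

    def precision(theta, _size=size, _var=var):
        return sp.eye(_size, format="csc") / _var, -_size * float(np.log(_var))

    return LatentBlock("fixed", labels, design, (), precision)


def _genetic_blocks(
    spec: ModelSpec, phen: pd.DataFrame, genomics: GenomicData | None
) -> tuple[list[LatentBlock], list[Hyper]]:
    blocks: list[LatentBlock] = []
    hypers: list[Hyper] = []
    if spec.genetic == "none":
        return blocks, hypers
    line_ids = phen["line_id"].to_numpy()
    uniq = pd.unique(line_ids)
    index = pd.Series(np.arange(len(uniq)), index=uniq)
    obs_line = index[line_ids].to_numpy()
    ig = InverseGammaVariancePrior()
    if spec.genetic in ("iid", "markers_iid"):
        blocks.append(
            LatentBlock(
                "genetic_iid",
                list(uniq),
                _incidence(obs_line, len(uniq)),
                ("var_n",),
                _IidPrecision(len(uniq), "var_n"),
            )
        )
        hypers.append(Hyper("var_n", "variance", ig))
    if spec.genetic == "grm":
        if genomics is None:
            raise ValueError("genetic='grm' requires genomic data")
        order = genomics.line_ids
        lookup = {lid: i for i, lid in enumerate(order)}
        missing = [l for l in uniq if l not in lookup]
        if missing:
            raise ValueError(f"lines without genotypes: {missing[:5]}")
        obs_idx = np.array([lookup[l] for l in line_ids])
        blocks.append(
            LatentBlock(
                "genetic_add",
                list(order),
                _incidence(obs_idx, len(order)),
                ("var_a",),
                _GrmPrecision(genomics.a, "var_a"),
            )
        )
        hypers.append(Hyper("var_a", "variance", ig))
    if spec.genetic in ("markers", "markers_iid"):
        if genomics is None or genomics.z_star is None:
            raise ValueError("marker models require compressed genomic data (z_star)")
        z_obs = genomics.rows_for(line_ids, "z_star")
        p_star = z_obs.shape[1]
        blocks.append(
            LatentBlock(
                "markers",
                [f"pc{i + 1}" for i in range(p_star)],
                sp.csr_matrix(z_obs),
                ("var_u",),
                _IidPrecision(p_star, "var_u"),
            )
        )
        hypers.append(Hyper("var_u", "variance", ig))
    return blocks, hypers


def _spatial_blocks(
    spec: ModelSpec, phen: pd.DataFrame, layouts: dict[str, FieldLayout], trial_ids: list
) -> tuple[list[LatentBlock], list[Hyper]]:
    blocks: list[LatentBlock] = []
    hypers: list[Hyper] = []
    if spec.spatial == "none":
        return blocks, hypers
    groups = spec.spatial_groups or (tuple(trial_ids),)
    grouped = [t for g in groups for t in g]
    if sorted(grouped) != sorted(trial_ids) or len(grouped) != len(trial_ids):
        raise ValueError(
            f"spatial_groups must partition the trial set {trial_ids}, got {groups}"
        )
    ig = InverseGammaVariancePrior()
    for gi, group in enumerate(groups):
        gname = f"g{gi}"
        coords_all = np.vstack([layouts[t].coords for t in group])
        lo = coords_all.min(axis=0)
        hi = coords_all.max(axis=0)
        diameter = float(np.sqrt(((hi - lo) ** 2).sum()))
        if spec.spatial == "rowcol":
            hypers.append(Hyper(f"var_row:{gname}", "variance", ig, group=gname))
            hypers.append(Hyper(f"var_col:{gname}", "variance", ig, group=gname))
        elif spec.spatial == "ar1xar1":
            hypers.append(Hyper(f"var_s:{gname}", "variance", ig, group=gname))
            rho_prior = FisherZGaussianPrior()
            hypers.append(Hyper(f"rho_r:{gname}", "rho", rho_prior, group=gname))
            hypers.append(Hyper(f"rho_c:{gname}", "rho", rho_prior, group=gname))
        else:  # matern
            mk, mt = matern_prior_means(diameter)
            hypers.append(
                Hyper(
                    f"log_kappa:{gname}",
                    "log_kappa",
                    GaussianPrior(mean=mk, sd=1.0),
                    group=gname,
                    diameter=diameter,
                )
            )
            hypers.append(
                Hyper(
                    f"log_tau:{gname}",
                    "log_tau",
                    GaussianPrior(mean=mt, sd=1.0),
                    group=gname,
                    diameter=diameter,
                )
            )
        for t in group:
            lay = layouts[t]
            mask = (phen["trial_id"] == t).to_numpy()
            sub = phen.loc[mask]
            if spec.spatial == "rowcol":
                for which in ("row", "col"):
                    size = lay.n_rows if which == "row" else lay.n_cols
                    idx = sub[which].to_numpy(dtype=int) - 1
                    design = sp.csr_matrix(
                        (np.ones(mask.sum()), (np.flatnonzero(mask), idx)),
                        shape=(len(phen), size),
                    )
                    blocks.append(
                        LatentBlock(
                            f"{which}[{t}]",
                            [f"{which}{i + 1}" for i in range(size)],
                            design,
                            (f"var_{which}:{gname}",),
                            _IidPrecision(size, f"var_{which}:{gname}"),
                        )
                    )
                continue
            if spec.spatial == "ar1xar1":
                plot_idx = (sub["row"].to_numpy(dtype=int) - 1) * lay.n_cols + (
                    sub["col"].to_numpy(dtype=int) - 1
                )
                if lay.n_plots != lay.n_rows * lay.n_cols:
                    raise ValueError(
                        f"AR1xAR1 requires a full lattice; trial {t!r} is not"
                    )
                prec = _Ar1xAr1Precision(lay.n_rows, lay.n_cols, gname)
                labels = [f"plot_r{r}_c{c}" for r in range(1, lay.n_rows + 1) for c in range(1, lay.n_cols + 1)]
            else:  # matern: plot order = layout order, match obs by (row, col)
                key = {(r, c): i for i, (r, c) in enumerate(zip(lay.row, lay.col))}
                plot_idx = np.array(
                    [key[(r, c)] for r, c in zip(sub["row"], sub["col"])]
                )
                prec = _MaternPrecision(lay.coords, gname)
                labels = [f"plot{i}" for i in range(lay.n_plots)]
            design = sp.csr_matrix(
                (np.ones(mask.sum()), (np.flatnonzero(mask), plot_idx)),
                shape=(len(phen), len(labels)),
            )
            blocks.append(
                LatentBlock(f"spatial[{t}]", labels, design, tuple(prec.names), prec)
            )
    return blocks, hypers


def assemble(
    spec: ModelSpec,
    phenotypes: pd.DataFrame,
    layouts: dict[str, FieldLayout],
    genomics: GenomicData | None = None,
) -> AssembledModel:
    """Build the latent Gaussian model for the given data.

    ``phenotypes`` needs columns ``trial_id, line_id, row, col, phenotype``
    (plus any covariates named in the spec); every trial appearing in the
    table must have a layout.  Marker models additionally need ``genomics``
    with a compressed ``z_star``.
    """
    required = {"trial_id", "line_id", "row", "col", "phenotype"}
    if spec.genetic == "none":
        required.discard("line_id")
    missing = required - set(phenotypes.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns {sorted(missing)}")
    phen = phenotypes.reset_index(drop=True)
    if spec.genetic == "none" and "line_id" not in phen.columns:
        phen = phen.assign(line_id="na")
    trial_ids = list(pd.unique(phen["trial_id"]))
    for t in trial_ids:
        if t not in layouts:
            raise ValueError(f"no layout for trial {t!r}")

    blocks = [_fixed_block(spec, phen, trial_ids)]
    gb, gh = _genetic_blocks(spec, phen, genomics)
    sb, sh = _spatial_blocks(spec, phen, layouts, trial_ids)
    blocks += gb + sb
    hypers = [Hyper("var_e", "variance", InverseGammaVariancePrior())] + gh + sh
    if len(hypers) > MAX_HYPERS:
        raise ValueError(
            f"{len(hypers)} hyperparameters exceeds the supported maximum of {MAX_HYPERS}; "
            "group trials to share spatial hyperparameters"
        )
    if len(hypers) > WARN_HYPERS:
        warnings.warn(
            f"{len(hypers)} hyperparameters; integration over the hyperparameter "
            "space degrades beyond about 10",
            stacklevel=2,
        )
    return AssembledModel(
        spec=spec,
        blocks=blocks,
        hypers=hypers,
        n_obs=len(phen),
        y_default=phen["phenotype"].to_numpy(dtype=float),
        obs_info=phen[[c for c in ("trial_id", "line_id", "row", "col") if c in phen.columns]],
        genomics=genomics,
    )
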