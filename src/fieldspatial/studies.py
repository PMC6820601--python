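"""End-to-end case studies.

Three orchestrated experiments mirror the study design:

* :func:`run_simulation_study` -- the breeding-programme simulation grid:
  spatial proportion x generator x spatial model x marker usage, scored by
  correlation, CRPS and top-ranking capture for the phenotyped PYT lines
  and for a genotyped-but-unphenotyped DH cohort.
* :func:`run_multitrial` -- four synthetic trials analysed singly and
  jointly with trial-specific intercepts and two grouped sets of spatial
  hyperparameters (the multi-trial wheat structure W1/W2/W1M/W2M).
* :func:`run_nelder` -- the Nelder wheel spacing trial: Matern and
  no-spatial fits, recovery of the five generating parameters, and
  reconstruction of the spatial field on a prediction grid.

Scoring scale: phenotypes are standardized before analysis, so true
breeding values are centred at the phenotyped cohort's mean and divided by
the standardization sd before comparison with the (deviation-scale)
estimated effects.  The top-capture rank window defaults to one tenth of
the cohort, preserving the full-scale study's null expectation of one
captured individual (10 x 100 / 1000).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .breeding import (
    ProgrammeConfig,
    ProgrammeState,
    VarianceConfig,
    run_programme,
    simulate_trial_phenotypes,
    standardize,
)
from .genomics import GenomicData, polymorphic_mask, vanraden_grm
from .inference import FitResult, fit, predict_lines
from .model import ModelSpec, assemble
from .scoring import correlation, crps_gaussian, summarize_study, top_capture
from .spatial import (
    FieldLayout,
    MaternParams,
    NelderDesign,
    matern_cov,
    nelder_layout,
    sample_field,
)

__all__ = [
    "SimulationStudyConfig",
    "StudyResult",
    "run_simulation_study",
    "MultiTrialConfig",
    "MultiTrialResult",
    "run_multitrial",
    "NelderConfig",
    "NelderResult",
    "run_nelder",
]


def _child_rngs(seed, n: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# simulation study


@dataclass(frozen=True)
class SimulationStudyConfig:
    """Grid of the simulation study.  Defaults are desk scale; the
    full-scale study uses the full-size :class:`ProgrammeConfig`, 100
    replicates and an explicit 500-component marker rule."""

    programme: ProgrammeConfig = field(default_factory=ProgrammeConfig)
    n_replicates: int = 10
    props: tuple[float, ...] = (0.0, 0.5, 0.75)
    generators: tuple[str, ...] = ("matern",)
    models: tuple[str, ...] = ("none", "rowcol", "ar1xar1", "matern")
    marker_settings: tuple[bool, ...] = (False, True)
    pc_rule: float | int = 0.95
    strategy: str = "eb"
    n_top: int = 10
    top_rank_fraction: float = 0.1


@dataclass
class StudyResult:
    results: pd.DataFrame
    summary: pd.DataFrame
    prediction_summary: pd.DataFrame
    manifest: dict

    def table(self, metric: str, prediction: bool = False) -> pd.DataFrame:
        """Wide table (models x (markers, proportion)) for one metric."""
        src = self.prediction_summary if prediction else self.summary
        sub = src[src["metric"] == metric]
        cols = [c for c in ("markers", "prop_spatial") if c in sub.columns]
        return sub.pivot_table(index="model", columns=cols, values="mean")


def _pyt_layouts(cfg: ProgrammeConfig) -> dict[str, FieldLayout]:
    return {
        t: FieldLayout.lattice(cfg.pyt_rows, cfg.pyt_cols, trial_id=t)
        for t in ("loc1", "loc2")
    }


def _study_genomics(state: ProgrammeState, pc_rule) -> tuple[GenomicData, np.ndarray]:
    """Training-set genomics (polymorphic SNPs only) and the prediction
    cohort projected into the training principal-component basis."""
    z_train = state.pyt.snp_dosage()
    mask = polymorphic_mask(z_train)
    geno = vanraden_grm(z_train[:, mask], state.pyt.ids).compressed(pc_rule)
    z_star_new = geno.project(state.prediction.snp_dosage()[:, mask])
    return geno, z_star_new


def run_simulation_study(config: SimulationStudyConfig, seed: int) -> StudyResult:
    """Run the full replicate grid and aggregate the result tables."""
    rngs = _child_rngs(seed, config.n_replicates)
    layouts = _pyt_layouts(config.programme)
    layout_list = list(layouts.values())
    rows = []
    for rep, rng in enumerate(rngs):
        state = run_programme(config.programme, seed=rng)[0]
        geno, z_star_new = _study_genomics(state, config.pc_rule)
        n_rank = max(config.n_top, int(round(config.top_rank_fraction * state.pyt.n)))
        n_rank_pred = max(
            config.n_top, int(round(config.top_rank_fraction * state.prediction.n))
        )
        for generator in config.generators:
            for prop in config.props:
                vc = VarianceConfig(prop_spatial=prop, spatial_generator=generator)
                phen = simulate_trial_phenotypes(
                    state.pyt,
                    state.pyt_tbv,
                    layout_list,
                    vc,
                    state.sigma2_g_base,
                    seed=rng,
                    year=state.year,
                )
                phen_std, stats = standardize(phen, "year")
                sd = float(stats["sd"].iloc[0])
                centre = float(state.pyt_tbv.mean())
                tbv = (state.pyt_tbv - centre) / sd
                tbv_new = (state.prediction_tbv - centre) / sd
                fields = phen[["spatial_effect", "plot_residual"]].to_numpy()
                spatial_share = fields[:, 0].var() / fields.var(axis=0).sum()
                for markers in config.marker_settings:
                    for model_name in config.models:
                        spec = ModelSpec(
                            spatial=model_name,
                            genetic="markers" if markers else "iid",
                            intercept_per_trial=True,
                        )
                        m = assemble(spec, phen_std, layouts, geno if markers else None)
                        f = fit(m, strategy=config.strategy)
                        bv, bv_sd = f.breeding_values(state.pyt.ids)
                        row = {
                            "replicate": rep,
                            "generator": generator,
                            "prop_spatial": prop,
                            "markers": markers,
                            "model": model_name,
                            "correlation": correlation(tbv, bv),
                            "crps": crps_gaussian(bv, bv_sd, tbv).mean(),
                            "top_capture": top_capture(tbv, bv, config.n_top, n_rank),
                            "realized_h2": state.realized_h2_plot,
                            "realized_spatial_share": spatial_share,
                            "phenotype_sd": sd,
                        }
                        if markers:
                            pm, ps = predict_lines(f, z_star_new)
                            row |= {
                                "pred_correlation": correlation(tbv_new, pm),
                                "pred_crps": crps_gaussian(pm, ps, tbv_new).mean(),
                                "pred_top_capture": top_capture(
                                    tbv_new, pm, config.n_top, n_rank_pred
                                ),
                            }
                        rows.append(row)
    results = pd.DataFrame(rows)
    summary = summarize_study(results)
    pred = results[results["markers"]]
    prediction_summary = summarize_study(
        pred,
        metrics=("pred_correlation", "pred_crps", "pred_top_capture"),
        keys=("prop_spatial", "model", "generator"),
    )
    manifest = {
        "seed": seed,
        "n_replicates": config.n_replicates,
        "programme": asdict(config.programme),
        "props": list(config.props),
        "generators": list(config.generators),
        "strategy": config.strategy,
        "pc_rule": config.pc_rule,
        "mean_realized_h2": float(results["realized_h2"].mean()),
    }
    return StudyResult(results, summary, prediction_summary, manifest)


# ---------------------------------------------------------------------------
# multi-trial study


@dataclass(frozen=True)
class MultiTrialConfig:
    """Synthetic multi-trial data with the grouped-hyperparameter structure
    of the multi-year wheat analysis: four trials, two replicates per line,
    spatial fields independent per trial but sharing hyperparameters within
    two year-like groups."""

    n_lines: int = 100
    n_rows: int = 20
    n_cols: int = 10
    n_markers: int = 300
    trial_ids: tuple[str, ...] = ("t2011_fi", "t2011_mws", "t2012_fi", "t2012_mws")
    groups: tuple[tuple[str, ...], ...] = (
        ("t2011_fi", "t2011_mws"),
        ("t2012_fi", "t2012_mws"),
    )
    intercepts: tuple[float, ...] = (0.0, 1.0, -0.5, 2.0)
    # per-group spatial truth (range, variance), trials inherit their group's
    spatial_range: tuple[float, ...] = (8.0, 4.0)
    spatial_var: tuple[float, ...] = (0.6, 0.3)
    var_additive: float = 0.5
    var_nonadditive: float = 0.1
    var_residual: float = 0.4
    pc_rule: float | int = 0.95
    strategy: str = "eb"

    def __post_init__(self) -> None:
        if self.n_rows * self.n_cols != 2 * self.n_lines:
            raise ValueError("layout must hold exactly two replicates per line")
        grouped = [t for g in self.groups for t in g]
        if sorted(grouped) != sorted(self.trial_ids):
            raise ValueError("groups must partition trial_ids")


@dataclass
class MultiTrialResult:
    phenotypes: pd.DataFrame
    single_fits: dict[str, FitResult]
    joint_fit: FitResult
    single_marker_fits: dict[str, FitResult]
    joint_marker_fit: FitResult
    genetic_sd: pd.DataFrame
    manifest: dict

    @property
    def n_spatial_hyper_sets(self) -> int:
        groups = {
            h.group
            for h in self.joint_fit.model.hypers
            if h.group is not None
        }
        return len(groups)


def _simulate_multitrial(config: MultiTrialConfig, rng: np.random.Generator):
    q = rng.uniform(0.2, 0.8, size=config.n_markers)
    z_raw = rng.binomial(2, q, size=(config.n_lines, config.n_markers)).astype(float)
    keep = polymorphic_mask(z_raw)
    z_raw = z_raw[:, keep]
    u = rng.standard_normal(z_raw.shape[1])
    zc = z_raw - z_raw.mean(axis=0)
    tbv = zc @ u
    tbv *= np.sqrt(config.var_additive / tbv.var())
    nonadd = rng.normal(0.0, np.sqrt(config.var_nonadditive), config.n_lines)
    g = tbv + nonadd
    line_ids = np.array([f"L{i:03d}" for i in range(config.n_lines)])

    group_of = {t: gi for gi, grp in enumerate(config.groups) for t in grp}
    layouts = {}
    frames = []
    for ti, t in enumerate(config.trial_ids):
        lay = FieldLayout.lattice(config.n_rows, config.n_cols, trial_id=t)
        layouts[t] = lay
        gi = group_of[t]
        cov = matern_cov(
            lay.coords,
            MaternParams(sigma2=config.spatial_var[gi], range_=config.spatial_range[gi]),
        )
        x = sample_field(cov=cov, rng=rng)[0]
        # two replicates: lines assigned to plots at random
        assign = rng.permutation(np.repeat(np.arange(config.n_lines), 2))
        e = rng.normal(0.0, np.sqrt(config.var_residual), lay.n_plots)
        y = config.intercepts[ti] + g[assign] + x + e
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": t,
                    "year": t.split("_")[0],
                    "location": t,
                    "row": lay.row,
                    "col": lay.col,
                    "x_coord": lay.coords[:, 0],
                    "y_coord": lay.coords[:, 1],
                    "line_id": line_ids[assign],
                    "phenotype": y,
                }
            )
        )
    phen = pd.concat(frames, ignore_index=True)
    return phen, layouts, z_raw, line_ids, tbv, g


def _genetic_sd_rows(fitres: FitResult, fit_name: str) -> list[dict]:
    hs = fitres.hyper_summary
    rows = []
    for var_name in ("var_n", "var_a"):
        sub = hs[hs["name"] == var_name]
        if len(sub):
            rows.append(
                {
                    "fit": fit_name,
                    "hyper": var_name,
                    "estimate": float(sub["estimate"].iloc[0]),
                    "sd": float(sub["sd"].iloc[0]),
                }
            )
    return rows


def run_multitrial(config: MultiTrialConfig, seed: int) -> MultiTrialResult:
    """Fit the four single-trial models and the joint grouped models, with
    and without markers, on one synthetic multi-trial data set."""
    (rng,) = _child_rngs(seed, 1)
    phen, layouts, z_raw, line_ids, tbv, g = _simulate_multitrial(config, rng)
    geno = vanraden_grm(z_raw, line_ids, scale=True).compressed(config.pc_rule)

    sd_rows = []
    single_fits = {}
    single_marker_fits = {}
    for t in config.trial_ids:
        sub, _ = standardize(phen[phen["trial_id"] == t], "trial")
        m1 = assemble(ModelSpec(spatial="matern", genetic="iid"), sub, layouts)
        f1 = fit(m1, strategy=config.strategy)
        single_fits[t] = f1
        sd_rows += _genetic_sd_rows(f1, f"W1[{t}]")
        m2 = assemble(
            ModelSpec(spatial="matern", genetic="markers_iid"), sub, layouts, geno
        )
        single_marker_fits[t] = fit(m2, strategy=config.strategy)

    joint, _ = standardize(phen, "global")
    mj = assemble(
        ModelSpec(
            spatial="matern",
            genetic="iid",
            intercept_per_trial=True,
            spatial_groups=config.groups,
        ),
        joint,
        layouts,
    )
    joint_fit = fit(mj, strategy=config.strategy)
    sd_rows += _genetic_sd_rows(joint_fit, "W1M")
    mjm = assemble(
        ModelSpec(
            spatial="matern",
            genetic="markers_iid",
            intercept_per_trial=True,
            spatial_groups=config.groups,
        ),
        joint,
        layouts,
        geno,
    )
    joint_marker_fit = fit(mjm, strategy=config.strategy)

    manifest = {
        "seed": seed,
        "config": asdict(config),
        "p_star": geno.p_star,
        "joint_hypers": [h.name for h in mj.hypers],
        "joint_marker_hypers": [h.name for h in mjm.hypers],
    }
    return MultiTrialResult(
        phenotypes=phen,
        single_fits=single_fits,
        joint_fit=joint_fit,
        single_marker_fits=single_marker_fits,
        joint_marker_fit=joint_marker_fit,
        genetic_sd=pd.DataFrame(sd_rows),
        manifest=manifest,
    )


# ---------------------------------------------------------------------------
# Nelder wheel


@dataclass(frozen=True)
class NelderConfig:
    design: NelderDesign = field(default_factory=NelderDesign)
    intercept: float = 10.0
    density_effect: float = 10.0
    sigma2_s: float = 0.5
    range_: float = 10.0
    sigma2_e: float = 0.5
    strategy: str = "grid"
    grid_step: float = 4.0
    grid_margin: float = 5.0


@dataclass
class NelderResult:
    phenotypes: pd.DataFrame
    matern_fit: FitResult
    nospatial_fit: FitResult
    truth: dict
    coverage: dict
    reconstruction: pd.DataFrame
    manifest: dict

    @property
    def residual_inflation(self) -> float:
        """NoSpatial residual-variance estimate over the true residual
        variance (expected to be roughly 2 when half of the plot variance is
        spatially structured)."""
        return self.nospatial_fit.theta_mode["var_e"] / self.truth["sigma2_e"]


def _reconstruct_field(
    fitres: FitResult, layout: FieldLayout, grid_coords: np.ndarray
) -> pd.DataFrame:
    """Posterior mean and sd of the Matern field on a prediction grid, by
    Gaussian conditioning at the modal hyperparameters."""
    theta = fitres.theta_mode
    group = next(h.group for h in fitres.model.hypers if h.kind == "log_kappa")
    kappa = theta[f"log_kappa:{group}"]
    tau = theta[f"log_tau:{group}"]
    from .spatial import sigma2_from_spde

    params = MaternParams(
        sigma2=sigma2_from_spde(kappa, tau), range_=np.sqrt(8.0) / kappa
    )
    all_coords = np.vstack([layout.coords, grid_coords])
    cov = matern_cov(all_coords, params)
    n_obs = layout.n_plots
    c_oo = cov[:n_obs, :n_obs]
    c_go = cov[n_obs:, :n_obs]
    c_gg_diag = np.diag(cov)[n_obs:]
    b = np.linalg.solve(c_oo, c_go.T).T
    sl = fitres.model.block_slices()[f"spatial[{layout.trial_id}]"]
    mu_o = fitres.latent_mean[sl]
    sig_o = fitres.cov_mode[sl, sl]
    mean_g = b @ mu_o
    var_g = c_gg_diag - np.einsum("ij,ij->i", b, c_go) + np.einsum(
        "ij,jk,ik->i", b, sig_o, b
    )
    return pd.DataFrame(
        {
            "x_coord": grid_coords[:, 0],
            "y_coord": grid_coords[:, 1],
            "mean": mean_g,
            "sd": np.sqrt(np.maximum(var_g, 0.0)),
        }
    )


def run_nelder(config: NelderConfig, seed: int) -> NelderResult:
    """Simulate one Nelder wheel data set, fit Matern and NoSpatial models,
    summarize parameter recovery and reconstruct the spatial field."""
    (rng,) = _child_rngs(seed, 1)
    layout = nelder_layout(config.design)
    dens = layout.extra["density"].to_numpy()
    cov = matern_cov(
        layout.coords, MaternParams(sigma2=config.sigma2_s, range_=config.range_)
    )
    x = sample_field(cov=cov, rng=rng)[0]
    y = (
        config.intercept
        + config.density_effect * dens
        + x
        + rng.normal(0.0, np.sqrt(config.sigma2_e), layout.n_plots)
    )
    phen = layout.to_frame().assign(phenotype=y, true_spatial=x)

    spec = ModelSpec(spatial="matern", genetic="none", covariates=("density",))
    m = assemble(spec, phen, {layout.trial_id: layout})
    matern_fit = fit(m, strategy=config.strategy)
    m0 = assemble(
        ModelSpec(spatial="none", genetic="none", covariates=("density",)),
        phen,
        {layout.trial_id: layout},
    )
    nospatial_fit = fit(m0, strategy=config.strategy)

    truth = {
        "intercept": config.intercept,
        "density_effect": config.density_effect,
        "sigma2_s": config.sigma2_s,
        "range": config.range_,
        "sigma2_e": config.sigma2_e,
    }
    lo, hi = matern_fit.latent_interval("fixed", 0)
    coverage = {"intercept": bool(lo <= truth["intercept"] <= hi)}
    lo, hi = matern_fit.latent_interval("fixed", 1)
    coverage["density_effect"] = bool(lo <= truth["density_effect"] <= hi)
    _, (lo, hi) = matern_fit.matern_interval("sigma2_s")
    coverage["sigma2_s"] = bool(lo <= truth["sigma2_s"] <= hi)
    _, (lo, hi) = matern_fit.matern_interval("range")
    coverage["range"] = bool(lo <= truth["range"] <= hi)
    lo, hi = matern_fit.hyper_interval("var_e")
    coverage["sigma2_e"] = bool(lo <= truth["sigma2_e"] <= hi)

    rmax = config.design.radii[-1] + config.grid_margin
    ticks = np.arange(-rmax, rmax + config.grid_step, config.grid_step)
    gx, gy = np.meshgrid(ticks, ticks)
    grid_coords = np.column_stack([gx.ravel(), gy.ravel()])
    reconstruction = _reconstruct_field(matern_fit, layout, grid_coords)

    manifest = {"seed": seed, "config": {**asdict(config), "design": asdict(config.design)}}
    return NelderResult(
        phenotypes=phen,
        matern_fit=matern_fit,
        nospatial_fit=nospatial_fit,
        truth=truth,
        coverage=coverage,
        reconstruction=reconstruction,
        manifest=manifest,
    )
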