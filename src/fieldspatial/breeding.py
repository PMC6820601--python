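"""Wheat-like breeding-programme and field-trial simulator.

Emulates the study system: a genome of 21 chromosomes carrying SNP markers
and QTL, a recurrent-selection programme (crosses among inbred parents,
doubled-haploid progeny, headrow selection into a preliminary yield trial,
further selection of new parents), and yield phenotypes for the preliminary
yield trial (PYT) composed of year, location, genetic, spatially dependent
plot and independent plot effects.

All individuals are fully homozygous (inbred founders, doubled-haploid
progeny), so a single haplotype per individual determines the genotype;
haplotypes are nevertheless stored as pairs so that the doubled-haploid
invariant (zero heterozygosity) is a checkable property rather than an
encoding accident.

Meiosis uses a Haldane (no-interference) model: each chromosome is 1 Morgan
long with equally spaced loci, and the recombination fraction between
adjacent loci at map distance ``d`` is ``(1 - exp(-2 d)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spatial import AR1Params, FieldLayout, MaternParams, ar1xar1_cov, matern_cov, sample_field

__all__ = [
    "Genome",
    "Population",
    "TraitArchitecture",
    "VarianceConfig",
    "ProgrammeConfig",
    "ProgrammeState",
    "make_founders",
    "cross_and_dh",
    "true_breeding_values",
    "run_programme",
    "simulate_trial_phenotypes",
    "standardize",
]


# ---------------------------------------------------------------------------
# genome and populations


@dataclass(frozen=True)
class Genome:
    """Marker/QTL map.  Loci are equally spaced on each chromosome; QTL
    positions are spread evenly among the loci and flagged by ``is_qtl``."""

    n_chr: int = 21
    n_snp_per_chr: int = 100
    n_qtl_per_chr: int = 100
    chr_length: float = 1.0  # Morgans

    def __post_init__(self) -> None:
        if self.n_chr < 1:
            raise ValueError("n_chr must be >= 1")
        if self.n_snp_per_chr < 0 or self.n_qtl_per_chr < 0:
            raise ValueError("locus counts must be non-negative")
        if self.n_snp_per_chr + self.n_qtl_per_chr < 1:
            raise ValueError("need at least one locus per chromosome")
        if self.chr_length <= 0:
            raise ValueError("chr_length must be positive")

    @property
    def loci_per_chr(self) -> int:
        return self.n_snp_per_chr + self.n_qtl_per_chr

    @property
    def n_loci(self) -> int:
        return self.n_chr * self.loci_per_chr

    @property
    def positions(self) -> np.ndarray:
        """Map positions (Morgans) within chromosome, tiled over chromosomes."""
        within = np.linspace(0.0, self.chr_length, self.loci_per_chr, endpoint=True)
        return np.tile(within, self.n_chr)

    @property
    def chromosome(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_chr), self.loci_per_chr)

    @property
    def is_qtl(self) -> np.ndarray:
        mask = np.zeros(self.loci_per_chr, dtype=bool)
        if self.n_qtl_per_chr > 0:
            idx = np.linspace(0, self.loci_per_chr - 1, self.n_qtl_per_chr)
            mask[np.round(idx).astype(int)] = True
            # guarantee the requested count even with rounding collisions
            short = self.n_qtl_per_chr - mask.sum()
            if short > 0:
                mask[np.flatnonzero(~mask)[:short]] = True
        return np.tile(mask, self.n_chr)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    def locus_table(self, allele_freq: np.ndarray | None = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "chr": self.chromosome,
                "index": np.arange(self.n_loci),
                "pos_morgan": self.positions,
                "is_qtl": self.is_qtl,
            }
        )
        if allele_freq is not None:
            out["allele_freq"] = np.asarray(allele_freq, dtype=float)
        return out

    def recombination_fractions(self) -> np.ndarray:
        """Haldane recombination fraction between consecutive loci; 0.5 across
        chromosome boundaries (independent assortment)."""
        d = np.diff(self.positions)
        r = 0.5 * (1.0 - np.exp(-2.0 * np.abs(d)))
        r[np.diff(self.chromosome) != 0] = 0.5
        return r


@dataclass
class Population:
    """A set of individuals with paired haplotypes (n, 2, n_loci)."""

    genome: Genome
    ids: np.ndarray
    haplotypes: np.ndarray  # uint8, (n, 2, n_loci)
    generation: int = 0
    is_doubled_haploid: bool = False

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        h = np.asarray(self.haplotypes, dtype=np.uint8)
        if h.ndim != 3 or h.shape[1] != 2 or h.shape[2] != self.genome.n_loci:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if len(self.ids) != h.shape[0]:
            raise ValueError("ids/haplotypes length mismatch")
        self.haplotypes = h

    @property
    def n(self) -> int:
        return len(self.ids)

    def dosage(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele dosage in {0, 1, 2}, optionally restricted to ``loci``."""
        d = self.haplotypes.sum(axis=1)
        return d if loci is None else d[:, loci]

    def snp_dosage(self) -> np.ndarray:
        return self.dosage(self.genome.snp_index)

    def heterozygosity(self) -> np.ndarray:
        """Per-individual fraction of heterozygous loci."""
        return (self.haplotypes[:, 0] != self.haplotypes[:, 1]).mean(axis=1)

    def subset(self, index: np.ndarray) -> "Population":
        return Population(
            genome=self.genome,
            ids=self.ids[index],
            haplotypes=self.haplotypes[index],
            generation=self.generation,
            is_doubled_haploid=self.is_doubled_haploid,
        )


def make_founders(
    genome: Genome,
    n_founders: int,
    maf_law=("uniform", 0.1, 0.9),
    seed: np.random.Generator | int | None = None,
) -> tuple[Population, np.ndarray]:
    """Sample fully inbred founder lines.

    Per-locus allele frequencies ``q`` follow ``maf_law``: either a tuple
    ``("uniform", lo, hi)``, a scalar (point mass) or a callable
    ``f(rng, n_loci) -> q``.  Returns the population and the frequencies.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders to cross")
    rng = np.random.default_rng(seed)
    if callable(maf_law):
        q = np.asarray(maf_law(rng, genome.n_loci), dtype=float)
    elif np.isscalar(maf_law):
        q = np.full(genome.n_loci, float(maf_law))
    else:
        kind, lo, hi = maf_law
        if kind != "uniform":
            raise ValueError(f"unknown maf_law {maf_law!r}")
        q = rng.uniform(lo, hi, size=genome.n_loci)
    hap = (rng.random((n_founders, genome.n_loci)) < q).astype(np.uint8)
    haplotypes = np.repeat(hap[:, None, :], 2, axis=1)
    pop = Population(
        genome=genome,
        ids=np.array([f"F{i:04d}" for i in range(n_founders)]),
        haplotypes=haplotypes,
        generation=0,
        is_doubled_haploid=False,
    )
    return pop, q


def _gametes(hap_pair: np.ndarray, n: int, genome: Genome, rng: np.random.Generator) -> np.ndarray:
    """``n`` recombinant gametes from one individual's haplotype pair.

    The source-haplotype indicator along the genome is a two-state Markov
    chain: uniform start per chromosome, switch probability equal to the
    Haldane recombination fraction between adjacent loci.
    """
    n_loci = genome.n_loci
    r = genome.recombination_fractions()
    thresholds = np.empty(n_loci)
    thresholds[0] = 0.5
    thresholds[1:] = r
    # chromosome starts re-randomize the source haplotype
    starts = np.flatnonzero(np.diff(genome.chromosome) != 0) + 1
    thresholds[starts] = 0.5
    switches = rng.random((n, n_loci)) < thresholds
    which = np.cumsum(switches, axis=1) % 2
    return np.where(which == 0, hap_pair[0], hap_pair[1]).astype(np.uint8)


def cross_and_dh(
    parents: Population,
    n_crosses: int,
    n_dh_per_cross: int,
    seed: np.random.Generator | int | None = None,
    *,
    generation: int | None = None,
) -> Population:
    """Make ``n_crosses`` biparental crosses and ``n_dh_per_cross``
    doubled-haploid lines per cross.

    Each cross picks two distinct parents at random; an F1 gamete is drawn
    from each parent to form the F1, and each DH line is a recombinant F1
    gamete duplicated into a homozygous pair.
    """
    if parents.n == 0:
        raise ValueError("empty parent set")
    if parents.n < 2:
        raise ValueError("need at least 2 parents to cross")
    if n_crosses < 1 or n_dh_per_cross < 1:
        raise ValueError("n_crosses and n_dh_per_cross must be >= 1")
    rng = np.random.default_rng(seed)
    genome = parents.genome
    gen = parents.generation + 1 if generation is None else generation
    out = np.empty((n_crosses * n_dh_per_cross, genome.n_loci), dtype=np.uint8)
    for c in range(n_crosses):
        p1, p2 = rng.choice(parents.n, size=2, replace=False)
        f1 = np.stack(
            [
                _gametes(parents.haplotypes[p1], 1, genome, rng)[0],
                _gametes(parents.haplotypes[p2], 1, genome, rng)[0],
            ]
        )
        out[c * n_dh_per_cross : (c + 1) * n_dh_per_cross] = _gametes(
            f1, n_dh_per_cross, genome, rng
        )
    ids = np.array(
        [f"G{gen:02d}_C{c:03d}_D{d:03d}" for c in range(n_crosses) for d in range(n_dh_per_cross)]
    )
    return Population(
        genome=genome,
        ids=ids,
        haplotypes=np.repeat(out[:, None, :], 2, axis=1),
        generation=gen,
        is_doubled_haploid=True,
    )


# ---------------------------------------------------------------------------
# trait


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive allele-substitution effects at the QTL of a genome."""

    genome: Genome
    qtl_effects: np.ndarray

    def __post_init__(self) -> None:
        eff = np.asarray(self.qtl_effects, dtype=float)
        if len(eff) != len(self.genome.qtl_index):
            raise ValueError("qtl_effects length must match the genome's QTL count")
        object.__setattr__(self, "qtl_effects", eff)

    @classmethod
    def sample(cls, genome: Genome, seed=None) -> "TraitArchitecture":
        rng = np.random.default_rng(seed)
        return cls(genome=genome, qtl_effects=rng.standard_normal(len(genome.qtl_index)))

    def rescaled_to(self, pop: Population, sigma2_g: float) -> "TraitArchitecture":
        """Rescale effects so that the variance of breeding values in ``pop``
        equals ``sigma2_g``."""
        bv = true_breeding_values(pop, self)
        v = bv.var()
        if v <= 0:
            raise ValueError("population has no genetic variance; cannot rescale")
        return replace(self, qtl_effects=self.qtl_effects * np.sqrt(sigma2_g / v))


def true_breeding_values(pop: Population, arch: TraitArchitecture) -> np.ndarray:
    """Breeding value of each individual: QTL dosage times effect, summed."""
    if arch.genome != pop.genome:
        raise ValueError("architecture defined on a different genome")
    return pop.dosage(pop.genome.qtl_index).astype(float) @ arch.qtl_effects


# ---------------------------------------------------------------------------
# variance configuration and trial phenotypes


@dataclass(frozen=True)
class VarianceConfig:
    """Variance anchoring for the preliminary yield trial.

    ``h2_plot`` is the plot-level heritability sigma2_g / (sigma2_g +
    sigma2_e), with sigma2_g the base genetic variance, fixing sigma2_e.
    ``prop_spatial`` of sigma2_e is spatially structured; year and location
    effects each have variance sigma2_e.
    """

    h2_plot: float = 0.25
    prop_spatial: float = 0.0
    spatial_generator: str = "matern"  # or "ar1xar1"
    spatial_range: float = 10.0
    ar1_rho: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.h2_plot < 1:
            raise ValueError("h2_plot must be in (0, 1)")
        if not 0 <= self.prop_spatial < 1:
            raise ValueError("prop_spatial must be in [0, 1)")
        if self.spatial_generator not in ("matern", "ar1xar1"):
            raise ValueError("spatial_generator must be 'matern' or 'ar1xar1'")

    def sigma2_e(self, sigma2_g: float) -> float:
        return sigma2_g * (1.0 - self.h2_plot) / self.h2_plot


def _spatial_draw(
    layout: FieldLayout, var_config: VarianceConfig, sigma2_spatial: float, rng: np.random.Generator
) -> np.ndarray:
    if sigma2_spatial <= 0:
        return np.zeros(layout.n_plots)
    if var_config.spatial_generator == "matern":
        cov = matern_cov(
            layout.coords, MaternParams(sigma2=sigma2_spatial, range_=var_config.spatial_range)
        )
        return sample_field(cov=cov, n_samples=1, rng=rng)[0]
    params = AR1Params(rho_r=var_config.ar1_rho, rho_c=var_config.ar1_rho, variance=sigma2_spatial)
    cov = ar1xar1_cov(layout.n_rows, layout.n_cols, params)
    draw = sample_field(cov=cov, n_samples=1, rng=rng)[0]
    # covariance is in row-major plot order
    order = (layout.row - 1) * layout.n_cols + (layout.col - 1)
    return draw[order]


def simulate_trial_phenotypes(
    pyt_lines: Population,
    tbv: np.ndarray,
    layouts: list[FieldLayout],
    var_config: VarianceConfig,
    sigma2_g_base: float,
    seed: np.random.Generator | int | None = None,
    *,
    year: int = 0,
) -> pd.DataFrame:
    """Simulate PYT phenotypes: year + location + breeding value + spatial +
    plot residual, one plot per line per location.

    Lines are assigned to plots at random within each location.  Spatial
    fields are independent draws per location; their variance is
    ``prop_spatial * sigma2_e`` and the independent plot residual carries the
    remainder.
    """
    rng = np.random.default_rng(seed)
    sigma2_e = var_config.sigma2_e(sigma2_g_base)
    s2_spatial = var_config.prop_spatial * sigma2_e
    s2_plot = (1.0 - var_config.prop_spatial) * sigma2_e
    year_eff = rng.normal(0.0, np.sqrt(sigma2_e))
    frames = []
    tbv = np.asarray(tbv, dtype=float)
    if len(tbv) != pyt_lines.n:
        raise ValueError("tbv length must match population size")
    for layout in layouts:
        if layout.n_plots != pyt_lines.n:
            raise ValueError(
                f"layout {layout.trial_id!r} has {layout.n_plots} plots "
                f"for {pyt_lines.n} lines"
            )
        loc_eff = rng.normal(0.0, np.sqrt(sigma2_e))
        perm = rng.permutation(pyt_lines.n)  # line -> plot assignment
        x = _spatial_draw(layout, var_config, s2_spatial, rng)
        e = rng.normal(0.0, np.sqrt(s2_plot), size=layout.n_plots)
        y = year_eff + loc_eff + tbv[perm] + x + e
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": layout.trial_id,
                    "year": year,
                    "location": layout.trial_id,
                    "row": layout.row,
                    "col": layout.col,
                    "x_coord": layout.coords[:, 0],
                    "y_coord": layout.coords[:, 1],
                    "line_id": pyt_lines.ids[perm],
                    "phenotype": y,
                    "spatial_effect": x,
                    "plot_residual": e,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def standardize(
    table: pd.DataFrame, grouping: str = "year", column: str = "phenotype"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centre and scale ``column`` within groups.

    ``grouping``: ``"year"`` (per year, across locations -- the simulation
    study convention), ``"trial"`` (per trial) or ``"global"`` (one mean/sd
    across all records -- the multi-trial convention).  Returns the
    standardized table and a per-group mean/sd table.
    """
    table = table.copy()
    if grouping == "year":
        keys = table["year"]
    elif grouping == "trial":
        keys = table["trial_id"]
    elif grouping == "global":
        keys = pd.Series(0, index=table.index)
    else:
        raise ValueError("grouping must be 'year', 'trial' or 'global'")
    stats = []
    for key, idx in table.groupby(keys).groups.items():
        vals = table.loc[idx, column].to_numpy(dtype=float)
        if len(vals) < 2:
            raise ValueError(f"group {key!r} has fewer than 2 records")
        mu, sd = vals.mean(), vals.std(ddof=0)
        if sd == 0:
            raise ValueError(f"group {key!r} has zero standard deviation")
        table.loc[idx, column] = (vals - mu) / sd
        stats.append({"group": key, "mean": mu, "sd": sd, "n": len(vals)})
    return table, pd.DataFrame(stats)


# ---------------------------------------------------------------------------
# breeding programme


@dataclass(frozen=True)
class ProgrammeConfig:
    """Sizes and heritabilities of the recurrent-selection programme.

    Defaults are the desk-scale study configuration; the full-size programme
    of the study system is ``n_crosses=100, n_dh_per_cross=100,
    n_pyt=1000, pyt_rows=50, pyt_cols=20, n_advanced=100, n_parents=50,
    burn_in_years=19, genome=Genome(21, 1000, 1000)``.
    """

    genome: Genome = field(default_factory=Genome)
    n_founders: int = 50
    n_crosses: int = 50
    n_dh_per_cross: int = 40
    n_pyt: int = 200
    pyt_rows: int = 20
    pyt_cols: int = 10
    n_advanced: int = 50
    n_parents: int = 30
    burn_in_years: int = 10
    n_record_years: int = 1
    n_prediction_lines: int = 200
    h2_plot: float = 0.25
    h2_headrow: float = 0.1
    h2_advanced: float = 0.5

    def __post_init__(self) -> None:
        n_lines = self.n_crosses * self.n_dh_per_cross
        if self.n_pyt > n_lines:
            raise ValueError("n_pyt exceeds number of DH candidates")
        if self.n_advanced > self.n_pyt or self.n_parents > self.n_advanced:
            raise ValueError("selection sizes must be nested")
        if self.n_pyt != self.pyt_rows * self.pyt_cols:
            raise ValueError("PYT layout must hold exactly n_pyt plots")


@dataclass
class ProgrammeState:
    """One recorded year of the programme: the PYT cohort with true breeding
    values and genotypes, a genotyped-but-unphenotyped DH prediction cohort,
    and the variance anchors."""

    year: int
    pyt: Population
    pyt_tbv: np.ndarray
    prediction: Population
    prediction_tbv: np.ndarray
    parents: Population
    sigma2_g_base: float
    sigma2_e: float

    @property
    def realized_sigma2_g(self) -> float:
        return float(np.var(self.pyt_tbv))

    @property
    def realized_h2_plot(self) -> float:
        return self.realized_sigma2_g / (self.realized_sigma2_g + self.sigma2_e)


def _select_top(scores: np.ndarray, n: int) -> np.ndarray:
    if n > len(scores):
        raise ValueError(f"cannot select {n} from {len(scores)} candidates")
    return np.argsort(scores, kind="stable")[::-1][:n]


def run_programme(
    config: ProgrammeConfig,
    seed: np.random.Generator | int | None = None,
    *,
    ebv_selector=None,
) -> list[ProgrammeState]:
    """Run the breeding programme and return one state per recorded year.

    Each cycle: cross parents, make DH lines, select the best headrows on a
    low-heritability phenotype into the PYT, select advanced lines on the PYT
    phenotype mean over two notional replicates, and new parents on a
    higher-heritability advanced phenotype.  During recorded years the PYT
    selection criterion can be replaced by estimated breeding values through
    ``ebv_selector(state) -> scores`` (the study convention is a
    no-spatial marker model fitted to the recorded trial data).

    The base genetic variance is fixed at 1 in the first DH cohort; the PYT
    residual variance follows from ``h2_plot`` and stays constant, so
    realized heritability drifts below ``h2_plot`` as selection erodes the
    genetic variance.
    """
    rng = np.random.default_rng(seed)
    genome = config.genome
    founders, _ = make_founders(genome, config.n_founders, seed=rng)
    arch = TraitArchitecture.sample(genome, seed=rng)

    parents = founders
    states: list[ProgrammeState] = []
    sigma2_g_base = 1.0
    sigma2_e = None
    total_years = config.burn_in_years + config.n_record_years
    for year in range(1, total_years + 1):
        dh = cross_and_dh(
            parents, config.n_crosses, config.n_dh_per_cross, seed=rng, generation=year
        )
        if year == 1:
            arch = arch.rescaled_to(dh, sigma2_g_base)
        tbv = true_breeding_values(dh, arch)
        if sigma2_e is None:
            sigma2_e = sigma2_g_base * (1.0 - config.h2_plot) / config.h2_plot

        def noisy(values: np.ndarray, h2: float, n_rep: int = 1) -> np.ndarray:
            s2 = sigma2_g_base * (1.0 - h2) / h2 / n_rep
            return values + rng.normal(0.0, np.sqrt(s2), size=len(values))

        headrow_idx = _select_top(noisy(tbv, config.h2_headrow), config.n_pyt)
        pyt = dh.subset(headrow_idx)
        pyt_tbv = tbv[headrow_idx]

        recorded = year > config.burn_in_years
        state = None
        if recorded:
            pred = cross_and_dh(
                parents,
                max(1, config.n_prediction_lines // config.n_dh_per_cross),
                config.n_dh_per_cross,
                seed=rng,
                generation=year,
            )
            keep = rng.permutation(pred.n)[: config.n_prediction_lines]
            pred = pred.subset(keep)
            state = ProgrammeState(
                year=year,
                pyt=pyt,
                pyt_tbv=pyt_tbv,
                prediction=pred,
                prediction_tbv=true_breeding_values(pred, arch),
                parents=parents,
                sigma2_g_base=sigma2_g_base,
                sigma2_e=sigma2_e,
            )
            states.append(state)

        # PYT selection: phenotype mean of the two locations, or EBV in
        # recorded years when a selector is supplied
        if recorded and ebv_selector is not None:
            pyt_scores = np.asarray(ebv_selector(state), dtype=float)
            if len(pyt_scores) != pyt.n:
                raise ValueError("ebv_selector must score every PYT line")
        else:
            pyt_scores = noisy(pyt_tbv, config.h2_plot, n_rep=2)
        adv_idx = _select_top(pyt_scores, config.n_advanced)
        adv_scores = noisy(pyt_tbv[adv_idx], config.h2_advanced)
        parent_idx = adv_idx[_select_top(adv_scores, config.n_parents)]
        parents = pyt.subset(parent_idx)
    return states
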