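import numpy as np
import pandas as pd
import pytest

from fieldspatial.breeding import Genome, Population
from fieldspatial.spatial import FieldLayout


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_genome():
    return Genome(n_chr=2, n_snp_per_chr=6, n_qtl_per_chr=4)


@pytest.fixture
def small_layout():
    return FieldLayout.lattice(4, 5, trial_id="t1")


def make_phenotypes(layout: FieldLayout, n_lines: int, rng, extra_trials=()):
    """Random phenotype table on one or more layouts, lines recycled."""
    layouts = [layout, *extra_trials]
    frames = []
    for lay in layouts:
        n = lay.n_plots
        lines = [f"L{i % n_lines}" for i in range(n)]
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": lay.trial_id,
                    "line_id": rng.permutation(lines),
                    "row": lay.row,
                    "col": lay.col,
                    "x_coord": lay.coords[:, 0],
                    "y_coord": lay.coords[:, 1],
                    "phenotype": rng.normal(size=n),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def toy_phenotypes(small_layout, rng):
    return make_phenotypes(small_layout, n_lines=10, rng=rng)


@pytest.fixture
def inbred_population(tiny_genome, rng):
    hap = (rng.random((6, tiny_genome.n_loci)) < 0.5).astype(np.uint8)
    return Population(
        genome=tiny_genome,
        ids=np.array([f"P{i}" for i in range(6)]),
        haplotypes=np.repeat(hap[:, None, :], 2, axis=1),
    )
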