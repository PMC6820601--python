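"""Reading and writing the package's delimited-text interchange formats.

Everything is plain tab-separated text (pandas round-trips) plus small JSON
metadata: phenotype/layout tables, genotype matrices with a locus sidecar
table, fitted-model summaries, and run manifests recording seed, config
hash and library versions.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .spatial import FieldLayout

__all__ = [
    "write_table",
    "read_table",
    "write_layout",
    "read_layout",
    "write_genotypes",
    "read_genotypes",
    "write_fit_result",
    "config_hash",
    "write_manifest",
]


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_layout(layout: FieldLayout, path) -> Path:
    return write_table(layout.to_frame(), path)


def read_layout(path) -> FieldLayout:
    df = read_table(path)
    trial = str(df["trial_id"].iloc[0])
    extra_cols = [
        c
        for c in df.columns
        if c not in ("trial_id", "row", "col", "x_coord", "y_coord")
    ]
    return FieldLayout(
        trial_id=trial,
        row=df["row"].to_numpy(dtype=int),
        col=df["col"].to_numpy(dtype=int),
        coords=df[["x_coord", "y_coord"]].to_numpy(dtype=float),
        extra=df[extra_cols] if extra_cols else None,
    )


def write_genotypes(path, z_raw: np.ndarray, line_ids, locus_table: pd.DataFrame | None = None) -> Path:
    """Dosage matrix as lines x loci TSV with a ``.loci.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(np.asarray(z_raw), index=pd.Index(line_ids, name="line_id"))
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t")
    if locus_table is not None:
        write_table(locus_table, path.with_suffix(".loci.tsv"))
    return path


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.to_numpy()


def write_fit_result(fitres, prefix) -> dict[str, Path]:
    """Serialize a :class:`~fieldspatial.inference.FitResult`: one row per
    latent effect, the hyperparameter summary, and scalar metadata."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    slices = fitres.model.block_slices()
    rows = []
    for block in fitres.model.blocks:
        sl = slices[block.name]
        for lab, m, s in zip(
            block.labels, fitres.latent_mean[sl], fitres.latent_sd[sl]
        ):
            rows.append({"block": block.name, "label": lab, "mean": m, "sd": s})
    paths = {
        "effects": write_table(pd.DataFrame(rows), prefix.with_suffix(".effects.tsv")),
        "hypers": write_table(fitres.hyper_summary, prefix.with_suffix(".hypers.tsv")),
    }
    meta = {
        "strategy": fitres.strategy,
        "log_posterior_mode": fitres.lp_mode,
        "n_iter": fitres.n_iter,
        "n_eval": fitres.n_eval,
        "n_integration_points": len(fitres.weights),
        "theta_mode": fitres.theta_mode,
    }
    meta_path = prefix.with_suffix(".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=float))
    paths["meta"] = meta_path
    return paths


def config_hash(obj) -> str:
    """Stable short hash of a (nested, JSON-serializable) configuration."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def write_manifest(manifest: dict, path) -> Path:
    """Run manifest: user content plus config hash and library versions."""
    import scipy

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    full = dict(manifest)
    full["config_hash"] = config_hash(manifest)
    full["versions"] = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    path.write_text(json.dumps(full, indent=2, default=str))
    return path
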