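"""Model evaluation: correlation, CRPS, top-ranking capture, study tables.

The continuous ranked probability score of a predictive distribution ``F``
against an observed value ``y`` is ``integral (F(u) - 1{y <= u})^2 du``;
it is negatively oriented (smaller is better).  For a Gaussian predictive
``N(mu, sigma^2)`` it has the closed form

    CRPS = sigma * ( z (2 Phi(z) - 1) + 2 phi(z) - 1/sqrt(pi) ),
    z = (y - mu) / sigma,

which degenerates to ``|y - mu|`` as sigma -> 0.  Breeding-value accuracy
is scored as the Pearson correlation between true and estimated values and
by how many of the best ``n_top`` true individuals appear among the top
``n_rank`` estimated ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = ["crps_gaussian", "correlation", "top_capture", "summarize_study"]


def crps_gaussian(mu, sigma, y) -> np.ndarray | float:
    """Closed-form CRPS of a Gaussian predictive; negatively oriented."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    scalar = mu.ndim == 0 and sigma.ndim == 0 and y.ndim == 0
    mu, sigma, y = np.broadcast_arrays(mu, sigma, y)
    out = np.empty(mu.shape)
    zero = sigma == 0
    out[zero] = np.abs(y[zero] - mu[zero])
    s = sigma[~zero]
    z = (y[~zero] - mu[~zero]) / s
    out[~zero] = s * (z * (2.0 * norm.cdf(z) - 1.0) + 2.0 * norm.pdf(z) - 1.0 / np.sqrt(np.pi))
    return float(out) if scalar else out


def correlation(true_values, est_values) -> float:
    """Pearson correlation between true and estimated values."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(est_values, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if len(t) < 3:
        raise ValueError("need at least 3 values")
    if t.std() == 0 or e.std() == 0:
        raise ValueError("zero variance input")
    return float(np.corrcoef(t, e)[0, 1])


def top_capture(true_values, est_values, n_top: int = 10, n_rank: int = 100) -> int:
    """Number of the true top ``n_top`` individuals found among the
    estimated top ``n_rank``.  "Best" means largest value; ties break by
    the stable original order."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(est_values, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if not n_top <= n_rank <= len(t):
        raise ValueError("need n_top <= n_rank <= length")
    true_top = set(np.argsort(-t, kind="stable")[:n_top])
    est_top = set(np.argsort(-e, kind="stable")[:n_rank])
    return len(true_top & est_top)


def summarize_study(
    results: pd.DataFrame,
    metrics: tuple[str, ...] = ("correlation", "crps", "top_capture"),
    keys: tuple[str, ...] = ("markers", "prop_spatial", "model"),
    replicate_col: str = "replicate",
) -> pd.DataFrame:
    """Per-cell mean and standard error over replicates.

    Returns a long table with one row per (cell, metric) carrying
    ``mean``, ``se = sd / sqrt(n_rep)`` and ``n_rep``.  Raises if any cell
    has fewer than 2 replicates or the replicate grid is incomplete.
    """
    present = [k for k in keys if k in results.columns]
    if not present:
        raise ValueError(f"none of the grouping keys {keys} present")
    counts = results.groupby(list(present))[replicate_col].nunique()
    if counts.nunique() > 1:
        bad = counts[counts < counts.max()]
        raise ValueError(f"missing replicates for cells: {bad.index.tolist()}")
    if counts.min() < 2:
        raise ValueError("need at least 2 replicates per cell")
    rows = []
    for cell, sub in results.groupby(list(present)):
        cell = cell if isinstance(cell, tuple) else (cell,)
        for metric in metrics:
            if metric not in sub.columns:
                continue
            vals = sub[metric].to_numpy(dtype=float)
            rows.append(
                dict(zip(present, cell))
                | {
                    "metric": metric,
                    "mean": vals.mean(),
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)),
                    "n_rep": len(vals),
                }
            )
    return pd.DataFrame(rows)


def study_table(summary: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Wide table for one metric: rows = spatial model, columns =
    (markers, proportion of spatial variance), mirroring the study's result
    tables."""
    sub = summary[summary["metric"] == metric]
    cols = [c for c in ("markers", "prop_spatial") if c in sub.columns]
    return sub.pivot_table(index="model", columns=cols, values="mean")
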