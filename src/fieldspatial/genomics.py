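"""Genomic structures: VanRaden relationship matrix and marker compression.

The additive genetic effect of line ``j`` can be modelled either through a
relationship matrix, ``a ~ N(0, A sigma2_a)`` with ``A = Z Z^T / k``,
``Z`` the column-centred dosage matrix and ``k = 2 sum_l q_l (1 - q_l)``,
or equivalently through marker effects ``a = Z u`` with iid ``u``; the two
parameterizations agree when ``sigma2_a = k sigma2_u``.  To shrink model
dimension, ``Z`` can be replaced by its leading principal components
``Z* = Z V[:, :p*]`` from a singular value decomposition, keeping enough
components to explain a requested share of the variation in ``Z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GenomicData",
    "polymorphic_mask",
    "impute_missing",
    "vanraden_grm",
    "pc_compress",
    "extend_grm_nongenotyped",
]


def polymorphic_mask(z_raw: np.ndarray, min_freq: float = 0.0) -> np.ndarray:
    """Boolean mask of marker columns segregating in ``z_raw`` (allele
    frequency strictly inside ``(min_freq, 1 - min_freq)``).  Selection and
    drift fix loci over breeding cycles; fixed markers carry no relationship
    information and break the VanRaden scaling, so they are dropped."""
    q = np.asarray(z_raw, dtype=float).mean(axis=0) / 2.0
    return (q > min_freq) & (q < 1.0 - min_freq)


def impute_missing(z_raw: np.ndarray) -> np.ndarray:
    """Replace missing dosages (NaN) by their column mean."""
    z = np.array(z_raw, dtype=float)
    missing = np.isnan(z)
    if not missing.any():
        return z
    fully = missing.all(axis=0)
    if fully.any():
        raise ValueError(f"column(s) {np.flatnonzero(fully).tolist()} fully missing")
    means = np.nanmean(z, axis=0)
    idx = np.where(missing)
    z[idx] = means[idx[1]]
    return z


@dataclass(frozen=True)
class GenomicData:
    """Centred (optionally scaled) dosages with the derived VanRaden GRM."""

    line_ids: np.ndarray
    z_raw: np.ndarray
    freqs: np.ndarray
    z: np.ndarray
    a: np.ndarray
    k: float
    scaled: bool = False
    z_star: np.ndarray | None = None
    v: np.ndarray | None = None
    singular_values: np.ndarray | None = None

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def p_star(self) -> int | None:
        return None if self.z_star is None else self.z_star.shape[1]

    def compressed(self, rule) -> "GenomicData":
        """Return a copy with ``z_star`` from :func:`pc_compress`."""
        z_star, v, s = pc_compress(self.z, rule)
        return GenomicData(
            line_ids=self.line_ids,
            z_raw=self.z_raw,
            freqs=self.freqs,
            z=self.z,
            a=self.a,
            k=self.k,
            scaled=self.scaled,
            z_star=z_star,
            v=v,
            singular_values=s,
        )

    def project(self, z_raw_new: np.ndarray) -> np.ndarray:
        """Map new lines' raw dosages into the training principal-component
        basis: centre (and scale) with the *training* frequencies, then apply
        the training rotation ``V``."""
        if self.v is None:
            raise ValueError("call compressed() before projecting new lines")
        z_new = np.asarray(z_raw_new, dtype=float) - 2.0 * self.freqs
        if self.scaled:
            z_new = z_new / self.z_raw.std(axis=0, ddof=0)
        return z_new @ self.v

    def rows_for(self, line_ids: np.ndarray, matrix: str = "z_star") -> np.ndarray:
        """Rows of ``z`` / ``z_star`` for the given line ids, in order."""
        lookup = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            idx = np.array([lookup[lid] for lid in line_ids])
        except KeyError as exc:
            raise KeyError(f"line {exc.args[0]!r} has no genotype") from None
        mat = getattr(self, matrix)
        if mat is None:
            raise ValueError(f"{matrix} not available (call compressed() first)")
        return mat[idx]


def vanraden_grm(
    z_raw: np.ndarray,
    line_ids: np.ndarray | None = None,
    *,
    scale: bool = False,
) -> GenomicData:
    """VanRaden genomic relationship matrix ``A = Z Z^T / k``.

    Allele frequencies are estimated from the dosages themselves.  With
    ``scale=True`` the centred columns are additionally divided by their
    standard deviation (the convention used for the multi-trial wheat
    analysis); the default is centring only.
    """
    z_raw = np.asarray(z_raw, dtype=float)
    if np.isnan(z_raw).any():
        raise ValueError("missing dosages; run impute_missing first")
    m, p = z_raw.shape
    q = z_raw.mean(axis=0) / 2.0
    mono = (q <= 0) | (q >= 1)
    if mono.any():
        raise ValueError(
            f"monomorphic marker column(s): {np.flatnonzero(mono).tolist()[:10]}"
        )
    z = z_raw - 2.0 * q
    if scale:
        sd = z.std(axis=0, ddof=0)
        z = z / sd
    k = float(2.0 * np.sum(q * (1.0 - q)))
    if k <= 0:
        raise ValueError("k = 2 sum q(1-q) is zero")
    a = z @ z.T / k
    if line_ids is None:
        line_ids = np.arange(m)
    return GenomicData(
        line_ids=np.asarray(line_ids), z_raw=z_raw, freqs=q, z=z, a=a, k=k, scaled=scale
    )


def pc_compress(z: np.ndarray, rule) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Compress a centred genotype matrix to its leading principal components.

    ``rule`` is either an explicit component count ``p*`` or a fraction in
    (0, 1): the smallest ``p*`` whose cumulative squared singular values
    reach that share of the variation in ``Z``.  Returns
    ``(Z* = Z V[:, :p*], V[:, :p*], singular values)``.
    """
    z = np.asarray(z, dtype=float)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(z.shape) * np.finfo(float).eps)) if len(s) else 0
    if isinstance(rule, (int, np.integer)):
        p_star = int(rule)
        if p_star < 1 or p_star > rank:
            raise ValueError(f"p* must be in [1, rank(Z)={rank}]")
    elif isinstance(rule, float):
        if not 0 < rule < 1:
            raise ValueError("variance-explained threshold must be in (0, 1)")
        frac = np.cumsum(s**2) / np.sum(s**2)
        p_star = int(np.searchsorted(frac, rule) + 1)
        p_star = min(p_star, rank)
    else:
        raise TypeError("rule must be an int (p*) or a float threshold")
    v = vt.T[:, :p_star]
    return z @ v, v, s


def extend_grm_nongenotyped(a: np.ndarray, m_extra: int) -> np.ndarray:
    """Append ``m_extra`` non-genotyped lines with identity self-relationship
    and zero relationship to the genotyped block."""
    if m_extra < 0:
        raise ValueError("m_extra must be >= 0")
    if m_extra == 0:
        return np.asarray(a, dtype=float)
    m = len(a)
    out = np.zeros((m + m_extra, m + m_extra))
    out[:m, :m] = a
    out[m:, m:] = np.eye(m_extra)
    return out
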