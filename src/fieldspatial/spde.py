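"""Finite-element (SPDE) approximation of the Matern field.

A Matern field with smoothness ``nu = alpha - d/2`` solves the stochastic
partial differential equation ``(kappa^2 - Delta)^{alpha/2} x(s) = W(s)``
with white noise ``W``.  Discretizing the weak form with piecewise-linear
finite elements on a triangulation turns the field into a Gaussian Markov
random field with sparse precision; for ``alpha = 2`` (``nu = 1`` in two
dimensions, the setting used throughout this package)

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

where ``C`` is the (lumped, hence diagonal) mass matrix and ``G`` the
stiffness matrix.  Observation locations are mapped onto mesh nodes by
barycentric interpolation.

The mesh is a regular triangulated grid over the bounding box of the
observation coordinates, extended on every side to push boundary effects
away from the data.  Defaults: spacing of one tenth of the spatial range
and an extension of one range.  With lumped-mass P1 elements this keeps the
interior correlation within about 0.02 of the exact Matern correlation
(coarser meshes, e.g. range/5, leave short-distance errors near 0.08).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .spatial import range_from_kappa

__all__ = ["FemMesh", "fem_matrices", "projection_matrix", "spde_fem_precision"]


@dataclass(frozen=True)
class FemMesh:
    """Regular triangulated grid (squares split along the (0,0)-(1,1) diagonal)."""

    x0: float
    y0: float
    spacing: float
    nx: int  # nodes in x
    ny: int  # nodes in y

    @property
    def n_nodes(self) -> int:
        return self.nx * self.ny

    @property
    def nodes(self) -> np.ndarray:
        xs = self.x0 + self.spacing * np.arange(self.nx)
        ys = self.y0 + self.spacing * np.arange(self.ny)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def node_index(self, ix: np.ndarray, iy: np.ndarray) -> np.ndarray:
        return ix * self.ny + iy

    @property
    def triangles(self) -> np.ndarray:
        ix, iy = np.meshgrid(
            np.arange(self.nx - 1), np.arange(self.ny - 1), indexing="ij"
        )
        ix = ix.ravel()
        iy = iy.ravel()
        n00 = self.node_index(ix, iy)
        n10 = self.node_index(ix + 1, iy)
        n01 = self.node_index(ix, iy + 1)
        n11 = self.node_index(ix + 1, iy + 1)
        lower = np.column_stack([n00, n10, n11])
        upper = np.column_stack([n00, n11, n01])
        return np.vstack([lower, upper])

    @classmethod
    def covering(
        cls, coords: np.ndarray, spacing: float, extension: float
    ) -> "FemMesh":
        """Mesh covering the bounding box of ``coords`` plus ``extension`` on
        each side."""
        coords = np.asarray(coords, dtype=float)
        if spacing <= 0 or extension < 0:
            raise ValueError("spacing must be positive and extension non-negative")
        x0 = coords[:, 0].min() - extension
        x1 = coords[:, 0].max() + extension
        y0 = coords[:, 1].min() - extension
        y1 = coords[:, 1].max() + extension
        nx = int(np.ceil((x1 - x0) / spacing)) + 1
        ny = int(np.ceil((y1 - y0) / spacing)) + 1
        if nx < 2 or ny < 2:
            raise ValueError("degenerate mesh (fewer than 2 nodes per axis)")
        return cls(x0=x0, y0=y0, spacing=spacing, nx=nx, ny=ny)


def fem_matrices(mesh: FemMesh) -> tuple[np.ndarray, sp.csc_matrix]:
    """Lumped mass (diagonal, as a vector) and stiffness matrices."""
    nodes = mesh.nodes
    tris = mesh.triangles
    p0 = nodes[tris[:, 0]]
    p1 = nodes[tris[:, 1]]
    p2 = nodes[tris[:, 2]]
    e0 = p2 - p1
    e1 = p0 - p2
    e2 = p1 - p0
    # twice the signed area
    det = e2[:, 0] * (-e1[:, 1]) - e2[:, 1] * (-e1[:, 0])
    area = 0.5 * np.abs(det)
    if np.any(area <= 0):
        raise ValueError("degenerate mesh triangle")
    # gradient of barycentric basis i is perp(e_i) / (2 area)
    grads = np.stack([e0, e1, e2], axis=1)  # (T, 3, 2)
    grads = np.stack([-grads[:, :, 1], grads[:, :, 0]], axis=2) / det[:, None, None]

    c_diag = np.zeros(mesh.n_nodes)
    rows, cols, vals = [], [], []
    for i in range(3):
        np.add.at(c_diag, tris[:, i], area / 3.0)
        for j in range(3):
            rows.append(tris[:, i])
            cols.append(tris[:, j])
            vals.append(area * np.einsum("td,td->t", grads[:, i], grads[:, j]))
    g = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(mesh.n_nodes, mesh.n_nodes),
    ).tocsc()
    return c_diag, g


def projection_matrix(mesh: FemMesh, coords: np.ndarray) -> sp.csr_matrix:
    """Barycentric interpolation from mesh nodes to arbitrary points inside
    the mesh.  A point lying exactly on a node gets a unit row."""
    coords = np.asarray(coords, dtype=float)
    u = (coords[:, 0] - mesh.x0) / mesh.spacing
    v = (coords[:, 1] - mesh.y0) / mesh.spacing
    if np.any(u < -1e-9) or np.any(v < -1e-9) or np.any(u > mesh.nx - 1 + 1e-9) or np.any(
        v > mesh.ny - 1 + 1e-9
    ):
        raise ValueError("point outside mesh")
    ix = np.clip(np.floor(u).astype(int), 0, mesh.nx - 2)
    iy = np.clip(np.floor(v).astype(int), 0, mesh.ny - 2)
    lu = u - ix
    lv = v - iy
    n00 = mesh.node_index(ix, iy)
    n10 = mesh.node_index(ix + 1, iy)
    n01 = mesh.node_index(ix, iy + 1)
    n11 = mesh.node_index(ix + 1, iy + 1)
    n = len(coords)
    rows = np.repeat(np.arange(n), 3)
    cols = np.empty((n, 3), dtype=int)
    wts = np.empty((n, 3))
    lower = lv <= lu
    # lower triangle (0,0)-(1,0)-(1,1): f = f00 (1-u) + f10 (u-v) + f11 v
    cols[lower] = np.column_stack([n00, n10, n11])[lower]
    wts[lower] = np.column_stack([1.0 - lu, lu - lv, lv])[lower]
    # upper triangle (0,0)-(1,1)-(0,1): f = f00 (1-v) + f11 u + f01 (v-u)
    cols[~lower] = np.column_stack([n00, n11, n01])[~lower]
    wts[~lower] = np.column_stack([1.0 - lv, lu, lv - lu])[~lower]
    a = sp.coo_matrix((wts.ravel(), (rows, cols.ravel())), shape=(n, mesh.n_nodes))
    a.sum_duplicates()
    a.eliminate_zeros()
    return a.tocsr()


def spde_fem_precision(
    coords: np.ndarray,
    kappa: float,
    tau: float,
    *,
    mesh: FemMesh | None = None,
    spacing: float | None = None,
    extension: float | None = None,
) -> tuple[sp.csc_matrix, sp.csr_matrix, FemMesh]:
    """Sparse SPDE precision (alpha = 2) and projection onto ``coords``.

    Returns ``(Q, A, mesh)`` where ``Q`` is the node precision and ``A`` maps
    node values to the observation coordinates.
    """
    if kappa <= 0 or tau <= 0:
        raise ValueError("kappa and tau must be positive")
    if mesh is None:
        rng = range_from_kappa(kappa)
        spacing = rng / 10.0 if spacing is None else spacing
        extension = rng if extension is None else extension
        mesh = FemMesh.covering(np.asarray(coords, dtype=float), spacing, extension)
    c_diag, g = fem_matrices(mesh)
    c_inv = sp.diags(1.0 / c_diag)
    c_mat = sp.diags(c_diag)
    q = tau**2 * (kappa**4 * c_mat + 2.0 * kappa**2 * g + g @ c_inv @ g)
    a = projection_matrix(mesh, coords)
    return q.tocsc(), a, mesh
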