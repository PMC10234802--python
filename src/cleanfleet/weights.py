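"""Contiguity spatial weights on the analysis grid.

Cells are neighbors under queen contiguity when their squares share an edge
or a corner (rook: an edge only). Weights are row-standardized, the default
for lattice spatial-error models: W = D^-1 A with A the symmetric binary
adjacency and D the diagonal of row degrees.

For the simultaneous autoregressive likelihood we need the eigenvalues of
W. Because A is symmetric, W is similar to the symmetric matrix
D^-1/2 A D^-1/2, so its spectrum is real; the largest eigenvalue of a
row-standardized matrix is exactly 1, and the feasible interval for the
autoregressive parameter is (1/min(eig), 1/max(eig)).
"""

from __future__ import annotations

import functools

import numpy as np
import scipy.sparse as sp

from .errors import ConfigError, DataError

__all__ = ["SpatialWeights", "grid_adjacency", "build_contiguity_weights", "lattice_weights"]


class SpatialWeights:
    """Row-standardized spatial weights built from a symmetric binary adjacency.

    Parameters
    ----------
    adjacency : scipy.sparse matrix
        Symmetric, binary, zero-diagonal neighbor structure.
    """

    def __init__(self, adjacency):
        A = sp.csr_matrix(adjacency, dtype=float)
        if A.shape[0] != A.shape[1]:
            raise DataError("adjacency must be square")
        if A.shape[0] < 2:
            raise DataError("weights need at least 2 observations")
        if A.diagonal().any():
            raise DataError("adjacency has nonzero diagonal entries")
        if (abs(A - A.T) > 1e-12).nnz:
            raise DataError("adjacency must be symmetric before row-standardization")
        self.adjacency = A
        deg = np.asarray(A.sum(axis=1)).ravel()
        self.degrees = deg
        if (deg == 0).any():
            raise DataError(
                f"{int((deg == 0).sum())} observations have no neighbors (islands); "
                "contiguity weights require every unit to have at least one neighbor"
            )
        self.W = sp.diags(1.0 / deg) @ A
        self.W = sp.csr_matrix(self.W)
        self.n = A.shape[0]
        self._eigs = None

    # -- spectrum -----------------------------------------------------------

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of W, via the symmetric similarity D^-1/2 A D^-1/2.

        Computed densely and cached; intended for n up to a few thousand.
        """
        if self._eigs is None:
            if self.n > 5000:
                raise DataError(
                    f"dense eigenvalue computation limited to n <= 5000 (got {self.n})"
                )
            d = 1.0 / np.sqrt(self.degrees)
            S = (sp.diags(d) @ self.adjacency @ sp.diags(d)).toarray()
            self._eigs = np.linalg.eigvalsh(S)
        return self._eigs

    def lambda_bounds(self):
        """Open feasible interval for the autoregressive parameter."""
        w = self.eigenvalues()
        return (1.0 / w.min(), 1.0 / w.max())

    # -- structure ----------------------------------------------------------

    def subset(self, idx) -> "SpatialWeights":
        """Weights restricted to the given observation indices (re-standardized)."""
        idx = np.asarray(idx)
        A = self.adjacency[idx][:, idx]
        return SpatialWeights(A)

    def permute(self, perm) -> "SpatialWeights":
        perm = np.asarray(perm)
        if sorted(perm) != list(range(self.n)):
            raise DataError("perm must be a permutation of 0..n-1")
        return SpatialWeights(self.adjacency[perm][:, perm])


def grid_adjacency(nrows: int, ncols: int, contiguity: str = "queen") -> sp.csr_matrix:
    """Binary symmetric adjacency of an ``nrows`` x ``ncols`` lattice."""
    if contiguity not in ("queen", "rook"):
        raise ConfigError(f"contiguity must be 'queen' or 'rook', got {contiguity!r}")
    if nrows * ncols < 2:
        raise ConfigError("grid must contain at least 2 cells")
    offsets = [(0, 1), (1, 0)]
    if contiguity == "queen":
        offsets += [(1, 1), (1, -1)]
    rows_i, rows_j = [], []
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        rows_i.append(idx[r0, c0].ravel())
        rows_j.append(idx[r1, c1].ravel())
    i = np.concatenate(rows_i)
    j = np.concatenate(rows_j)
    data = np.ones(len(i))
    n = nrows * ncols
    A = sp.coo_matrix((data, (i, j)), shape=(n, n))
    return sp.csr_matrix(A + A.T)


def build_contiguity_weights(grid, contiguity: str = "queen") -> SpatialWeights:
    """Row-standardized contiguity weights for an analysis grid.

    ``grid`` may be a :class:`~cleanfleet.grid.Grid` or an ``(nrows, ncols)``
    pair. Queen contiguity (edge or corner shared) is the default; rook
    (edge only) is available for sensitivity runs.
    """
    if hasattr(grid, "nrows"):
        nrows, ncols = grid.nrows, grid.ncols
    else:
        nrows, ncols = grid
    return SpatialWeights(grid_adjacency(nrows, ncols, contiguity))


@functools.lru_cache(maxsize=8)
def lattice_weights(nrows: int, ncols: int, contiguity: str = "queen") -> SpatialWeights:
    """Cached lattice weights: repeated fits on the same grid shape share one
    object, so the (dense) eigenvalue decomposition is computed only once."""
    return build_contiguity_weights((nrows, ncols), contiguity)
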