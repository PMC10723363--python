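"""Vectorization of symmetric region-by-region matrices into edge vectors.

Convention: row-major upper triangle with ``i < j``, diagonal excluded, giving
``R(R-1)/2`` edges (30135 for the 246-region atlas).  Covariance flattening for
harmonization includes the diagonal (``R(R+1)/2``; 30381 for 246 regions).
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_edges", "edge_vector", "edge_matrix"]


def n_edges(n_regions: int, include_diagonal: bool = False) -> int:
    """Number of upper-triangle entries for an R x R symmetric matrix."""
    if include_diagonal:
        return n_regions * (n_regions + 1) // 2
    return n_regions * (n_regions - 1) // 2


def edge_vector(mat: np.ndarray, include_diagonal: bool = False) -> np.ndarray:
    """Flatten the upper triangle of a square matrix (row-major, i < j)."""
    mat = np.asarray(mat)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {mat.shape}")
    k = 0 if include_diagonal else 1
    iu = np.triu_indices(mat.shape[0], k=k)
    return mat[iu]


def edge_matrix(vec: np.ndarray, n_regions: int, diagonal: float = 0.0) -> np.ndarray:
    """Rebuild a symmetric matrix from an upper-triangle edge vector."""
    vec = np.asarray(vec)
    if vec.shape[0] != n_edges(n_regions):
        raise ValueError(
            f"edge vector length {vec.shape[0]} does not match "
            f"{n_edges(n_regions)} for R={n_regions}"
        )
    mat = np.full((n_regions, n_regions), diagonal, dtype=float)
    iu = np.triu_indices(n_regions, k=1)
    mat[iu] = vec
    mat[(iu[1], iu[0])] = vec
    return mat
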