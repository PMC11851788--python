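"""Isometric log-ratio (ILR) machinery for compositional diet proportions.

The ILR transform maps the open K-simplex bijectively onto R^(K-1) while
preserving Aitchison geometry, which lets diet proportions be modelled with
ordinary linear predictors. The basis here is the Helmert-type default: the
first coordinate is sqrt(1/2)*log(p1/p2), the j-th balances the first j parts
against part j+1.
"""
from __future__ import annotations

import numpy as np


def helmert_basis(k: int) -> np.ndarray:
    """Orthonormal ILR contrast matrix of shape (k-1, k).

    Rows are orthonormal and sum to zero, so ``V @ log(p)`` equals
    ``V @ clr(p)`` for any composition p.
    """
    if k < 2:
        raise ValueError("need at least 2 parts for an ILR basis")
    v = np.zeros((k - 1, k))
    for j in range(1, k):
        scale = np.sqrt(j / (j + 1.0))
        v[j - 1, :j] = scale / j
        v[j - 1, j] = -scale
    return v


def ilr_transform(p, basis: np.ndarray | None = None) -> np.ndarray:
    """Map interior simplex point(s) to (k-1)-dimensional real coordinates.

    Raises on boundary compositions (zero parts): the transform is only
    defined on the open simplex.
    """
    p = np.asarray(p, dtype=float)
    k = p.shape[-1]
    if basis is None:
        basis = helmert_basis(k)
    if np.any(p <= 0):
        raise ValueError("ILR is undefined on the simplex boundary (zero proportions)")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-8):
        raise ValueError("proportions must sum to 1")
    return np.log(p) @ basis.T


def inverse_ilr(z, basis: np.ndarray | None = None) -> np.ndarray:
    """Map real coordinates back onto the open simplex (softmax of V^T z)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    k = z.shape[-1] + 1
    if basis is None:
        basis = helmert_basis(k)
    y = z @ basis
    y -= y.max(axis=-1, keepdims=True)
    e = np.exp(y)
    return e / e.sum(axis=-1, keepdims=True)
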