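"""Compositional-data transforms: multiplicative zero replacement and
isometric log-ratio (ILR) coordinates.

Compositions carry only relative information; log-ratio coordinates map the
simplex to an unconstrained Euclidean space where ordinary statistics apply.
The ILR here uses the canonical sequential-binary-partition (pivot) basis —
balance j contrasts part j against parts j+1..D — which is orthonormal, so
the transform is an isometry between Aitchison and Euclidean geometry.  The
basis is a parameter: any orthonormal basis of the clr hyperplane may be
supplied.
"""

from __future__ import annotations

import numpy as np


def closure(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    total = x.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("composition must have positive total")
    return x / total


def multiplicative_replacement(comp: np.ndarray, delta: float = 1e-5
                               ) -> np.ndarray:
    """Replace zero parts by ``delta`` and rescale the non-zero parts by
    (1 - z*delta), z = number of zeros, so the output is strictly positive
    and still sums to 1."""
    comp = np.asarray(comp, dtype=float)
    if np.any(comp < 0):
        raise ValueError("composition parts must be non-negative")
    if not np.allclose(comp.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError("composition must sum to 1")
    zeros = comp == 0
    if np.any(zeros.all(axis=-1)):
        raise ValueError("all-zero composition")
    positive = comp[~zeros] if comp.ndim == 1 else comp[comp > 0]
    if delta <= 0 or delta >= positive.min():
        raise ValueError("delta must satisfy 0 < delta < min positive part")
    z = zeros.sum(axis=-1, keepdims=True)
    out = comp * (1.0 - z * delta)
    out[zeros] = delta
    return out


def sbp_basis(d: int) -> np.ndarray:
    """Orthonormal pivot (sequential binary partition) basis, shape (D-1, D).

    Row j (0-based) is the clr direction contrasting part j against the
    geometric mean of parts j+1..D-1, scaled to unit norm:
    sqrt(r/(r+1)) on part j and -1/sqrt(r*(r+1)) on the r = D-1-j trailing
    parts.
    """
    if d < 2:
        raise ValueError("need at least 2 parts")
    basis = np.zeros((d - 1, d))
    for j in range(d - 1):
        r = d - 1 - j
        basis[j, j] = np.sqrt(r / (r + 1.0))
        basis[j, j + 1:] = -1.0 / np.sqrt(r * (r + 1.0))
    return basis


def ilr_transform(comp: np.ndarray, basis: np.ndarray | None = None
                  ) -> np.ndarray:
    """ILR coordinates of a strictly positive composition (D parts ->
    D-1 coordinates).  Scale-invariant: the input is closed first."""
    comp = np.asarray(comp, dtype=float)
    if np.any(comp <= 0):
        raise ValueError("ILR requires strictly positive parts; replace zeros first")
    comp = closure(comp)
    d = comp.shape[-1]
    if basis is None:
        basis = sbp_basis(d)
    return np.log(comp) @ basis.T


def ilr_inverse(coords: np.ndarray, basis: np.ndarray | None = None,
                d: int | None = None) -> np.ndarray:
    """Composition recovering the given ILR coordinates (sums to 1)."""
    coords = np.asarray(coords, dtype=float)
    if basis is None:
        if d is None:
            d = coords.shape[-1] + 1
        basis = sbp_basis(d)
    logc = coords @ basis
    x = np.exp(logc - logc.max(axis=-1, keepdims=True))
    return closure(x)


def aitchison_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Aitchison distance = Euclidean distance between clr vectors."""
    lx, ly = np.log(closure(x)), np.log(closure(y))
    cx = lx - lx.mean(axis=-1, keepdims=True)
    cy = ly - ly.mean(axis=-1, keepdims=True)
    return float(np.linalg.norm(cx - cy))
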