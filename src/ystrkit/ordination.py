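"""Classical (Torgerson) metric multidimensional scaling.

Given a symmetric zero-diagonal distance matrix D, double-center the
squared distances, B = -1/2 * J D^2 J with J = I - 11'/m, and embed on
the top eigenpairs with non-negative eigenvalues.  The embedding is
deterministic up to sign; axes are canonicalized so the first nonzero
loading of each axis is positive.  Negative input entries (slightly
negative Phi-st estimates are routine) are clipped to zero first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import eigh

__all__ = ["Embedding", "classical_mds"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Embedding:
    """MDS result: coordinates, eigenvalues, and a strain diagnostic."""

    labels: tuple[str, ...]
    coordinates: np.ndarray  # (m, dims)
    eigenvalues: np.ndarray  # all eigenvalues of B, descending
    strain: float  # |sum of discarded+negative eigenvalues| / sum |eigenvalues|

    def __post_init__(self) -> None:
        assert self.coordinates.shape[0] == len(self.labels)


def classical_mds(
    labels: Sequence[str], distances: np.ndarray, dims: int = 2
) -> Embedding:
    """Embed a labeled distance matrix in ``dims`` Euclidean dimensions."""
    D = np.asarray(distances, dtype=float).copy()
    m = D.shape[0]
    if D.shape != (m, m) or len(labels) != m:
        raise ValueError("distance matrix must be square and match labels")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if dims < 1:
        raise ValueError("dims must be >= 1")
    neg = int((D < 0).sum())
    if neg:
        log.info("clipping %d negative distance entries to 0 before MDS", neg)
        D[D < 0] = 0.0
    np.fill_diagonal(D, 0.0)

    J = np.eye(m) - np.ones((m, m)) / m
    B = -0.5 * J @ (D * D) @ J
    vals, vecs = eigh(B)  # ascending
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]

    tol = max(1e-12, 1e-9 * max(abs(vals[0]), 1.0)) if m else 0.0
    n_pos = int(np.sum(vals > tol))
    k = min(dims, n_pos)
    coords = np.zeros((m, dims))
    if k:
        coords[:, :k] = vecs[:, :k] * np.sqrt(vals[:k])
    if k < dims:
        log.warning(
            "requested %d dimensions but only %d positive eigenvalues; "
            "padding with zero axes", dims, n_pos,
        )
    # canonical sign: first nonzero loading of each axis positive
    for ax in range(dims):
        col = coords[:, ax]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, ax] = -col

    total = np.abs(vals).sum()
    captured = vals[:k].sum() if k else 0.0
    strain = float((total - captured) / total) if total > 0 else 0.0
    return Embedding(
        labels=tuple(labels),
        coordinates=coords,
        eigenvalues=vals,
        strain=strain,
    )
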