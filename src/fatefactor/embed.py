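"""PCA embedding of the landmark expression matrix.

The M x N landmark matrix is column-centered and projected onto its first
L right singular vectors, giving the M x L observation matrix whose
columns are modelled downstream as independent bifurcating Gaussian
processes.  One principal component is retained per trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .downsample import LandmarkSet

__all__ = ["Embedding", "pca_embed"]


@dataclass
class Embedding:
    """PCA scores (M x L), orthonormal gene projection (N x L), centering
    vector and per-component explained variance."""

    scores: np.ndarray
    projection: np.ndarray
    centering: np.ndarray
    explained_variance: np.ndarray


def pca_embed(landmarks: LandmarkSet, l: int) -> Embedding:
    """Column-centered SVD-based PCA of the landmark matrix.

    Sign convention: each projection column is flipped so that its
    largest-magnitude coordinate is positive, making the output unique.
    """
    Y = np.asarray(landmarks.landmark_expr, dtype=float)
    M, N = Y.shape
    if l > min(M, N):
        raise ValueError(f"l={l} exceeds min(M, N)={min(M, N)}")
    centering = Y.mean(axis=0)
    Yc = Y - centering
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(M, N) * np.finfo(float).eps)) if s.size else 0
    if l > rank:
        raise ValueError(
            f"requested {l} components but centered matrix has rank {rank}")
    V = Vt[:l].T
    # deterministic sign: largest-|entry| coordinate of each component positive
    for j in range(l):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    scores = Yc @ V
    ev = (s[:l] ** 2) / max(M - 1, 1)
    return Embedding(scores=scores, projection=V, centering=centering,
                     explained_variance=ev)
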