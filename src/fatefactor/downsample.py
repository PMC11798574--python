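"""Landmark (metacell) downsampling and landmark->cell mapping.

Cells are partitioned into M clusters in gene space by seeded k-means
(k-means++ initialization, 10 restarts, best within-cluster sum of squares
kept); each cluster centroid is one landmark, treated downstream as a
representative point of the cellular trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Sequence, Union

import numpy as np
from sklearn.cluster import KMeans

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet", "landmark_downsample", "choose_landmark_count",
    "map_landmarks_to_cells", "auto_landmark_count",
]


@dataclass
class LandmarkSet:
    """A partition of cells into M landmarks with mean-expression profiles.

    ``assignment`` holds 0-based landmark indices per cell; ``landmark_expr``
    row m is the mean expression of the cells assigned to landmark m.
    """

    assignment: np.ndarray
    landmark_expr: np.ndarray
    cell_ids: List[str]
    gene_ids: List[str]

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        self.landmark_expr = np.asarray(self.landmark_expr, dtype=float)

    @property
    def M(self) -> int:
        return self.landmark_expr.shape[0]

    @property
    def landmark_size(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.M)


def landmark_downsample(expr: ExpressionMatrix, m: int, seed: int,
                        n_restarts: int = 10) -> LandmarkSet:
    """Partition cells into ``m`` landmarks by seeded k-means.

    Deterministic given ``seed``.  Raises ``ValueError`` if ``m`` exceeds
    the number of cells.
    """
    n = expr.n_cells
    if not 1 <= m <= n:
        raise ValueError(f"m={m} out of range for {n} cells")
    X = expr.values
    if m == n:
        # identity partition: each cell its own landmark
        order = np.arange(n)
        return LandmarkSet(order, X.copy(), expr.cell_ids, expr.gene_ids)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate-point convergence noise
        km = KMeans(n_clusters=m, init="k-means++", n_init=n_restarts,
                    random_state=int(seed) % (2**31))
        labels = km.fit_predict(X)
    # repair empty clusters by reseeding from the farthest-from-centroid
    # cell (can occur with duplicated cells)
    for k in range(m):
        if not np.any(labels == k):
            centers = km.cluster_centers_[labels]
            d2 = ((X - centers) ** 2).sum(axis=1)
            # donors only from clusters that keep >= 1 member
            counts = np.bincount(labels, minlength=m)
            d2[counts[labels] <= 1] = -1.0
            donor = int(np.argmax(d2))
            logger.info("reseeding empty landmark %d from cell %d", k, donor)
            labels[donor] = k
    centroids = np.vstack([X[labels == k].mean(axis=0) for k in range(m)])
    return LandmarkSet(labels, centroids, expr.cell_ids, expr.gene_ids)


def _wcss(X: np.ndarray, lm: LandmarkSet) -> float:
    diffs = X - lm.landmark_expr[lm.assignment]
    return float(np.sum(diffs * diffs))


def choose_landmark_count(expr: ExpressionMatrix, candidates: Sequence[int],
                          seed: int = 0) -> int:
    """Pick the landmark count minimizing a BIC-like penalized WCSS.

    Score(m) = WCSS(m) + m * n_genes * log(n_cells); ties go to smaller m.
    """
    if len(candidates) == 0:
        raise ValueError("candidates must be non-empty")
    n, N = expr.n_cells, expr.n_genes
    if any(c > n or c < 1 for c in candidates):
        raise ValueError("candidates must lie in [1, n_cells]")
    best_m, best_score = None, np.inf
    for m in sorted(set(int(c) for c in candidates)):
        lm = landmark_downsample(expr, m, seed)
        score = _wcss(expr.values, lm) + m * N * np.log(n)
        if score < best_score - 1e-12:
            best_m, best_score = m, score
    return int(best_m)


def auto_landmark_count(expr: ExpressionMatrix, seed: int = 0,
                        refine: bool = True) -> int:
    """Default landmark count: clamp(3*sqrt(n_cells), 20, 300), optionally
    refined over {0.5x, 1x, 2x} by :func:`choose_landmark_count`."""
    n = expr.n_cells
    base = int(np.clip(round(np.sqrt(n)) * 3, 20, 300))
    base = min(base, n)
    if not refine:
        return base
    cands = sorted({max(1, min(n, c)) for c in (base // 2, base, base * 2)})
    return choose_landmark_count(expr, cands, seed=seed)


def map_landmarks_to_cells(landmarks: LandmarkSet,
                           landmark_values: Union[np.ndarray, Sequence]) -> np.ndarray:
    """Transfer a per-landmark vector (or labels) to cells by assignment."""
    vals = np.asarray(landmark_values)
    if vals.shape[0] != landmarks.M:
        raise ValueError(
            f"landmark_values has length {vals.shape[0]}, expected {landmarks.M}")
    return vals[landmarks.assignment]


def map_new_cells(landmarks: LandmarkSet, X_new: np.ndarray) -> np.ndarray:
    """Assign held-out cells to the nearest landmark centroid.

    Ties go to the lowest landmark index (argmin's first-hit convention).
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    d2 = ((X_new[:, None, :] - landmarks.landmark_expr[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)
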