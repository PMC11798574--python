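"""Factor rotation: attributing embedding columns to trajectories.

An orthogonal rotation R (Givens-parameterized) is applied to the PCA
scores so that each rotated column w_l = Y* r_l is scored against its own
trajectory kernel s_l plus an iid Gaussian error term.  The same rotation
applied to the gene projection matrix gives per-gene trajectory weights
u_l = V r_l, and genes with |u| above a threshold form the highly
weighted gene (HWG) set of each trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.linalg
import scipy.optimize

from .bifurcation import (ModelState, build_trajectory_covariance,
                          nearest_psd_repair)
from .embed import Embedding

__all__ = [
    "FactorResult", "givens_rotation", "rotation_log_likelihood",
    "fit_rotation", "factor_scores", "gene_weights", "select_hwg",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class FactorResult:
    """Factor scores W (M x L), gene weights U (N x L), per-trajectory
    highly weighted genes and the fitted error scale."""

    W: np.ndarray
    U: np.ndarray
    R: np.ndarray
    hwg: List[List[Tuple[str, float]]]
    sigma_error: float
    gene_ids: List[str] = field(default_factory=list)


def givens_rotation(angles: Sequence[float], L: Optional[int] = None
                    ) -> np.ndarray:
    """Orthogonal L x L matrix as a product of Givens rotations.

    Planes are traversed in fixed order (0,1), (0,2), ..., (L-2, L-1);
    the determinant is +1 for any angles.
    """
    angles = np.asarray(angles, dtype=float)
    if L is None:
        # solve L(L-1)/2 = len(angles)
        L = int(round((1 + np.sqrt(1 + 8 * angles.size)) / 2))
    if L * (L - 1) // 2 != angles.size:
        raise ValueError(f"{angles.size} angles do not fit any L")
    R = np.eye(L)
    k = 0
    for i in range(L - 1):
        for j in range(i + 1, L):
            c, s = np.cos(angles[k]), np.sin(angles[k])
            G = np.eye(L)
            G[i, i] = c
            G[j, j] = c
            G[i, j] = -s
            G[j, i] = s
            R = R @ G
            k += 1
    return R


def _trajectory_cholesky(state: ModelState, sigma: float) -> List[np.ndarray]:
    chols = []
    for st in state.trajectories:
        S = build_trajectory_covariance(state.T, st)
        S = S + sigma ** 2 * np.eye(S.shape[0])
        S = nearest_psd_repair((S + S.T) / 2.0)
        chols.append(np.linalg.cholesky(S))
    return chols


def rotation_log_likelihood(Ystar: np.ndarray, R: np.ndarray,
                            state: ModelState,
                            sigma_error: Optional[float] = None) -> float:
    """Sum over trajectories of log N(Y* r_l ; 0, s_l + sigma_error^2 I):
    each rotated column against its own trajectory kernel."""
    Y = np.asarray(Ystar, dtype=float)
    sigma = state.sigma_error if sigma_error is None else sigma_error
    W = Y @ np.asarray(R, dtype=float)
    total = 0.0
    for l, Lc in enumerate(_trajectory_cholesky(state, sigma)):
        z = scipy.linalg.solve_triangular(Lc, W[:, l], lower=True,
                                          check_finite=False)
        logdet = 2.0 * np.sum(np.log(np.diag(Lc)))
        total += -0.5 * float(z @ z) - 0.5 * (logdet + Lc.shape[0] * _LOG2PI)
    return float(total)


def _canonicalize_rotation(R: np.ndarray) -> np.ndarray:
    """Match columns to trajectories via the largest |diagonal| entries and
    make the diagonal nonnegative (permutation + sign canonical form)."""
    L = R.shape[0]
    R = R.copy()
    # greedy assignment of columns to rows by |R|
    perm = [-1] * L
    used_rows: set = set()
    order = np.dstack(np.unravel_index(np.argsort(-np.abs(R), axis=None),
                                       R.shape))[0]
    used_cols: set = set()
    for i, j in order:
        if i in used_rows or j in used_cols:
            continue
        perm[i] = j
        used_rows.add(i)
        used_cols.add(j)
        if len(used_rows) == L:
            break
    R = R[:, perm]
    for j in range(L):
        if R[j, j] < 0:
            R[:, j] = -R[:, j]
    return R


def fit_rotation(Ystar: np.ndarray, state: ModelState,
                 n_starts: int = 8, seed: int = 0
                 ) -> Tuple[np.ndarray, float]:
    """Maximize the rotation likelihood over Givens angles and log error
    scale by seeded multi-start local optimization.

    Returns the canonicalized rotation and the fitted sigma_error.  For
    L = 1 the rotation is fixed at +1 (the likelihood is sign-invariant).
    """
    Y = np.asarray(Ystar, dtype=float)
    L = state.L
    n_angles = L * (L - 1) // 2
    rng = np.random.default_rng(seed)

    def neg(params):
        angles, logsig = params[:n_angles], params[-1]
        sigma = float(np.exp(logsig))
        R = givens_rotation(angles, L)
        try:
            val = rotation_log_likelihood(Y, R, state, sigma_error=sigma)
        except np.linalg.LinAlgError:
            return 1e12
        return -val if np.isfinite(val) else 1e12

    if n_angles == 0:
        res = scipy.optimize.minimize_scalar(
            lambda v: neg(np.array([v])), bounds=(-6, 3), method="bounded")
        return np.array([[1.0]]), float(np.exp(res.x))

    starts = []
    grid = np.linspace(0, np.pi / 2, max(2, n_starts // 2), endpoint=False)
    for g in grid:
        starts.append(np.concatenate([np.full(n_angles, g), [np.log(0.3)]]))
    while len(starts) < n_starts:
        starts.append(np.concatenate([rng.uniform(0, np.pi, n_angles),
                                      [rng.normal(np.log(0.3), 0.5)]]))

    best, best_val = None, np.inf
    for x0 in starts:
        res = scipy.optimize.minimize(neg, x0, method="Nelder-Mead",
                                      options=dict(maxiter=400, xatol=1e-5,
                                                   fatol=1e-7))
        if res.fun < best_val:
            best, best_val = res.x, res.fun
    if best is None or not np.isfinite(best_val):
        raise RuntimeError("rotation fit failed from all starts")
    R = _canonicalize_rotation(givens_rotation(best[:n_angles], L))
    return R, float(np.exp(best[-1]))


def factor_scores(Ystar: np.ndarray, R: np.ndarray) -> np.ndarray:
    """W = Y* R."""
    Y, R = np.asarray(Ystar, dtype=float), np.asarray(R, dtype=float)
    if Y.shape[1] != R.shape[0]:
        raise ValueError(f"shape mismatch: {Y.shape} @ {R.shape}")
    return Y @ R


def gene_weights(embedding: Embedding, R: np.ndarray) -> np.ndarray:
    """U = V R, so centered expression times u_l reproduces w_l up to the
    error term."""
    V, R = np.asarray(embedding.projection, dtype=float), np.asarray(R, dtype=float)
    if V.shape[1] != R.shape[0]:
        raise ValueError(f"shape mismatch: {V.shape} @ {R.shape}")
    return V @ R


def select_hwg(U: np.ndarray, gene_ids: Sequence[str],
               threshold: float = 0.05) -> List[List[Tuple[str, float]]]:
    """Per-trajectory genes with |weight| strictly above the threshold,
    sorted by decreasing |weight|, signs retained."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    U = np.asarray(U, dtype=float)
    out = []
    for l in range(U.shape[1]):
        col = U[:, l]
        idx = np.where(np.abs(col) > threshold)[0]
        idx = idx[np.argsort(-np.abs(col[idx]), kind="stable")]
        out.append([(str(gene_ids[i]), float(col[i])) for i in idx])
    return out


def factorize(Ystar: np.ndarray, embedding: Embedding, state: ModelState,
              gene_ids: Sequence[str], hwg_threshold: float = 0.05,
              seed: int = 0) -> FactorResult:
    """Full factorization step: fit R, compute W, U and HWG sets."""
    R, sigma_error = fit_rotation(Ystar, state, seed=seed)
    W = factor_scores(Ystar, R)
    U = gene_weights(embedding, R)
    hwg = select_hwg(U, gene_ids, hwg_threshold)
    return FactorResult(W=W, U=U, R=R, hwg=hwg, sigma_error=sigma_error,
                        gene_ids=[str(g) for g in gene_ids])
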