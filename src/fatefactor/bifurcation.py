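"""Bifurcating Gaussian-process covariance model.

Each of L latent trajectories is a Gaussian process over pseudotime
t in [0, 1] that splits into two branches at a bifurcation time b.  Every
landmark carries a discrete phase label c: 0 before the split (t < b),
1 or 2 for the two branches after it (t >= b).  The covariance between
two landmarks is piecewise:

* both pre-branch (c_x = c_y = 0):        k_rbf(tx, ty) + k_pl(tx, ty)
* same branch after the split (c_x = c_y): k_rbf(tx, ty) + k_pl(tx-b, ty-b)
* different branches (c_x != c_y):         k_rbf(tx, b) k_rbf(b, ty) / k_rbf(b, b)

with an RBF component k_rbf(x, y) = lambda_rbf * exp(-alpha_rbf (x-y)^2)
and a polynomial component k_pl(x, y) = (lambda_pl * x * y + c_pl)^d.
The product-through-the-split form decorrelates branches while keeping
both correlated with the shared trunk.

The observation model sums the L trajectory covariances plus isotropic
noise; every embedding column is scored against that one summed
covariance (a mixture of independent bifurcating GPs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
import scipy.linalg

from .config import PriorConfig

__all__ = [
    "KernelParams", "BifurcationState", "ModelState",
    "rbf_kernel", "poly_kernel", "bifurcation_kernel",
    "enforce_phase_labels", "build_trajectory_covariance",
    "total_covariance", "nearest_psd_repair",
    "log_marginal_likelihood", "log_prior", "log_posterior",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class KernelParams:
    """Hyperparameters of the RBF + polynomial trajectory kernel."""

    lambda_rbf: float = 1.0
    alpha_rbf: float = 1.0
    lambda_pl: float = 1.0
    c_pl: float = 0.0
    d_pl: int = 2

    def __post_init__(self) -> None:
        if self.lambda_rbf <= 0 or self.alpha_rbf <= 0:
            raise ValueError("lambda_rbf and alpha_rbf must be positive")
        if self.d_pl < 1:
            raise ValueError("d_pl must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_rbf, self.alpha_rbf, self.lambda_pl,
                         self.c_pl, float(self.d_pl)])


@dataclass
class BifurcationState:
    """One trajectory's bifurcation time, per-landmark phase labels and
    kernel hyperparameters."""

    b: float
    labels: np.ndarray
    kernel: KernelParams

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)

    def check_consistent(self, T: np.ndarray) -> None:
        """Assert the phase constraint: label 0 iff t < b, else in {1, 2}."""
        T = np.asarray(T)
        pre = T < self.b
        if np.any(self.labels[pre] != 0):
            raise ValueError("pre-branch landmark with nonzero label")
        if np.any(~np.isin(self.labels[~pre], (1, 2))):
            raise ValueError("post-branch landmark with label not in {1,2}")


@dataclass
class ModelState:
    """One posterior sample / point estimate of the full model."""

    T: np.ndarray
    trajectories: List[BifurcationState]
    sigma_S: float
    R: Optional[np.ndarray] = None
    sigma_error: float = 1.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)

    @property
    def L(self) -> int:
        return len(self.trajectories)

    @property
    def M(self) -> int:
        return self.T.shape[0]

    def check_consistent(self) -> None:
        for st in self.trajectories:
            st.check_consistent(self.T)

    def copy(self) -> "ModelState":
        return ModelState(
            T=self.T.copy(),
            trajectories=[BifurcationState(st.b, st.labels.copy(),
                                           replace(st.kernel))
                          for st in self.trajectories],
            sigma_S=self.sigma_S,
            R=None if self.R is None else self.R.copy(),
            sigma_error=self.sigma_error,
        )


# ---------------------------------------------------------------------------
# kernels


def rbf_kernel(tx, ty, p: KernelParams):
    """lambda_rbf * exp(-alpha_rbf * (tx - ty)^2); accepts scalars or arrays."""
    d = np.subtract(tx, ty)
    return p.lambda_rbf * np.exp(-p.alpha_rbf * d * d)


def poly_kernel(tx, ty, p: KernelParams):
    """(lambda_pl * tx * ty + c_pl)^d_pl; accepts scalars or arrays."""
    return (p.lambda_pl * np.multiply(tx, ty) + p.c_pl) ** p.d_pl


def bifurcation_kernel(tx: float, ty: float, cx: int, cy: int, b: float,
                       p: KernelParams) -> float:
    """Piecewise trajectory covariance between two landmarks.

    Labels must satisfy the phase constraint (0 iff t < b, with t = b
    counting as post-branch).
    """
    for t, c in ((tx, cx), (ty, cy)):
        if (t < b) != (c == 0):
            raise ValueError(
                f"label {c} inconsistent with t={t}, b={b} (0 iff t < b)")
    if cx == 0 and cy == 0:
        return float(rbf_kernel(tx, ty, p) + poly_kernel(tx, ty, p))
    if cx == cy:
        return float(rbf_kernel(tx, ty, p) + poly_kernel(tx - b, ty - b, p))
    return float(rbf_kernel(tx, b, p) * rbf_kernel(b, ty, p) / rbf_kernel(b, b, p))


def enforce_phase_labels(T: np.ndarray, state: BifurcationState,
                         rng: np.random.Generator) -> BifurcationState:
    """Repair labels to satisfy the phase constraint under ``T``.

    Pre-branch labels are forced to 0; post-branch labels that are
    currently 0 are resampled uniformly from {1, 2}; valid post-branch
    labels are preserved.  Idempotent: a second application consumes no
    randomness.
    """
    T = np.asarray(T)
    labels = np.asarray(state.labels, dtype=np.int64).copy()
    pre = T < state.b
    labels[pre] = 0
    invalid = (~pre) & (labels == 0)
    if np.any(invalid):
        labels[invalid] = rng.integers(1, 3, size=int(invalid.sum()))
    return BifurcationState(state.b, labels, state.kernel)


# ---------------------------------------------------------------------------
# covariance assembly


def build_trajectory_covariance(T: np.ndarray,
                                state: BifurcationState) -> np.ndarray:
    """M x M covariance of one bifurcating trajectory (vectorized)."""
    T = np.asarray(T, dtype=float)
    state.check_consistent(T)
    p, b = state.kernel, state.b
    c = state.labels
    R = rbf_kernel(T[:, None], T[None, :], p)
    P0 = poly_kernel(T[:, None], T[None, :], p)
    Ts = T - b
    P1 = poly_kernel(Ts[:, None], Ts[None, :], p)
    rb = rbf_kernel(T, b, p)
    cross = np.outer(rb, rb) / p.lambda_rbf
    both_pre = (c[:, None] == 0) & (c[None, :] == 0)
    same_post = (c[:, None] == c[None, :]) & (c[:, None] != 0)
    S = np.where(both_pre, R + P0, np.where(same_post, R + P1, cross))
    return S


def nearest_psd_repair(S: np.ndarray, jitter_start: float = 1e-8,
                       max_doublings: int = 10) -> np.ndarray:
    """Return ``S`` if positive-definite, else the smallest-jitter repair.

    Jitter on the diagonal doubles from ``jitter_start`` until Cholesky
    succeeds (at most ``max_doublings`` times); eigenvalue clipping at
    1e-10 is the last resort.  Repairs are logged at DEBUG level.
    """
    S = np.asarray(S, dtype=float)
    try:
        np.linalg.cholesky(S)
        return S
    except np.linalg.LinAlgError:
        pass
    jitter = float(jitter_start)
    for _ in range(max_doublings + 1):
        try:
            np.linalg.cholesky(S + jitter * np.eye(S.shape[0]))
            logger.debug("covariance repaired with jitter %.3g", jitter)
            return S + jitter * np.eye(S.shape[0])
        except np.linalg.LinAlgError:
            jitter *= 2.0
    w, V = np.linalg.eigh((S + S.T) / 2.0)
    w = np.clip(w, 1e-10, None)
    repaired = (V * w) @ V.T
    try:
        np.linalg.cholesky(repaired)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise np.linalg.LinAlgError(
            f"covariance not repairable: min eig {w.min():.3g}") from exc
    logger.debug("covariance repaired by eigenvalue clipping")
    return repaired


def total_covariance(T: np.ndarray, trajectories: Sequence[BifurcationState],
                     sigma_S: float, repair: bool = True) -> np.ndarray:
    """Summed trajectory covariances plus observation noise sigma_S^2 I."""
    T = np.asarray(T, dtype=float)
    M = T.shape[0]
    S = np.zeros((M, M))
    for st in trajectories:
        S += build_trajectory_covariance(T, st)
    S[np.diag_indices(M)] += sigma_S ** 2
    S = (S + S.T) / 2.0
    if repair:
        S = nearest_psd_repair(S)
    return S


# ---------------------------------------------------------------------------
# likelihood and posterior


def _mvn_logpdf_chol(Y: np.ndarray, chol_lower: np.ndarray) -> float:
    """Sum of zero-mean MVN log-densities of the columns of Y given the
    lower Cholesky factor of their common covariance."""
    M = chol_lower.shape[0]
    Z = scipy.linalg.solve_triangular(chol_lower, Y, lower=True,
                                      check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(chol_lower)))
    ncol = Y.shape[1] if Y.ndim == 2 else 1
    return float(-0.5 * np.sum(Z * Z) - 0.5 * ncol * (logdet + M * _LOG2PI))


def log_marginal_likelihood(Ystar: np.ndarray, T: np.ndarray,
                            trajectories: Sequence[BifurcationState],
                            sigma_S: float) -> float:
    """Log p(Y*) with every column scored against the same summed
    covariance; one shared Cholesky factorization."""
    Ystar = np.atleast_2d(np.asarray(Ystar, dtype=float))
    if Ystar.shape[0] == 1 and np.asarray(T).shape[0] != 1:
        Ystar = Ystar.T
    S = total_covariance(T, trajectories, sigma_S, repair=True)
    L = np.linalg.cholesky(S)
    return _mvn_logpdf_chol(Ystar, L)


def _half_normal_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -np.inf
    return float(0.5 * np.log(2.0 / np.pi) - np.log(scale)
                 - 0.5 * (x / scale) ** 2)


def log_prior(state: ModelState, priors: PriorConfig) -> float:
    """Sum of log-prior terms; -inf encodes out-of-support parameters."""
    T = state.T
    if np.any(T < 0) or np.any(T > 1):
        return -np.inf
    lp = 0.0
    for st in state.trajectories:
        if not 0.0 <= st.b <= 1.0:
            return -np.inf
        p = st.kernel
        if p.lambda_rbf <= 0 or p.alpha_rbf <= 0 or p.lambda_pl <= 0:
            return -np.inf
        for val, sd in ((np.log(p.lambda_rbf), priors.log_lambda_rbf_sd),
                        (np.log(p.alpha_rbf), priors.log_alpha_rbf_sd),
                        (np.log(p.lambda_pl), priors.log_lambda_pl_sd)):
            lp += -0.5 * (val / sd) ** 2 - np.log(sd) - 0.5 * _LOG2PI
        lp += -0.5 * (p.c_pl / priors.c_pl_sd) ** 2 \
            - np.log(priors.c_pl_sd) - 0.5 * _LOG2PI
        # post-branch labels uniform on {1, 2}
        lp += -np.log(2.0) * float(np.sum(st.labels != 0))
    hs = _half_normal_logpdf(state.sigma_S, priors.sigma_s_scale)
    if not np.isfinite(hs):
        return -np.inf
    lp += hs
    return float(lp)


def log_posterior(Ystar: np.ndarray, state: ModelState,
                  priors: PriorConfig) -> float:
    """Log posterior up to a constant; -inf for invalid states."""
    lp = log_prior(state, priors)
    if not np.isfinite(lp):
        return -np.inf
    try:
        state.check_consistent()
    except ValueError:
        return -np.inf
    ll = log_marginal_likelihood(Ystar, state.T, state.trajectories,
                                 state.sigma_S)
    return float(lp + ll)
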