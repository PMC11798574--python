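"""Numba-compiled inner loop of the marginal likelihood.

Array-based mirror of :mod:`fatefactor.bifurcation` used by the MCMC:
trajectory parameters are packed as ``B`` (L,), ``C`` (L, M) int64 labels
and ``P`` (L, 5) rows ``[lambda_rbf, alpha_rbf, lambda_pl, c_pl, d_pl]``.
A test asserts agreement with the plain-numpy reference implementation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _add_traj_cov(S, T, b, c, lam, alpha, lpl, cpl, d):
    M = T.shape[0]
    for i in range(M):
        ti = T[i]
        ci = c[i]
        for j in range(i + 1):
            tj = T[j]
            cj = c[j]
            if ci == 0 and cj == 0:
                v = lam * np.exp(-alpha * (ti - tj) ** 2) \
                    + (lpl * ti * tj + cpl) ** d
            elif ci == cj:
                v = lam * np.exp(-alpha * (ti - tj) ** 2) \
                    + (lpl * (ti - b) * (tj - b) + cpl) ** d
            else:
                v = lam * np.exp(-alpha * ((ti - b) ** 2 + (tj - b) ** 2))
            S[i, j] += v
            if i != j:
                S[j, i] += v


@njit(cache=True)
def total_cov_arrays(T, B, C, P, sigma_S):
    M = T.shape[0]
    L = B.shape[0]
    S = np.zeros((M, M))
    for l in range(L):
        _add_traj_cov(S, T, B[l], C[l], P[l, 0], P[l, 1], P[l, 2], P[l, 3],
                      P[l, 4])
    s2 = sigma_S * sigma_S
    for i in range(M):
        S[i, i] += s2
    return S


@njit(cache=True)
def _cholesky_inplace(S, Lout):
    """Lower Cholesky of S into Lout; returns False if not PD."""
    n = S.shape[0]
    for i in range(n):
        for j in range(i + 1):
            s = S[i, j]
            for k in range(j):
                s -= Lout[i, k] * Lout[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                Lout[i, i] = np.sqrt(s)
            else:
                Lout[i, j] = s / Lout[j, j]
    return True


@njit(cache=True)
def _mvn_loglik_chol(Lc, Y):
    """Sum of zero-mean MVN column log-densities given lower Cholesky Lc."""
    M = Lc.shape[0]
    ncol = Y.shape[1]
    logdet = 0.0
    for i in range(M):
        logdet += np.log(Lc[i, i])
    logdet *= 2.0
    quad = 0.0
    z = np.empty(M)
    for q in range(ncol):
        for i in range(M):
            s = Y[i, q]
            for k in range(i):
                s -= Lc[i, k] * z[k]
            z[i] = s / Lc[i, i]
            quad += z[i] * z[i]
    return -0.5 * quad - 0.5 * ncol * (logdet + M * _LOG2PI)


@njit(cache=True)
def log_marginal_arrays(Y, T, B, C, P, sigma_S):
    """Marginal log-likelihood of Y (M x ncol) under the summed covariance;
    escalating diagonal jitter mirrors the PSD repair of the reference
    implementation.  Returns -inf if the covariance is unrepairable."""
    M = T.shape[0]
    S = total_cov_arrays(T, B, C, P, sigma_S)
    Lc = np.zeros((M, M))
    if _cholesky_inplace(S, Lc):
        return _mvn_loglik_chol(Lc, Y)
    jitter = 1e-8
    for _ in range(11):
        S2 = S.copy()
        for i in range(M):
            S2[i, i] += jitter
        if _cholesky_inplace(S2, Lc):
            return _mvn_loglik_chol(Lc, Y)
        jitter *= 2.0
    return -np.inf


@njit(cache=True)
def derive_labels(T, b, aux):
    """Phase labels from latent branch identities: 0 if t < b, else the
    identity in {1, 2}."""
    M = T.shape[0]
    out = np.empty(M, dtype=np.int64)
    for i in range(M):
        out[i] = 0 if T[i] < b else aux[i]
    return out
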