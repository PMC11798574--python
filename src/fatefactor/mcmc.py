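"""Posterior sampling for the bifurcating-GP mixture.

One sweep updates, in order: pseudotime coordinates by adaptive
Metropolis-within-Gibbs (AMWG, reflecting proposals on [0, 1], scales
adapted toward 44% acceptance), each bifurcation time by univariate slice
sampling, branch identities by exact two-point Gibbs, and the kernel
hyperparameters / observation noise by slice sampling on log (or natural)
scale.

Branch labels are handled by data augmentation: every landmark carries a
latent branch identity in {1, 2} for every trajectory, and the observable
phase label is 0 where t < b and the identity otherwise.  The uniform
prior over identities marginalizes to a uniform prior on post-branch
labels, so the augmented chain targets exactly the intended posterior
while keeping the bifurcation-time slice density well-defined and
pseudotime proposals symmetric when they cross a bifurcation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from ._fast import derive_labels, log_marginal_arrays
from .bifurcation import (BifurcationState, KernelParams, ModelState)
from .config import MCMCConfig, PriorConfig, RunConfig

__all__ = [
    "MCMCChain", "run_mcmc", "posterior_summary",
    "slice_update_scalar", "amwg_update_pseudotime",
    "gibbs_update_branch_labels", "amwg_sample",
]

_HALF_NORMAL_MEDIAN = 0.6744897501960817  # median of |N(0,1)|


@dataclass
class MCMCChain:
    """Thinned posterior samples plus sampler diagnostics."""

    samples: List[ModelState]
    log_post_trace: np.ndarray
    proposal_scales: np.ndarray
    acceptance_counts: np.ndarray
    seed: int
    sample_log_post: np.ndarray = field(default_factory=lambda: np.array([]))


# ---------------------------------------------------------------------------
# packed-array state used internally


class _ArrayState:
    """T (M,), B (L,), AUX (L,M) branch identities, P (L,5) kernel rows,
    sigma_S; labels are derived, never stored."""

    __slots__ = ("T", "B", "AUX", "P", "sigma_S")

    def __init__(self, T, B, AUX, P, sigma_S):
        self.T = np.asarray(T, dtype=float)
        self.B = np.asarray(B, dtype=float)
        self.AUX = np.asarray(AUX, dtype=np.int64)
        self.P = np.asarray(P, dtype=float)
        self.sigma_S = float(sigma_S)

    def labels(self) -> np.ndarray:
        L, M = self.AUX.shape
        C = np.empty((L, M), dtype=np.int64)
        for l in range(L):
            C[l] = derive_labels(self.T, self.B[l], self.AUX[l])
        return C

    def to_model_state(self) -> ModelState:
        C = self.labels()
        trajs = [BifurcationState(float(self.B[l]), C[l].copy(),
                                  KernelParams(*self.P[l, :4],
                                               int(self.P[l, 4])))
                 for l in range(self.B.shape[0])]
        return ModelState(self.T.copy(), trajs, self.sigma_S)

    @classmethod
    def from_model_state(cls, state: ModelState,
                         rng: np.random.Generator) -> "_ArrayState":
        L, M = state.L, state.M
        B = np.array([st.b for st in state.trajectories])
        P = np.vstack([st.kernel.as_array() for st in state.trajectories])
        AUX = np.empty((L, M), dtype=np.int64)
        for l, st in enumerate(state.trajectories):
            aux = np.asarray(st.labels, dtype=np.int64).copy()
            hidden = aux == 0
            aux[hidden] = rng.integers(1, 3, size=int(hidden.sum()))
            AUX[l] = aux
        return cls(state.T.copy(), B, AUX, P, state.sigma_S)


def _log_hyper_prior(P: np.ndarray, sigma_S: float,
                     priors: PriorConfig) -> float:
    lp = 0.0
    for l in range(P.shape[0]):
        lam, alpha, lpl, cpl = P[l, 0], P[l, 1], P[l, 2], P[l, 3]
        if lam <= 0 or alpha <= 0 or lpl <= 0:
            return -np.inf
        lp -= 0.5 * (math.log(lam) / priors.log_lambda_rbf_sd) ** 2
        lp -= 0.5 * (math.log(alpha) / priors.log_alpha_rbf_sd) ** 2
        lp -= 0.5 * (math.log(lpl) / priors.log_lambda_pl_sd) ** 2
        lp -= 0.5 * (cpl / priors.c_pl_sd) ** 2
    if sigma_S <= 0:
        return -np.inf
    lp -= 0.5 * (sigma_S / priors.sigma_s_scale) ** 2
    return lp


def _log_target(Y: np.ndarray, st: _ArrayState, priors: PriorConfig) -> float:
    """Augmented log posterior up to constants (uniform T, b and identity
    priors contribute only support checks)."""
    if np.any(st.T < 0) or np.any(st.T > 1):
        return -np.inf
    if np.any(st.B < 0) or np.any(st.B > 1):
        return -np.inf
    lp = _log_hyper_prior(st.P, st.sigma_S, priors)
    if not np.isfinite(lp):
        return -np.inf
    ll = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P, st.sigma_S)
    return float(lp + ll)


# ---------------------------------------------------------------------------
# samplers


def slice_update_scalar(logdensity: Callable[[float], float], current: float,
                        width: float, max_steps: int,
                        rng: np.random.Generator) -> float:
    """One stepping-out + shrinkage slice-sampling update (univariate).

    If stepping out exhausts ``max_steps`` the width is doubled once and
    the update retried; a second exhaustion raises ``RuntimeError``.
    """
    lp0 = logdensity(current)
    if not np.isfinite(lp0):
        raise ValueError("logdensity(current) must be finite")
    level = lp0 - rng.exponential()
    for attempt in range(2):
        w = width * (2.0 ** attempt)
        u = rng.random() * w
        left, right = current - u, current - u + w
        steps_l = steps_r = max_steps
        while steps_l > 0 and logdensity(left) > level:
            left -= w
            steps_l -= 1
        while steps_r > 0 and logdensity(right) > level:
            right += w
            steps_r -= 1
        if steps_l == 0 or steps_r == 0:
            if attempt == 1:
                raise RuntimeError("slice stepping-out exhausted max_steps")
            continue
        # shrinkage
        for _ in range(1000):
            x = left + rng.random() * (right - left)
            if logdensity(x) >= level:
                return float(x)
            if x < current:
                left = x
            else:
                right = x
        raise RuntimeError("slice shrinkage failed to find a point")
    raise AssertionError("unreachable")


def amwg_sample(logdensity: Callable[[np.ndarray], float], x0: np.ndarray,
                n_iter: int, rng: np.random.Generator,
                initial_scale: float = 1.0, adapt_interval: int = 50,
                target_acceptance: float = 0.44) -> np.ndarray:
    """Generic adaptive Metropolis-within-Gibbs on an arbitrary target.

    Calibration utility: per-coordinate Gaussian proposals with scales
    adapted toward the target acceptance rate by a Robbins-Monro step on
    the log scale.  Returns the (n_iter, d) array of states after each
    sweep.
    """
    x = np.asarray(x0, dtype=float).copy()
    d = x.shape[0]
    log_scales = np.full(d, math.log(initial_scale))
    acc = np.zeros(d, dtype=int)
    lp = logdensity(x)
    if not np.isfinite(lp):
        raise ValueError("logdensity(x0) must be finite")
    out = np.empty((n_iter, d))
    batch = 0
    for it in range(n_iter):
        for j in rng.permutation(d):
            old = x[j]
            x[j] = old + math.exp(log_scales[j]) * rng.normal()
            lp_new = logdensity(x)
            if math.log(rng.random()) < lp_new - lp:
                lp = lp_new
                acc[j] += 1
            else:
                x[j] = old
        out[it] = x
        if (it + 1) % adapt_interval == 0:
            batch += 1
            delta = min(0.25, 1.0 / math.sqrt(batch))
            rate = acc / adapt_interval
            log_scales += np.where(rate > target_acceptance, delta, -delta)
            acc[:] = 0
    return out


def _reflect01(x: float) -> float:
    # reflect into [0, 1]; proposals are at most a few widths out
    while x < 0.0 or x > 1.0:
        if x < 0.0:
            x = -x
        if x > 1.0:
            x = 2.0 - x
    return x


def _amwg_sweep(Y, st: _ArrayState, priors, log_scales, rng,
                current_lp: float) -> Tuple[float, np.ndarray]:
    """In-place AMWG sweep over pseudotime coordinates (random order)."""
    M = st.T.shape[0]
    L = st.B.shape[0]
    accepted = np.zeros(M, dtype=bool)
    order = rng.permutation(M)
    C = st.labels()
    for x in order:
        t_old = st.T[x]
        t_new = _reflect01(t_old + math.exp(log_scales[x]) * rng.normal())
        st.T[x] = t_new
        c_old = C[:, x].copy()
        for l in range(L):
            C[l, x] = 0 if t_new < st.B[l] else st.AUX[l, x]
        lp_new = log_marginal_arrays(Y, st.T, st.B, C, st.P, st.sigma_S)
        if math.log(rng.random()) < lp_new - current_lp:
            current_lp = lp_new
            accepted[x] = True
        else:
            st.T[x] = t_old
            C[:, x] = c_old
    return current_lp, accepted


def amwg_update_pseudotime(state: ModelState, Ystar: np.ndarray,
                           priors: PriorConfig, scales: np.ndarray,
                           rng: np.random.Generator
                           ) -> Tuple[ModelState, np.ndarray]:
    """Public single-sweep AMWG update on a :class:`ModelState`.

    Returns the updated state and per-coordinate acceptance flags.
    """
    st = _ArrayState.from_model_state(state, rng)
    Y = np.asarray(Ystar, dtype=float)
    lp = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P, st.sigma_S)
    log_scales = np.log(np.asarray(scales, dtype=float))
    _, accepted = _amwg_sweep(Y, st, priors, log_scales, rng, lp)
    return st.to_model_state(), accepted


def _gibbs_identity_sweep(Y, st: _ArrayState, priors, rng,
                          current_lp: float) -> float:
    """Exact 2-point Gibbs on branch identities; pre-branch identities are
    refreshed from their uniform prior (no likelihood effect)."""
    L, M = st.AUX.shape
    C = st.labels()
    for l in range(L):
        post = np.where(st.T >= st.B[l])[0]
        pre = np.where(st.T < st.B[l])[0]
        if pre.size:
            st.AUX[l, pre] = rng.integers(1, 3, size=pre.size)
        for x in rng.permutation(post):
            cur = C[l, x]
            other = 3 - cur
            C[l, x] = other
            lp_other = log_marginal_arrays(Y, st.T, st.B, C, st.P,
                                           st.sigma_S)
            # conditional P(cur) with uniform identity prior
            mx = max(current_lp, lp_other)
            p_cur = math.exp(current_lp - mx) / (
                math.exp(current_lp - mx) + math.exp(lp_other - mx))
            if rng.random() < p_cur:
                C[l, x] = cur
            else:
                st.AUX[l, x] = other
                current_lp = lp_other
    return current_lp


def gibbs_update_branch_labels(state: ModelState, Ystar: np.ndarray,
                               priors: PriorConfig,
                               rng: np.random.Generator) -> ModelState:
    """Public Gibbs update of post-branch labels on a :class:`ModelState`."""
    st = _ArrayState.from_model_state(state, rng)
    Y = np.asarray(Ystar, dtype=float)
    lp = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P, st.sigma_S)
    _gibbs_identity_sweep(Y, st, priors, rng, lp)
    return st.to_model_state()


def _slice_b_and_hypers(Y, st: _ArrayState, priors, cfg: MCMCConfig, rng,
                        current_lp: float) -> float:
    L = st.B.shape[0]

    # bifurcation times
    for l in range(L):
        def logdens_b(b):
            if not 0.0 <= b <= 1.0:
                return -np.inf
            old = st.B[l]
            st.B[l] = b
            val = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P,
                                      st.sigma_S)
            st.B[l] = old
            return val
        st.B[l] = slice_update_scalar(logdens_b, st.B[l], cfg.slice_width,
                                      cfg.slice_max_steps, rng)

    # kernel hyperparameters: log lambda_rbf, log alpha_rbf, log lambda_pl,
    # c_pl per trajectory (normal priors on the sampled scale)
    for l in range(L):
        for j, sd in ((0, priors.log_lambda_rbf_sd),
                      (1, priors.log_alpha_rbf_sd),
                      (2, priors.log_lambda_pl_sd),
                      (3, priors.c_pl_sd)):
            on_log = j < 3
            cur = math.log(st.P[l, j]) if on_log else st.P[l, j]

            def logdens_h(v, l=l, j=j, sd=sd, on_log=on_log):
                old = st.P[l, j]
                st.P[l, j] = math.exp(v) if on_log else v
                val = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P,
                                          st.sigma_S)
                st.P[l, j] = old
                return val - 0.5 * (v / sd) ** 2

            new = slice_update_scalar(logdens_h, cur, cfg.slice_width,
                                      cfg.slice_max_steps, rng)
            st.P[l, j] = math.exp(new) if on_log else new

    # observation noise, sampled on log scale with half-normal prior +
    # log-scale Jacobian
    def logdens_s(v):
        s = math.exp(v)
        val = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P, s)
        return val - 0.5 * (s / priors.sigma_s_scale) ** 2 + v

    st.sigma_S = math.exp(slice_update_scalar(
        logdens_s, math.log(st.sigma_S), cfg.slice_width,
        cfg.slice_max_steps, rng))

    return log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P, st.sigma_S)


# ---------------------------------------------------------------------------
# chain driver


def _initial_state(Ystar: np.ndarray, L: int, poly_degree: int,
                   priors: PriorConfig, rng: np.random.Generator
                   ) -> _ArrayState:
    M = Ystar.shape[0]
    ranks = np.argsort(np.argsort(Ystar[:, 0]))
    T = ranks / max(M - 1, 1)
    B = np.full(L, float(np.median(T)))
    AUX = rng.integers(1, 3, size=(L, M)).astype(np.int64)
    P = np.tile(np.array([1.0, 1.0, 1.0, 0.0, float(poly_degree)]), (L, 1))
    return _ArrayState(T, B, AUX, P, _HALF_NORMAL_MEDIAN * priors.sigma_s_scale)


def run_mcmc(Ystar: np.ndarray, config: RunConfig,
             priors: Optional[PriorConfig] = None) -> MCMCChain:
    """Run the full sampler on the embedding scores.

    Deterministic given ``config.mcmc.seed``; burn-in discarded and the
    remainder thinned.
    """
    cfg = config.mcmc
    priors = priors or config.priors
    rng = np.random.default_rng(cfg.seed)
    Y = np.ascontiguousarray(np.asarray(Ystar, dtype=float))
    M, L = Y.shape[0], config.L

    st = _initial_state(Y, L, config.poly_degree, priors, rng)
    lp = _log_target(Y, st, priors)
    tries = 0
    while not np.isfinite(lp):
        tries += 1
        if tries > 100:
            raise RuntimeError("non-finite posterior at initialization")
        st.T = rng.random(M)
        lp = _log_target(Y, st, priors)
    current_ll = log_marginal_arrays(Y, st.T, st.B, st.labels(), st.P,
                                     st.sigma_S)

    log_scales = np.full(M, math.log(cfg.proposal_scale))
    acc_batch = np.zeros(M, dtype=int)
    acc_total = np.zeros(M, dtype=int)
    trace = np.empty(cfg.iterations)
    samples: List[ModelState] = []
    sample_lp: List[float] = []
    batch_idx = 0

    for it in range(cfg.iterations):
        current_ll, accepted = _amwg_sweep(Y, st, priors, log_scales, rng,
                                           current_ll)
        acc_batch += accepted
        acc_total += accepted
        current_ll = _slice_b_and_hypers(Y, st, priors, cfg, rng, current_ll)
        current_ll = _gibbs_identity_sweep(Y, st, priors, rng, current_ll)
        trace[it] = current_ll + _log_hyper_prior(st.P, st.sigma_S, priors)

        if (it + 1) % cfg.adapt_interval == 0:
            batch_idx += 1
            delta = min(0.25, 1.0 / math.sqrt(batch_idx))
            rate = acc_batch / cfg.adapt_interval
            log_scales += np.where(rate > cfg.target_acceptance, delta,
                                   -delta)
            acc_batch[:] = 0

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thinning == 0:
            samples.append(st.to_model_state())
            sample_lp.append(trace[it])

    return MCMCChain(samples=samples, log_post_trace=trace,
                     proposal_scales=np.exp(log_scales),
                     acceptance_counts=acc_total, seed=cfg.seed,
                     sample_log_post=np.asarray(sample_lp))


# ---------------------------------------------------------------------------
# point estimate


def _canonicalize_swaps(samples: Sequence[ModelState],
                        ref: ModelState) -> List[ModelState]:
    """Resolve the per-trajectory 1<->2 label symmetry against a reference
    sample (majority agreement on jointly post-branch landmarks)."""
    out = []
    for s in samples:
        s = s.copy()
        for l, st in enumerate(s.trajectories):
            ref_lab = ref.trajectories[l].labels
            both = (st.labels != 0) & (ref_lab != 0)
            if both.sum() == 0:
                continue
            agree = int(np.sum(st.labels[both] == ref_lab[both]))
            if agree * 2 < both.sum():
                lab = st.labels
                lab[lab != 0] = 3 - lab[lab != 0]
        out.append(s)
    return out


def posterior_summary(chain: MCMCChain) -> ModelState:
    """Posterior point estimate: per-coordinate medians with the label-swap
    symmetry canonicalized against the highest-posterior sample, labels by
    majority vote (then re-enforced against the median pseudotime), and
    branch 1 defined as the larger branch."""
    if not chain.samples:
        raise ValueError("empty chain")
    if chain.sample_log_post.size == len(chain.samples):
        ref = chain.samples[int(np.argmax(chain.sample_log_post))]
    else:
        ref = chain.samples[-1]
    samples = _canonicalize_swaps(chain.samples, ref)

    M = samples[0].M
    L = samples[0].L
    T_med = np.median(np.vstack([s.T for s in samples]), axis=0)
    lo, hi = float(T_med.min()), float(T_med.max())
    span = hi - lo if hi > lo else 1.0
    T_est = (T_med - lo) / span

    trajs = []
    for l in range(L):
        b_med = float(np.median([s.trajectories[l].b for s in samples]))
        b_est = float(np.clip((b_med - lo) / span, 0.0, 1.0))
        P_med = np.median(np.vstack([s.trajectories[l].kernel.as_array()
                                     for s in samples]), axis=0)
        labs = np.vstack([s.trajectories[l].labels for s in samples])
        labels = np.zeros(M, dtype=np.int64)
        post = T_est >= b_est
        for x in np.where(post)[0]:
            votes = labs[:, x]
            n1, n2 = int(np.sum(votes == 1)), int(np.sum(votes == 2))
            labels[x] = 1 if n1 >= n2 else 2
        # branch 1 = larger branch
        if int(np.sum(labels == 2)) > int(np.sum(labels == 1)):
            labels[labels != 0] = 3 - labels[labels != 0]
        trajs.append(BifurcationState(
            b_est, labels,
            KernelParams(P_med[0], P_med[1], P_med[2], P_med[3],
                         int(round(P_med[4])))))

    sigma_med = float(np.median([s.sigma_S for s in samples]))
    est = ModelState(T_est, trajs, sigma_med)
    est.check_consistent()
    return est
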