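import numpy as np
import pytest
import scipy.stats

from conftest import random_consistent_state
from fatefactor.bifurcation import BifurcationState, KernelParams, ModelState
from fatefactor.config import MCMCConfig, PriorConfig, RunConfig
from fatefactor.mcmc import (amwg_sample, amwg_update_pseudotime,
                             gibbs_update_branch_labels, posterior_summary,
                             run_mcmc, slice_update_scalar, MCMCChain)


def _batch_se(x, n_batches=50):
    """Monte-Carlo standard error of the mean by batch means."""
    x = np.asarray(x)
    k = len(x) // n_batches
    means = x[:k * n_batches].reshape(n_batches, k).mean(axis=1)
    return means.std(ddof=1) / np.sqrt(n_batches)


class TestSliceSampler:
    def test_standard_normal_long_run(self):
        rng = np.random.default_rng(0)
        logd = lambda v: -0.5 * v * v
        x, draws = 0.0, np.empty(50_000)
        for i in range(50_000):
            x = slice_update_scalar(logd, x, width=1.0, max_steps=50,
                                    rng=rng)
            draws[i] = x
        assert abs(draws.mean()) < max(0.02, 3 * _batch_se(draws))
        assert 0.95 < draws.var() < 1.05

    def test_containment_in_narrow_support(self):
        rng = np.random.default_rng(1)
        lo, hi = 2.0, 2.001
        logd = lambda v: 0.0 if lo <= v <= hi else -np.inf
        x = 2.0005
        for _ in range(200):
            x = slice_update_scalar(logd, x, width=0.5, max_steps=20,
                                    rng=rng)
            assert lo <= x <= hi

    def test_symmetric_density_mean(self):
        rng = np.random.default_rng(2)
        c = 3.0  # symmetric bimodal around c
        logd = lambda v: float(np.logaddexp(-0.5 * (v - c - 1.5) ** 2,
                                            -0.5 * (v - c + 1.5) ** 2))
        x, total, n = c, 0.0, 20_000
        draws = np.empty(n)
        for i in range(n):
            x = slice_update_scalar(logd, x, width=1.0, max_steps=50,
                                    rng=rng)
            draws[i] = x
        assert abs(draws.mean() - c) < 3 * max(_batch_se(draws), 0.01)

    def test_nonfinite_start_rejected(self):
        with pytest.raises(ValueError):
            slice_update_scalar(lambda v: -np.inf, 0.0, 1.0, 10,
                                np.random.default_rng(0))


class TestGenericAMWG:
    def test_1d_gaussian_moments(self):
        rng = np.random.default_rng(3)
        out = amwg_sample(lambda x: -0.5 * ((x[0] - 2.0) / 1.5) ** 2,
                          np.zeros(1), 50_000, rng)
        x = out[:, 0]
        assert abs(x.mean() - 2.0) < 3 * _batch_se(x)
        assert abs(x.var() - 1.5 ** 2) < 3 * _batch_se((x - x.mean()) ** 2)

    def test_2d_correlated_gaussian_moments(self):
        rng = np.random.default_rng(4)
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)
        mu = np.array([-1.0, 0.5])
        logd = lambda x: -0.5 * (x - mu) @ prec @ (x - mu)
        out = amwg_sample(logd, np.zeros(2), 50_000, rng)
        for j in range(2):
            x = out[:, j]
            assert abs(x.mean() - mu[j]) < 3 * _batch_se(x)
            assert abs(x.var() - cov[j, j]) \
                < 3 * _batch_se((x - x.mean()) ** 2)


def _flat_model_state(M):
    """Near-zero kernel amplitudes: the pseudotime posterior is flat."""
    p = KernelParams(lambda_rbf=1e-12, alpha_rbf=1.0, lambda_pl=1e-12,
                     c_pl=0.0, d_pl=1)
    labels = np.zeros(M, dtype=int)
    return ModelState(np.full(M, 0.5), [BifurcationState(1.0, labels, p)],
                      sigma_S=1.0)


class TestModelAMWG:
    def test_flat_target_uniform_marginal(self):
        rng = np.random.default_rng(5)
        state = _flat_model_state(2)
        Y = np.zeros((2, 1))
        scales = np.full(2, 0.5)
        draws = np.empty(20_000)
        pri = PriorConfig()
        for i in range(20_000):
            state, _ = amwg_update_pseudotime(state, Y, pri, scales, rng)
            draws[i] = state.T[0]
        stat, pval = scipy.stats.kstest(draws[::10], "uniform")
        assert stat < 0.05
        assert pval > 0.01

    def test_zero_scale_chain_constant(self, rng):
        state = random_consistent_state(rng, M=4, L=1)
        Y = rng.normal(size=(4, 1))
        out, acc = amwg_update_pseudotime(state, Y, PriorConfig(),
                                          np.full(4, 1e-300), rng)
        np.testing.assert_allclose(out.T, state.T, atol=1e-12)
        assert acc.all()


class TestGibbsLabels:
    def test_symmetric_likelihood_fair_coin(self):
        # single post-branch landmark: flipping its label is an exact
        # symmetry, so the conditional must be 1/2
        rng = np.random.default_rng(6)
        T = np.array([0.1, 0.2, 0.9])
        p = KernelParams(1.0, 2.0, 0.5, 0.1, 2)
        Y = np.array([[0.3], [0.1], [-0.5]])
        ones = 0
        n = 4000
        for _ in range(n):
            state = ModelState(T, [BifurcationState(
                0.5, np.array([0, 0, 1]), p)], 0.5)
            out = gibbs_update_branch_labels(state, Y, PriorConfig(), rng)
            ones += out.trajectories[0].labels[2] == 1
        # binomial(4000, 1/2): 5 sigma band
        assert abs(ones - n / 2) < 5 * np.sqrt(n * 0.25)

    def test_all_pre_branch_unchanged(self, rng):
        T = np.array([0.1, 0.2, 0.3])
        p = KernelParams()
        state = ModelState(T, [BifurcationState(0.9, np.zeros(3, int), p)],
                           0.5)
        out = gibbs_update_branch_labels(state, rng.normal(size=(3, 1)),
                                         PriorConfig(), rng)
        np.testing.assert_array_equal(out.trajectories[0].labels,
                                      state.trajectories[0].labels)

    def test_separated_branches_recovered(self):
        # strong branch-specific linear trends: exact Gibbs from scrambled
        # labels should recover the truth up to the global 1<->2 swap
        rng = np.random.default_rng(7)
        M = 24
        T = np.linspace(0, 1, M)
        b = 0.3
        p = KernelParams(lambda_rbf=0.05, alpha_rbf=2.0, lambda_pl=8.0,
                         c_pl=0.05, d_pl=1)
        true = np.where(T < b, 0, np.where(np.arange(M) % 2 == 0, 1, 2))
        traj = BifurcationState(b, true, p)
        from fatefactor.bifurcation import total_covariance
        S = total_covariance(T, [traj], 0.05)
        Y = np.linalg.cholesky(S) @ rng.normal(size=(M, 2))
        scrambled = np.where(T < b, 0, rng.integers(1, 3, size=M))
        state = ModelState(T, [BifurcationState(b, scrambled, p)], 0.05)
        for _ in range(10):
            state = gibbs_update_branch_labels(state, Y, PriorConfig(), rng)
        got = state.trajectories[0].labels
        post = true != 0
        agree = np.mean(got[post] == true[post])
        assert max(agree, 1 - agree) >= 0.95


class TestRunMCMC:
    def _scores(self, seed=0, M=20):
        rng = np.random.default_rng(seed)
        return np.ascontiguousarray(rng.normal(size=(M, 2)))

    def test_bookkeeping_single_sample(self):
        cfg = RunConfig(L=2, mcmc=MCMCConfig(iterations=11, burn_in=10,
                                             thinning=1, seed=1))
        chain = run_mcmc(self._scores(), cfg)
        assert len(chain.samples) == 1
        assert np.all(np.isfinite(chain.log_post_trace))

    def test_determinism_same_seed(self):
        cfg = RunConfig(L=1, mcmc=MCMCConfig(iterations=30, burn_in=10,
                                             thinning=2, seed=9))
        a = run_mcmc(self._scores(), cfg)
        b = run_mcmc(self._scores(), cfg)
        np.testing.assert_array_equal(a.log_post_trace, b.log_post_trace)

    def test_states_satisfy_phase_constraint(self):
        cfg = RunConfig(L=2, mcmc=MCMCConfig(iterations=40, burn_in=20,
                                             thinning=4, seed=2))
        chain = run_mcmc(self._scores(1), cfg)
        for s in chain.samples:
            s.check_consistent()


class TestPosteriorSummary:
    def _state(self):
        T = np.linspace(0, 1, 6)
        labels = np.array([0, 0, 0, 1, 1, 2])
        return ModelState(T, [BifurcationState(
            0.5, labels, KernelParams(1.0, 2.0, 0.5, 0.1, 2))], 0.3)

    def test_constant_chain_returns_state(self):
        s = self._state()
        chain = MCMCChain(samples=[s.copy() for _ in range(9)],
                          log_post_trace=np.zeros(9),
                          proposal_scales=np.ones(6),
                          acceptance_counts=np.zeros(6, int), seed=0,
                          sample_log_post=np.zeros(9))
        est = posterior_summary(chain)
        np.testing.assert_allclose(est.T, s.T, atol=1e-12)
        assert est.trajectories[0].b == pytest.approx(0.5)
        np.testing.assert_array_equal(est.trajectories[0].labels,
                                      s.trajectories[0].labels)

    def test_swapped_duplicates_canonicalized(self):
        s = self._state()
        sw = s.copy()
        lab = sw.trajectories[0].labels
        lab[lab != 0] = 3 - lab[lab != 0]
        chain = MCMCChain(samples=[s.copy(), sw, s.copy(), sw.copy()],
                          log_post_trace=np.zeros(4),
                          proposal_scales=np.ones(6),
                          acceptance_counts=np.zeros(6, int), seed=0,
                          sample_log_post=np.array([1.0, 0.0, 0.0, 0.0]))
        est = posterior_summary(chain)
        np.testing.assert_array_equal(est.trajectories[0].labels,
                                      s.trajectories[0].labels)

    def test_empty_chain_raises(self):
        chain = MCMCChain([], np.array([]), np.ones(1), np.zeros(1, int), 0)
        with pytest.raises(ValueError):
            posterior_summary(chain)
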