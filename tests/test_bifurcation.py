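import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_consistent_state
from fatefactor._fast import derive_labels, log_marginal_arrays
from fatefactor.bifurcation import (BifurcationState, KernelParams,
                                    ModelState, bifurcation_kernel,
                                    build_trajectory_covariance,
                                    enforce_phase_labels, log_marginal_likelihood,
                                    log_posterior, log_prior,
                                    nearest_psd_repair, poly_kernel,
                                    rbf_kernel, total_covariance)
from fatefactor.config import PriorConfig


class TestElementaryKernels:
    def test_rbf_values(self):
        p = KernelParams(lambda_rbf=2.0, alpha_rbf=0.5)
        assert rbf_kernel(0.3, 0.3, p) == pytest.approx(2.0, abs=1e-15)
        assert rbf_kernel(0.0, 1.0, p) == pytest.approx(2.0 * np.exp(-0.5),
                                                        abs=1e-12)

    def test_poly_values(self):
        p = KernelParams(lambda_pl=1.0, c_pl=0.0, d_pl=1)
        assert poly_kernel(0.4, 0.5, p) == pytest.approx(0.2, abs=1e-15)
        p2 = KernelParams(lambda_pl=1.0, c_pl=1.0, d_pl=2)
        assert poly_kernel(2.0, 3.0, p2) == pytest.approx(49.0, abs=1e-12)
        assert poly_kernel(0.0, 0.7, p2) == pytest.approx(1.0, abs=1e-15)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_rbf_symmetry(self, a, b):
        p = KernelParams(lambda_rbf=1.3, alpha_rbf=2.2)
        assert rbf_kernel(a, b, p) == rbf_kernel(b, a, p)


class TestBifurcationKernel:
    P = KernelParams(lambda_rbf=1.0, alpha_rbf=1.0, lambda_pl=1.0,
                     c_pl=0.0, d_pl=1)

    def test_case_pre_branch(self):
        v = bifurcation_kernel(0.1, 0.2, 0, 0, 0.5, self.P)
        assert v == pytest.approx(np.exp(-0.01) + 0.02, abs=1e-12)

    def test_case_cross_branch(self):
        v = bifurcation_kernel(0.2, 0.8, 0, 1, 0.5, self.P)
        assert v == pytest.approx(np.exp(-0.09) * np.exp(-0.09), abs=1e-12)

    def test_case_same_branch_shifted_poly(self):
        v = bifurcation_kernel(0.6, 0.8, 1, 1, 0.5, self.P)
        assert v == pytest.approx(np.exp(-0.04) + 0.1 * 0.3, abs=1e-12)

    def test_boundary_collapses_to_amplitude(self):
        # both points at the split on different branches
        v = bifurcation_kernel(0.5, 0.5, 1, 2, 0.5, self.P)
        assert v == pytest.approx(self.P.lambda_rbf, abs=1e-15)

    def test_inconsistent_labels_raise(self):
        with pytest.raises(ValueError):
            bifurcation_kernel(0.1, 0.2, 1, 0, 0.5, self.P)
        with pytest.raises(ValueError):
            bifurcation_kernel(0.7, 0.2, 0, 0, 0.5, self.P)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0.01, 0.99),
           st.integers(1, 2), st.integers(1, 2))
    def test_symmetry_all_cases(self, tx, ty, b, cx_raw, cy_raw):
        cx = 0 if tx < b else cx_raw
        cy = 0 if ty < b else cy_raw
        a = bifurcation_kernel(tx, ty, cx, cy, b, self.P)
        c = bifurcation_kernel(ty, tx, cy, cx, b, self.P)
        assert a == pytest.approx(c, abs=1e-14)


class TestEnforcePhaseLabels:
    def test_all_pre_branch(self):
        T = np.array([0.1, 0.2, 0.3])
        st_ = BifurcationState(0.5, [1, 2, 1], KernelParams())
        out = enforce_phase_labels(T, st_, np.random.default_rng(0))
        assert np.all(out.labels == 0)

    def test_forced_reset_and_resample(self):
        T = np.array([0.2, 0.6])
        st_ = BifurcationState(0.5, [1, 1], KernelParams())
        out = enforce_phase_labels(T, st_, np.random.default_rng(0))
        assert out.labels[0] == 0 and out.labels[1] == 1

    def test_idempotent(self):
        T = np.array([0.2, 0.6, 0.9])
        st_ = BifurcationState(0.5, [0, 0, 0], KernelParams())
        rng = np.random.default_rng(1)
        once = enforce_phase_labels(T, st_, rng)
        twice = enforce_phase_labels(T, once, rng)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestCovariance:
    def test_matches_bruteforce_double_loop(self, rng):
        state = random_consistent_state(rng, M=12, L=1)
        traj = state.trajectories[0]
        S = build_trajectory_covariance(state.T, traj)
        brute = np.empty((12, 12))
        for i in range(12):
            for j in range(12):
                brute[i, j] = bifurcation_kernel(
                    state.T[i], state.T[j], traj.labels[i], traj.labels[j],
                    traj.b, traj.kernel)
        np.testing.assert_allclose(S, brute, atol=1e-12)
        np.testing.assert_allclose(S, S.T, atol=1e-14)

    def test_no_branching_reduces_to_plain_gp(self, rng):
        T = rng.random(8)
        p = KernelParams(1.2, 2.0, 0.7, 0.2, 2)
        traj = BifurcationState(1.1, np.zeros(8, dtype=int), p)
        S = build_trajectory_covariance(T, traj)
        plain = rbf_kernel(T[:, None], T[None, :], p) \
            + poly_kernel(T[:, None], T[None, :], p)
        np.testing.assert_allclose(S, plain, atol=1e-12)

    def test_total_covariance_props(self, rng):
        state = random_consistent_state(rng, M=10, L=3)
        S = total_covariance(state.T, state.trajectories, state.sigma_S)
        assert np.all(np.diag(S) >= state.sigma_S ** 2)
        perm = [state.trajectories[i] for i in (2, 0, 1)]
        S2 = total_covariance(state.T, perm, state.sigma_S)
        np.testing.assert_allclose(S, S2, atol=1e-12)

    def test_single_trajectory_total(self, rng):
        state = random_consistent_state(rng, M=6, L=1)
        S = total_covariance(state.T, state.trajectories, state.sigma_S,
                             repair=False)
        s1 = build_trajectory_covariance(state.T, state.trajectories[0])
        np.testing.assert_allclose(
            S, s1 + state.sigma_S ** 2 * np.eye(6), atol=1e-12)


class TestPsdRepair:
    def test_pd_matrix_unchanged(self, rng):
        A = rng.normal(size=(5, 5))
        S = A @ A.T + 5 * np.eye(5)
        out = nearest_psd_repair(S)
        assert out is S

    def test_zero_matrix_first_jitter(self):
        out = nearest_psd_repair(np.zeros((3, 3)), jitter_start=1e-8)
        np.testing.assert_allclose(out, 1e-8 * np.eye(3), atol=1e-20)

    def test_duplicate_pseudotimes_repairable(self):
        T = np.array([0.3, 0.3, 0.3, 0.8, 0.8])
        p = KernelParams(1.0, 2.0, 0.5, 0.1, 2)
        traj = BifurcationState(1.0, np.zeros(5, dtype=int), p)
        S = build_trajectory_covariance(T, traj)  # rank-deficient Gram
        np.linalg.cholesky(nearest_psd_repair(S))


class TestMarginalLikelihood:
    def test_univariate_closed_form(self):
        # one landmark at t=0, linear poly kernel contributes 0, rbf 1,
        # noise 1: total variance 2; y = 1
        p = KernelParams(1.0, 1.0, 1.0, 0.0, 1)
        traj = BifurcationState(0.5, np.array([0]), p)
        ll = log_marginal_likelihood(np.array([[1.0]]), np.array([0.0]),
                                     [traj], 1.0)
        assert ll == pytest.approx(-0.5 * np.log(4 * np.pi) - 0.25,
                                   abs=1e-12)

    def test_identical_columns_factorize(self, rng):
        state = random_consistent_state(rng, M=7, L=1)
        y = rng.normal(size=7)
        one = log_marginal_likelihood(y[:, None], state.T,
                                      state.trajectories, state.sigma_S)
        three = log_marginal_likelihood(np.tile(y[:, None], (1, 3)),
                                        state.T, state.trajectories,
                                        state.sigma_S)
        assert three == pytest.approx(3 * one, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(3, 15))
        L = int(rng.integers(1, 4))
        state = random_consistent_state(rng, M=M, L=L)
        Y = rng.normal(size=(M, L))
        S = total_covariance(state.T, state.trajectories, state.sigma_S)
        oracle = sum(
            scipy.stats.multivariate_normal(np.zeros(M), S).logpdf(Y[:, l])
            for l in range(L))
        ll = log_marginal_likelihood(Y, state.T, state.trajectories,
                                     state.sigma_S)
        assert ll == pytest.approx(oracle, abs=1e-8)

    def test_branch_swap_invariance(self, rng):
        state = random_consistent_state(rng, M=10, L=2)
        Y = rng.normal(size=(10, 2))
        ll = log_marginal_likelihood(Y, state.T, state.trajectories,
                                     state.sigma_S)
        swapped = state.copy()
        lab = swapped.trajectories[0].labels
        lab[lab != 0] = 3 - lab[lab != 0]
        ll2 = log_marginal_likelihood(Y, swapped.T, swapped.trajectories,
                                      swapped.sigma_S)
        assert ll == pytest.approx(ll2, rel=1e-12)

    def test_large_noise_iid_limit(self, rng):
        state = random_consistent_state(rng, M=8, L=1)
        Y = rng.normal(size=(8, 1))
        sig = 1e6
        ll = log_marginal_likelihood(Y, state.T, state.trajectories, sig)
        iid = -8 / 2 * np.log(2 * np.pi * sig ** 2) \
            - float((Y ** 2).sum()) / (2 * sig ** 2)
        assert ll == pytest.approx(iid, rel=1e-6)

    def test_fast_path_matches_reference(self, rng):
        for _ in range(10):
            M = int(rng.integers(2, 20))
            L = int(rng.integers(1, 4))
            state = random_consistent_state(rng, M=M, L=L)
            Y = np.ascontiguousarray(rng.normal(size=(M, L)))
            B = np.array([t.b for t in state.trajectories])
            C = np.vstack([t.labels for t in state.trajectories])
            P = np.vstack([t.kernel.as_array()
                           for t in state.trajectories])
            ref = log_marginal_likelihood(Y, state.T, state.trajectories,
                                          state.sigma_S)
            fast = log_marginal_arrays(Y, state.T, B, C, P, state.sigma_S)
            assert fast == pytest.approx(ref, abs=1e-8)

    def test_derive_labels_consistency(self, rng):
        T = rng.random(20)
        aux = rng.integers(1, 3, size=20).astype(np.int64)
        lab = derive_labels(T, 0.4, aux)
        assert np.all((lab == 0) == (T < 0.4))
        assert np.all(np.isin(lab[T >= 0.4], (1, 2)))


class TestLogPosterior:
    def test_out_of_support_pseudotime(self, rng):
        state = random_consistent_state(rng, M=5, L=1)
        state.T[0] = 1.5
        state.trajectories[0].labels[0] = \
            0 if state.T[0] < state.trajectories[0].b else 1
        Y = rng.normal(size=(5, 1))
        assert log_posterior(Y, state, PriorConfig()) == -np.inf

    def test_sigma_difference_decomposes(self, rng):
        state = random_consistent_state(rng, M=6, L=1)
        Y = rng.normal(size=(6, 1))
        pri = PriorConfig()
        other = state.copy()
        other.sigma_S = state.sigma_S * 1.5
        dpost = log_posterior(Y, other, pri) - log_posterior(Y, state, pri)
        dlik = (log_marginal_likelihood(Y, other.T, other.trajectories,
                                        other.sigma_S)
                - log_marginal_likelihood(Y, state.T, state.trajectories,
                                          state.sigma_S))
        dprior = (-0.5 * other.sigma_S ** 2) - (-0.5 * state.sigma_S ** 2)
        assert dpost == pytest.approx(dlik + dprior, abs=1e-10)

    def test_prior_finite_for_valid_state(self, rng):
        state = random_consistent_state(rng, M=5, L=2)
        assert np.isfinite(log_prior(state, PriorConfig()))
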