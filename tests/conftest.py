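import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fatefactor.bifurcation import BifurcationState, KernelParams, ModelState
from fatefactor.io import ExpressionMatrix

settings.register_profile(
    "suite", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr(rng):
    """30 cells x 8 genes, smooth gradient plus noise."""
    t = np.linspace(0, 1, 30)
    base = np.outer(t, rng.normal(size=8))
    X = base + rng.normal(scale=0.1, size=(30, 8))
    return ExpressionMatrix(X, [f"c{i}" for i in range(30)],
                            [f"g{j}" for j in range(8)])


@pytest.fixture
def blob_expr(rng):
    """Two well-separated 20-cell Gaussian blobs in 5 genes."""
    a = rng.normal(loc=0.0, scale=0.3, size=(20, 5))
    b = rng.normal(loc=8.0, scale=0.3, size=(20, 5))
    X = np.vstack([a, b])
    labels = np.array([0] * 20 + [1] * 20)
    expr = ExpressionMatrix(X, [f"c{i}" for i in range(40)],
                            [f"g{j}" for j in range(5)])
    return expr, labels


def random_consistent_state(rng, M=10, L=2, d_pl=2):
    """A random ModelState satisfying the phase-label constraint."""
    T = rng.random(M)
    trajs = []
    for _ in range(L):
        b = rng.random()
        labels = np.where(T < b, 0, rng.integers(1, 3, size=M)).astype(int)
        kp = KernelParams(lambda_rbf=float(rng.uniform(0.2, 2.0)),
                          alpha_rbf=float(rng.uniform(0.5, 5.0)),
                          lambda_pl=float(rng.uniform(0.1, 1.5)),
                          c_pl=float(rng.uniform(-0.3, 0.5)),
                          d_pl=d_pl)
        trajs.append(BifurcationState(b, labels, kp))
    return ModelState(T, trajs, sigma_S=float(rng.uniform(0.2, 1.0)))
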