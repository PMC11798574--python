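"""Factorization of single-cell trajectories into independent bifurcating
Gaussian processes over pseudotime, with consensus-tree assembly and
trajectory-comparison metrics."""

from .bifurcation import (BifurcationState, KernelParams, ModelState,
                          bifurcation_kernel, build_trajectory_covariance,
                          log_marginal_likelihood, total_covariance)
from .config import MCMCConfig, PriorConfig, RunConfig
from .downsample import LandmarkSet, landmark_downsample
from .embed import Embedding, pca_embed
from .io import ExpressionMatrix, read_expression
from .mcmc import MCMCChain, posterior_summary, run_mcmc

__version__ = "0.1.0"

__all__ = [
    "BifurcationState", "KernelParams", "ModelState", "bifurcation_kernel",
    "build_trajectory_covariance", "log_marginal_likelihood",
    "total_covariance", "MCMCConfig", "PriorConfig", "RunConfig",
    "LandmarkSet", "landmark_downsample", "Embedding", "pca_embed",
    "ExpressionMatrix", "read_expression", "MCMCChain", "posterior_summary",
    "run_mcmc", "TrajectoryModel", "TrajectoryResults",
]


def __getattr__(name):
    # lazy: model facade pulls in the full pipeline
    if name in ("TrajectoryModel", "TrajectoryResults"):
        from . import model
        return getattr(model, name)
    raise AttributeError(name)
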