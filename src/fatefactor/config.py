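"""Run-time configuration for the trajectory-factorization pipeline.

All randomness in the pipeline flows from a single user-supplied seed,
which is split deterministically per stage with :func:`split_seed`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Optional, Union

import numpy as np

__all__ = ["MCMCConfig", "PriorConfig", "RunConfig", "split_seed"]

# stage names hashed into per-module child seeds
_STAGES = ("downsample", "mcmc", "rotation", "simulate", "metrics")


def split_seed(seed: int, stage: str) -> int:
    """Derive a deterministic child seed (< 2**31) for a pipeline stage."""
    key = zlib.crc32(stage.encode("utf-8"))
    ss = np.random.SeedSequence(int(seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class MCMCConfig:
    """Sampler settings.

    ``iterations`` counts full sweeps (pseudotime block, bifurcation times,
    branch labels, kernel hyperparameters); ``burn_in`` sweeps are discarded
    and the remainder thinned by ``thinning``.
    """

    iterations: int = 5000
    burn_in: int = 2500
    thinning: int = 5
    seed: int = 0
    proposal_scale: float = 0.1
    adapt_interval: int = 50
    target_acceptance: float = 0.44
    slice_width: float = 0.5
    slice_max_steps: int = 50

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be < iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PriorConfig:
    """Weakly-informative priors.

    Pseudotime and bifurcation times are uniform on [0, 1]; post-branch
    labels uniform on {1, 2}; log kernel amplitudes/length-scales and the
    polynomial offset are standard normal; noise scales are half-normal.
    """

    t_uniform: bool = True
    log_lambda_rbf_sd: float = 1.0
    log_alpha_rbf_sd: float = 1.0
    log_lambda_pl_sd: float = 1.0
    c_pl_sd: float = 1.0
    sigma_s_scale: float = 1.0
    sigma_error_scale: float = 1.0


@dataclass
class RunConfig:
    """Top-level pipeline configuration.

    Parameters
    ----------
    L : int
        Number of independent bifurcating trajectories (and principal
        components retained); default 3.
    M : int or "auto"
        Landmark (metacell) count.  "auto" scales with sqrt(n_cells) and is
        refined by a penalized within-cluster-sum-of-squares criterion.
    hwg_threshold : float
        Absolute gene-weight cutoff for highly weighted genes.
    poly_degree : int
        Degree of the polynomial kernel component.
    """

    L: int = 3
    M: Union[int, str] = "auto"
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: PriorConfig = field(default_factory=PriorConfig)
    hwg_threshold: float = 0.05
    poly_degree: int = 2
    orientation_anchor: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be a positive integer")
        if self.hwg_threshold <= 0:
            raise ValueError("hwg_threshold must be > 0")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")
        if isinstance(self.mcmc, dict):
            self.mcmc = MCMCConfig(**self.mcmc)
        if isinstance(self.priors, dict):
            self.priors = PriorConfig(**self.priors)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)
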