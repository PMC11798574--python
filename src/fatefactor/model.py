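"""Model/Results facade over the full pipeline.

`TrajectoryModel` is constructed from an expression matrix (or DataFrame)
plus a :class:`~fatefactor.config.RunConfig`; ``fit()`` runs landmark
downsampling, PCA embedding, MCMC inference, factor rotation and
consensus-tree assembly, returning a :class:`TrajectoryResults` that
carries the estimates, diagnostics and output writers.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .bifurcation import ModelState
from .config import RunConfig, split_seed
from .consensus import ConsensusTree, assign_cells_to_tree, merge_consensus
from .downsample import (LandmarkSet, auto_landmark_count,
                         map_landmarks_to_cells, landmark_downsample)
from .embed import Embedding, pca_embed
from .factorize import FactorResult, factorize
from .io import ExpressionMatrix, write_fit
from .mcmc import MCMCChain, posterior_summary, run_mcmc
from .metrics import TrajectoryGraph, trajectory_from_tree

__all__ = ["TrajectoryModel", "TrajectoryResults"]


class TrajectoryModel:
    """Mixture-of-bifurcating-Gaussian-processes trajectory model.

    Parameters
    ----------
    expr : ExpressionMatrix
        Preprocessed (log-normalized) cells x genes matrix.
    config : RunConfig, optional
        Trajectory count L, landmark count M, MCMC settings, seed.
    """

    def __init__(self, expr: ExpressionMatrix,
                 config: Optional[RunConfig] = None):
        self.expr = expr
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       config: Optional[RunConfig] = None
                       ) -> "TrajectoryModel":
        """Build from a cells x genes DataFrame (index = cell ids)."""
        return cls(ExpressionMatrix.from_frame(df), config)

    def fit(self, verbose: bool = False) -> "TrajectoryResults":
        cfg = self.config
        seed = cfg.seed

        m = cfg.M
        if m == "auto":
            m = auto_landmark_count(self.expr, seed=split_seed(seed,
                                                               "downsample"))
        landmarks = landmark_downsample(
            self.expr, int(m), seed=split_seed(seed, "downsample"))
        embedding = pca_embed(landmarks, cfg.L)

        # standardize scores so the weakly-informative priors on kernel
        # amplitudes and noise apply regardless of expression scale;
        # gene weights (U = V R) are unaffected
        scale = float(np.sqrt(np.mean(embedding.scores ** 2)))
        scale = scale if scale > 0 else 1.0
        scores = embedding.scores / scale

        mcmc_cfg = replace(cfg.mcmc, seed=split_seed(seed, "mcmc"))
        run_cfg = replace(cfg, mcmc=mcmc_cfg)
        chain = run_mcmc(scores, run_cfg)
        estimate = posterior_summary(chain)

        factors = factorize(scores, embedding, estimate,
                            gene_ids=self.expr.gene_ids,
                            hwg_threshold=cfg.hwg_threshold,
                            seed=split_seed(seed, "rotation"))
        tree = merge_consensus(estimate)
        res = TrajectoryResults(self, landmarks, embedding, chain,
                                estimate, factors, tree)
        res.score_scale = scale
        # pseudotime direction is fixed at initialization (rank of PC1);
        # an anchor only reports whether the sampled orientation agrees
        if cfg.orientation_anchor is not None:
            if cfg.orientation_anchor not in self.expr.cell_ids:
                raise ValueError(
                    f"orientation_anchor {cfg.orientation_anchor!r} is not "
                    "a cell id")
            idx = self.expr.cell_ids.index(cfg.orientation_anchor)
            anchor_t = float(estimate.T[landmarks.assignment[idx]])
            res.anchor_is_early = anchor_t <= float(np.median(estimate.T))
        return res


class TrajectoryResults:
    """Fitted trajectory factorization.

    Attributes
    ----------
    estimate : ModelState
        Posterior point estimate (pseudotime, bifurcation times, branch
        labels, kernel hyperparameters).
    factors : FactorResult
        Rotation, factor scores, gene weights and highly weighted genes.
    tree : ConsensusTree
        Merged consensus trajectory.
    """

    def __init__(self, model: TrajectoryModel, landmarks: LandmarkSet,
                 embedding: Embedding, chain: MCMCChain,
                 estimate: ModelState, factors: FactorResult,
                 tree: ConsensusTree):
        self.model = model
        self.landmarks = landmarks
        self.embedding = embedding
        self.chain = chain
        self.estimate = estimate
        self.factors = factors
        self.tree = tree

    # -- per-cell views ----------------------------------------------------

    @property
    def cell_pseudotime(self) -> np.ndarray:
        return map_landmarks_to_cells(self.landmarks, self.estimate.T)

    def cell_branch_labels(self, trajectory: int) -> np.ndarray:
        labels = self.estimate.trajectories[trajectory].labels
        return map_landmarks_to_cells(self.landmarks, labels)

    @property
    def cell_segments(self) -> Sequence[str]:
        segs, _ = assign_cells_to_tree(self.tree, self.landmarks)
        return segs

    def to_trajectory_graph(self) -> TrajectoryGraph:
        """Milestone-graph view of the fit (for metric comparison)."""
        importance = dict(zip(self.factors.gene_ids,
                              np.abs(self.factors.U).max(axis=1)))
        return trajectory_from_tree(self.tree, self.landmarks,
                                    feature_importance=importance)

    def save(self, outdir: str) -> Sequence[str]:
        """Write all fit artifacts; see :func:`fatefactor.io.write_fit`."""
        import json
        import os

        from .metrics import trajectory_to_dict

        written = list(write_fit(outdir, self.landmarks, self.estimate,
                                 self.factors, self.tree))
        path = os.path.join(outdir, "trajectory.json")
        with open(path, "w") as fh:
            json.dump(trajectory_to_dict(self.to_trajectory_graph()), fh,
                      indent=1)
        written.append(path)
        return written

    # -- summaries ---------------------------------------------------------

    def summary(self) -> str:
        est = self.estimate
        cfg = self.model.config
        lines = [
            "Trajectory factorization results",
            "=" * 40,
            f"cells: {self.model.expr.n_cells}   genes: "
            f"{self.model.expr.n_genes}   landmarks: {self.landmarks.M}",
            f"trajectories (L): {est.L}   MCMC samples kept: "
            f"{len(self.chain.samples)}",
            f"observation noise sigma_S: {est.sigma_S:.4f}   "
            f"rotation error sigma: {self.factors.sigma_error:.4f}",
            "",
            "trajectory  bifurcation_time  branch1/branch2/pre  n_HWG",
        ]
        for l, st in enumerate(est.trajectories):
            n1 = int(np.sum(st.labels == 1))
            n2 = int(np.sum(st.labels == 2))
            n0 = int(np.sum(st.labels == 0))
            lines.append(f"{l + 1:>10d}  {st.b:>16.3f}  "
                         f"{n1:>7d}/{n2}/{n0:<9} {len(self.factors.hwg[l]):>5d}")
        lines.append("")
        lines.append(f"consensus tree: {len(self.tree.split_times)} "
                     f"branching point(s), "
                     f"{len(self.tree.terminal_segments)} terminal segment(s)")
        mean_acc = float(np.mean(self.chain.acceptance_counts)
                         / max(len(self.chain.log_post_trace), 1))
        lines.append(f"mean pseudotime acceptance rate: {mean_acc:.2f}")
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Scatter of the first two factor-score columns colored by
        consensus segment (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        W = self.factors.W
        segs = np.asarray(self.tree.landmark_segment)
        for seg in sorted(set(segs)):
            mask = segs == seg
            y = W[mask, 1] if W.shape[1] > 1 else self.estimate.T[mask]
            ax.scatter(W[mask, 0], y, label=seg, s=18)
        ax.set_xlabel("factor score 1")
        ax.set_ylabel("factor score 2" if W.shape[1] > 1 else "pseudotime")
        ax.legend(title="segment", fontsize=8)
        return ax
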