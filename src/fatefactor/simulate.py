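"""Synthetic data generation with full ground truth.

Two generators:

* :func:`simulate_from_model` draws from the model's own generative
  process (landmark pseudotimes, bifurcation times, branch labels, summed
  bifurcation-kernel covariance, loading matrix, noise) — used for
  parameter-recovery tests.
* :func:`simulate_toy_trajectory` places cells on a declared topology
  (linear / one bifurcation / two bifurcations) with branch-specific
  expression shifts — used for metric tests and end-to-end smoke runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from ._fast import derive_labels
from .bifurcation import (BifurcationState, KernelParams, ModelState,
                          total_covariance)
from .io import ExpressionMatrix

__all__ = ["TrajectoryDataset", "simulate_from_model",
           "simulate_toy_trajectory", "DEFAULT_GENERATOR"]

# default generative regime: desk-scale and recoverable
DEFAULT_GENERATOR = dict(
    m_landmarks=60, cells_per_landmark=10, n_genes=200, L=2,
    b_values=(0.4, 0.7), lambda_rbf=1.0, alpha_rbf=2.0, lambda_pl=0.5,
    c_pl=0.1, d_pl=2, sigma_S=0.3, gene_noise_sd=0.2,
)


@dataclass
class TrajectoryDataset:
    """Synthetic expression data plus the generating ground truth."""

    expr: ExpressionMatrix
    landmark_expr: np.ndarray
    T_landmark: np.ndarray
    T_cell: np.ndarray
    b_true: np.ndarray
    c_true: np.ndarray  # (L, M) labels
    scores_true: np.ndarray  # (M, L) latent score columns
    V_true: np.ndarray  # (N, L) loadings
    landmark_of_cell: np.ndarray
    sigma_S: float
    gene_noise_sd: float
    seed: int
    params: dict = field(default_factory=dict)


def _structured_loadings(n_genes: int, L: int, rng: np.random.Generator,
                         loaded_genes: Optional[int] = None) -> np.ndarray:
    """Orthonormal N x L loading matrix.

    With ``loaded_genes`` set, column 1 is supported on the first
    ``loaded_genes`` genes only (equal magnitudes, random signs) and the
    remaining columns on the rest — the planted-module regime used for
    gene-weight recovery checks.
    """
    if loaded_genes is None:
        A = rng.normal(size=(n_genes, L))
        Q, _ = np.linalg.qr(A)
        # deterministic sign convention
        for j in range(L):
            k = int(np.argmax(np.abs(Q[:, j])))
            if Q[k, j] < 0:
                Q[:, j] = -Q[:, j]
        return Q
    V = np.zeros((n_genes, L))
    signs = rng.choice([-1.0, 1.0], size=loaded_genes)
    V[:loaded_genes, 0] = signs / np.sqrt(loaded_genes)
    rest = n_genes - loaded_genes
    A = rng.normal(size=(rest, L - 1)) if L > 1 else np.zeros((rest, 0))
    if L > 1:
        Q, _ = np.linalg.qr(A)
        V[loaded_genes:, 1:] = Q
    return V


def simulate_from_model(m_landmarks: int = 60, cells_per_landmark: int = 10,
                        n_genes: int = 200, L: int = 2,
                        kernel_params: Optional[Sequence[KernelParams]] = None,
                        b_values: Sequence[float] = (0.4, 0.7),
                        sigma_S: float = 0.3, gene_noise_sd: float = 0.2,
                        seed: int = 0, factor_scores: bool = False,
                        loaded_genes: Optional[int] = None
                        ) -> TrajectoryDataset:
    """Forward-simulate the bifurcating-GP mixture.

    Landmark pseudotimes are sorted Uniform(0, 1) draws; labels follow the
    phase constraint with uniform branch choice; score columns are drawn
    from the zero-mean multivariate normal with the summed covariance
    (or, with ``factor_scores=True``, column l from its own trajectory
    covariance plus noise — the generative counterpart of the factor
    model, under which the rotation is identifiable); genes are produced
    by an orthonormal loading matrix plus iid Gaussian noise, and each
    landmark is replicated ``cells_per_landmark`` times with additional
    iid noise.
    """
    if len(b_values) != L:
        raise ValueError("b_values must have length L")
    rng = np.random.default_rng(seed)
    M, N = m_landmarks, n_genes
    if kernel_params is None:
        kernel_params = [KernelParams(DEFAULT_GENERATOR["lambda_rbf"],
                                      DEFAULT_GENERATOR["alpha_rbf"],
                                      DEFAULT_GENERATOR["lambda_pl"],
                                      DEFAULT_GENERATOR["c_pl"],
                                      DEFAULT_GENERATOR["d_pl"])
                         for _ in range(L)]

    T = np.sort(rng.random(M))
    trajs = []
    for l in range(L):
        aux = rng.integers(1, 3, size=M).astype(np.int64)
        labels = derive_labels(T, float(b_values[l]), aux)
        trajs.append(BifurcationState(float(b_values[l]), labels,
                                      kernel_params[l]))

    if factor_scores:
        cols = []
        for l in range(L):
            S_l = total_covariance(T, [trajs[l]], sigma_S, repair=True)
            Lc = np.linalg.cholesky(S_l)
            cols.append(Lc @ rng.normal(size=M))
        scores = np.column_stack(cols)
    else:
        S = total_covariance(T, trajs, sigma_S, repair=True)
        Lc = np.linalg.cholesky(S)
        scores = Lc @ rng.normal(size=(M, L))

    V = _structured_loadings(N, L, rng, loaded_genes=loaded_genes)
    Y_landmark = scores @ V.T + rng.normal(scale=gene_noise_sd, size=(M, N)) \
        if gene_noise_sd > 0 else scores @ V.T

    n_cells = M * cells_per_landmark
    landmark_of_cell = np.repeat(np.arange(M), cells_per_landmark)
    cells = Y_landmark[landmark_of_cell]
    if gene_noise_sd > 0 and cells_per_landmark > 1:
        cells = cells + rng.normal(scale=gene_noise_sd, size=cells.shape)
    cell_ids = [f"cell_{i + 1}" for i in range(n_cells)]
    gene_ids = [f"gene_{j + 1}" for j in range(N)]
    expr = ExpressionMatrix(cells, cell_ids, gene_ids)

    return TrajectoryDataset(
        expr=expr, landmark_expr=Y_landmark, T_landmark=T,
        T_cell=T[landmark_of_cell], b_true=np.asarray(b_values, dtype=float),
        c_true=np.vstack([st.labels for st in trajs]), scores_true=scores,
        V_true=V, landmark_of_cell=landmark_of_cell, sigma_S=sigma_S,
        gene_noise_sd=gene_noise_sd, seed=seed,
        params=dict(m_landmarks=M, cells_per_landmark=cells_per_landmark,
                    n_genes=N, L=L, factor_scores=factor_scores,
                    loaded_genes=loaded_genes))


def truth_model_state(data: TrajectoryDataset) -> ModelState:
    """Package the simulation ground truth as a :class:`ModelState`."""
    trajs = [BifurcationState(float(data.b_true[l]), data.c_true[l],
                              KernelParams())
             for l in range(data.b_true.shape[0])]
    return ModelState(data.T_landmark.copy(), trajs, data.sigma_S)


# ---------------------------------------------------------------------------
# toy labeled trajectories for metric tests


def simulate_toy_trajectory(topology: str, n_cells: int, seed: int = 0,
                            n_genes: int = 50, noise_sd: float = 0.5):
    """Cells on a declared topology with recoverable expression structure.

    Returns ``(TrajectoryGraph, ExpressionMatrix, truth_dict)``; branch
    means are shifted by twice the noise standard deviation so the
    topology is recoverable from expression.
    """
    from .metrics import TrajectoryGraph

    if n_cells < 10:
        raise ValueError("n_cells must be >= 10")
    rng = np.random.default_rng(seed)

    if topology == "linear":
        edges = [("root", "tipA", 1.0)]
    elif topology == "bifurcation":
        edges = [("root", "split1", 0.5), ("split1", "tipA", 0.5),
                 ("split1", "tipB", 0.5)]
    elif topology == "two_bifurcations":
        edges = [("root", "split1", 0.4), ("split1", "tipA", 0.6),
                 ("split1", "split2", 0.3), ("split2", "tipB", 0.3),
                 ("split2", "tipC", 0.3)]
    else:
        raise ValueError(f"unknown topology {topology!r}")

    G = nx.Graph()
    for u, v, w in edges:
        G.add_edge(u, v, length=w)

    # root-to-tip paths define branches; each cell: uniform arc position
    tips = [n for n in G.nodes if n.startswith("tip")]
    cell_ids = [f"cell_{i + 1}" for i in range(n_cells)]
    placement: Dict[str, Tuple[Tuple[str, str], float]] = {}
    branch_of: Dict[str, str] = {}
    pseudo: Dict[str, float] = {}
    depth = nx.single_source_dijkstra_path_length(G, "root", weight="length")
    max_depth = max(depth.values())
    for cid in cell_ids:
        tip = tips[rng.integers(len(tips))]
        path = nx.shortest_path(G, "root", tip)
        t = rng.random() * depth[tip]
        # walk the path to find the hosting edge
        acc = 0.0
        for u, v in zip(path[:-1], path[1:]):
            w = G[u][v]["length"]
            if t <= acc + w or (u, v) == (path[-2], path[-1]):
                placement[cid] = ((u, v), min(max((t - acc) / w, 0.0), 1.0))
                break
            acc += w
        # branch label = hosting edge (unambiguous branch identity)
        branch_of[cid] = "-".join(placement[cid][0])
        pseudo[cid] = t

    # expression: gene means drift with pseudotime; branch-specific offsets
    gene_ids = [f"gene_{j + 1}" for j in range(n_genes)]
    branches = sorted(set(branch_of.values()))
    shift = 2.0 * noise_sd
    offsets = {br: rng.normal(scale=shift, size=n_genes) for br in branches}
    slope = rng.normal(scale=1.0, size=n_genes)
    X = np.empty((n_cells, n_genes))
    for i, cid in enumerate(cell_ids):
        X[i] = slope * (pseudo[cid] / max_depth) + offsets[branch_of[cid]] \
            + rng.normal(scale=noise_sd, size=n_genes)
    expr = ExpressionMatrix(X, cell_ids, gene_ids)

    importance = np.abs(slope)
    traj = TrajectoryGraph(
        milestone_graph=G,
        cell_placement=placement,
        branch_assignment=branch_of,
        feature_importance=dict(zip(gene_ids, importance)),
    )
    truth = dict(pseudotime=pseudo, branch_of=branch_of, seed=seed)
    return traj, expr, truth
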