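"""Trajectory-comparison metrics.

Four similarity scores in [0, 1] between a reference and a predicted
trajectory, plus their geometric mean:

* ``him_score`` — 1 minus the HIM graph distance, combining the normalized
  Hamming distance between length-weighted adjacency matrices with the
  Ipsen-Mikhailov Laplacian-spectral distance (Lorentzian width calibrated
  per graph size so the empty/complete distance is 1).
* ``f1_branches`` — harmonic mean of branch Recovery and Relevance, each a
  mean best-Jaccard between branch cell-sets.
* ``cor_dist`` — Spearman correlation of geodesic cell-cell distances from
  sampled waypoints, mapped to [0, 1].
* ``wcor_features`` — weighted Pearson correlation of per-gene importance
  vectors, mapped to [0, 1].

Undefined components (e.g. missing importances) are excluded from the
geometric mean rather than imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import scipy.optimize
from scipy.stats import spearmanr

__all__ = ["TrajectoryGraph", "MetricReport", "him_score", "f1_branches",
           "cor_dist", "wcor_features", "overall_score",
           "compare_trajectories", "trajectory_from_tree"]


@dataclass
class TrajectoryGraph:
    """A milestone graph with per-cell placements and branch labels.

    ``cell_placement`` maps cell id -> ((milestone_u, milestone_v),
    fractional position in [0, 1] along that edge); ``branch_assignment``
    maps cell id -> branch label; ``feature_importance`` (optional) maps
    gene id -> nonnegative importance.
    """

    milestone_graph: nx.Graph
    cell_placement: Dict[str, Tuple[Tuple[str, str], float]]
    branch_assignment: Dict[str, str]
    feature_importance: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        for cid, (edge, frac) in self.cell_placement.items():
            if not self.milestone_graph.has_edge(*edge):
                raise ValueError(f"cell {cid} placed on missing edge {edge}")
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"cell {cid} fractional position {frac}")


@dataclass
class MetricReport:
    him: float
    f1_branches: float
    cordist: float
    wcorfeatures: Optional[float]
    overall: float

    def to_dict(self) -> dict:
        return dict(him=self.him, f1_branches=self.f1_branches,
                    cordist=self.cordist, wcorfeatures=self.wcorfeatures,
                    overall=self.overall)


# ---------------------------------------------------------------------------
# HIM


def _weighted_adjacency(G: nx.Graph, nodes: Sequence[str]) -> np.ndarray:
    idx = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, data in G.edges(data=True):
        w = float(data.get("length", 1.0))
        A[idx[u], idx[v]] = A[idx[v], idx[u]] = w
    return A


def _lorentzian_density(omegas: np.ndarray, gamma: float,
                        grid: np.ndarray) -> np.ndarray:
    dens = np.zeros_like(grid)
    for w in omegas:
        dens += gamma / ((grid - w) ** 2 + gamma ** 2)
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def _im_distance(A1: np.ndarray, A2: np.ndarray, gamma: float) -> float:
    def omegas(A):
        Lap = np.diag(A.sum(axis=1)) - A
        w = np.linalg.eigvalsh(Lap)
        w = np.clip(w, 0.0, None)
        return np.sqrt(w[1:])  # drop one zero mode

    w1, w2 = omegas(A1), omegas(A2)
    top = max(w1.max(initial=0.0), w2.max(initial=0.0))
    grid = np.linspace(0.0, top + 20.0 * gamma, 3000)
    rho1 = _lorentzian_density(w1, gamma, grid)
    rho2 = _lorentzian_density(w2, gamma, grid)
    return float(np.sqrt(np.trapezoid((rho1 - rho2) ** 2, grid)))


@lru_cache(maxsize=64)
def _calibrated_gamma(n: int) -> float:
    """Lorentzian width making the empty-vs-complete IM distance 1."""
    empty = np.zeros((n, n))
    complete = np.ones((n, n)) - np.eye(n)

    def f(g):
        return _im_distance(empty, complete, g) - 1.0

    return float(scipy.optimize.brentq(f, 0.01, 5.0, xtol=1e-4))


def him_score(ref: TrajectoryGraph, pred: TrajectoryGraph) -> float:
    """1 - HIM distance on the union milestone set, HIM =
    sqrt((H^2 + IM^2) / 2)."""
    if ref.milestone_graph.number_of_nodes() == 0 \
            or pred.milestone_graph.number_of_nodes() == 0:
        raise ValueError("empty milestone graph")
    nodes = sorted(set(ref.milestone_graph.nodes)
                   | set(pred.milestone_graph.nodes))
    A1 = _weighted_adjacency(ref.milestone_graph, nodes)
    A2 = _weighted_adjacency(pred.milestone_graph, nodes)
    n = len(nodes)
    maxw = max(A1.max(initial=0.0), A2.max(initial=0.0))
    if maxw > 0:
        A1n, A2n = A1 / maxw, A2 / maxw
    else:
        A1n, A2n = A1, A2
    if n < 2:
        return 1.0
    H = float(np.sum(np.abs(A1n - A2n)) / (n * (n - 1)))
    gamma = _calibrated_gamma(n)
    IM = _im_distance(A1n, A2n, gamma)
    him = float(np.sqrt((H ** 2 + IM ** 2) / 2.0))
    return float(np.clip(1.0 - him, 0.0, 1.0))


# ---------------------------------------------------------------------------
# F1 branches


def _branch_sets(traj: TrajectoryGraph) -> List[set]:
    groups: Dict[str, set] = {}
    for cid, br in traj.branch_assignment.items():
        groups.setdefault(str(br), set()).add(cid)
    return list(groups.values())


def f1_branches(ref: TrajectoryGraph, pred: TrajectoryGraph) -> float:
    """Harmonic mean of branch Recovery and Relevance (mean best Jaccard
    over reference / predicted branches respectively)."""
    if set(ref.branch_assignment) != set(pred.branch_assignment):
        raise ValueError("branch metrics require the same cell set")
    rb, pb = _branch_sets(ref), _branch_sets(pred)

    def jac(a: set, b: set) -> float:
        return len(a & b) / len(a | b) if a | b else 0.0

    recovery = float(np.mean([max(jac(r, p) for p in pb) for r in rb]))
    relevance = float(np.mean([max(jac(p, r) for r in rb) for p in pb]))
    if recovery + relevance == 0:
        return 0.0
    return 2.0 * recovery * relevance / (recovery + relevance)


# ---------------------------------------------------------------------------
# cordist


def _geodesic_matrix(traj: TrajectoryGraph, waypoints: Sequence[str],
                     cells: Sequence[str]) -> np.ndarray:
    G = traj.milestone_graph
    sp = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))

    def ends(cid):
        (u, v), p = traj.cell_placement[cid]
        w = float(G[u][v].get("length", 1.0))
        return u, v, p * w, (1.0 - p) * w

    D = np.empty((len(waypoints), len(cells)))
    for i, a in enumerate(waypoints):
        ua, va, dau, dav = ends(a)
        for j, b in enumerate(cells):
            ub, vb, dbu, dbv = ends(b)
            best = min(dau + sp[ua][ub] + dbu, dau + sp[ua][vb] + dbv,
                       dav + sp[va][ub] + dbu, dav + sp[va][vb] + dbv)
            if {ua, va} == {ub, vb}:
                # same edge: direct along-edge distance may be shorter
                (u1, v1), p1 = traj.cell_placement[a]
                (u2, v2), p2 = traj.cell_placement[b]
                w = float(G[u1][v1].get("length", 1.0))
                if (u1, v1) != (u2, v2):
                    p2 = 1.0 - p2
                best = min(best, abs(p1 - p2) * w)
            D[i, j] = best
    return D


def cor_dist(ref: TrajectoryGraph, pred: TrajectoryGraph,
             n_waypoints: int = 100, seed: int = 0) -> float:
    """(Spearman correlation + 1) / 2 between waypoint-to-cell geodesic
    distances of the two trajectories."""
    cells = sorted(ref.cell_placement)
    if set(cells) != set(pred.cell_placement):
        raise ValueError("distance metrics require the same cell set")
    if len(cells) < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    k = min(n_waypoints, len(cells))
    waypoints = [cells[i] for i in rng.choice(len(cells), size=k,
                                              replace=False)]
    D1 = _geodesic_matrix(ref, waypoints, cells)
    D2 = _geodesic_matrix(pred, waypoints, cells)
    rho = spearmanr(D1.ravel(), D2.ravel()).statistic
    if not np.isfinite(rho):
        rho = 0.0
    return float(np.clip((rho + 1.0) / 2.0, 0.0, 1.0))


# ---------------------------------------------------------------------------
# wcorfeatures


def wcor_features(ref_importance: Sequence[float],
                  pred_importance: Sequence[float],
                  weights: Optional[Sequence[float]] = None
                  ) -> Optional[float]:
    """Weighted Pearson correlation mapped to [0, 1]; weights default to
    the reference importance normalized to sum 1.  Returns ``None`` when a
    vector has zero weighted variance (excluded from the overall score)."""
    x = np.asarray(ref_importance, dtype=float)
    y = np.asarray(pred_importance, dtype=float)
    if x.shape != y.shape:
        raise ValueError("importance vectors must have equal length")
    w = x.copy() if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    w = w / w.sum()
    mx, my = float(w @ x), float(w @ y)
    cov = float(w @ ((x - mx) * (y - my)))
    vx = float(w @ ((x - mx) ** 2))
    vy = float(w @ ((y - my) ** 2))
    if vx <= 0 or vy <= 0:
        return None
    r = cov / np.sqrt(vx * vy)
    return float(np.clip((r + 1.0) / 2.0, 0.0, 1.0))


def overall_score(components: Sequence[Optional[float]]) -> float:
    """Geometric mean over the defined components; 0 annihilates."""
    vals = [c for c in components if c is not None]
    if not vals:
        raise ValueError("at least one component must be defined")
    if any(v < 0 or v > 1 for v in vals):
        raise ValueError("components must lie in [0, 1]")
    if any(v == 0 for v in vals):
        return 0.0
    return float(np.exp(np.mean(np.log(vals))))


def compare_trajectories(ref: TrajectoryGraph, pred: TrajectoryGraph,
                         n_waypoints: int = 100, seed: int = 0
                         ) -> MetricReport:
    """All four metrics plus their geometric mean."""
    him = him_score(ref, pred)
    f1 = f1_branches(ref, pred)
    cd = cor_dist(ref, pred, n_waypoints=n_waypoints, seed=seed)
    wc: Optional[float] = None
    if ref.feature_importance is not None \
            and pred.feature_importance is not None:
        genes = sorted(set(ref.feature_importance)
                       & set(pred.feature_importance))
        if genes:
            wc = wcor_features([ref.feature_importance[g] for g in genes],
                               [pred.feature_importance[g] for g in genes])
    return MetricReport(him=him, f1_branches=f1, cordist=cd,
                        wcorfeatures=wc,
                        overall=overall_score([him, f1, cd, wc]))


def trajectory_to_dict(traj: TrajectoryGraph) -> dict:
    """JSON-serializable trajectory interchange form."""
    return dict(
        edges=[[u, v, float(d.get("length", 1.0))] for u, v, d in
               traj.milestone_graph.edges(data=True)],
        cell_placement={c: [list(e), float(p)] for c, (e, p) in
                        traj.cell_placement.items()},
        branch_of={c: str(b) for c, b in traj.branch_assignment.items()},
        feature_importance=None if traj.feature_importance is None else
        {g: float(v) for g, v in traj.feature_importance.items()},
    )


def trajectory_from_dict(d: Mapping) -> TrajectoryGraph:
    G = nx.Graph()
    for u, v, w in d["edges"]:
        G.add_edge(u, v, length=float(w))
    placement = {c: ((e[0], e[1]), float(p))
                 for c, (e, p) in d["cell_placement"].items()}
    imp = d.get("feature_importance")
    return TrajectoryGraph(
        milestone_graph=G, cell_placement=placement,
        branch_assignment={c: str(b) for c, b in d["branch_of"].items()},
        feature_importance=None if imp is None else dict(imp))


# ---------------------------------------------------------------------------
# building a TrajectoryGraph from a fitted consensus tree


def trajectory_from_tree(tree, landmarks, cell_ids: Optional[Sequence[str]]
                         = None,
                         feature_importance: Optional[Mapping[str, float]]
                         = None) -> TrajectoryGraph:
    """Milestone-graph view of a fitted consensus tree with cells placed
    on their landmark's terminal segment."""
    from .consensus import ConsensusTree, assign_cells_to_tree

    assert isinstance(tree, ConsensusTree)
    max_time = float(tree.landmark_time.max()) if tree.landmark_time.size \
        else 1.0
    G = nx.Graph()
    seg_edge: Dict[str, Tuple[str, str]] = {}
    seg_span: Dict[str, Tuple[float, float]] = {}
    for seg in tree.segments:
        start_node = "root" if seg == "0" else seg.split("-")[0]
        kids = tree.children.get(seg)
        if kids:
            end_node = kids[0].split("-")[0]
            end_t = float(tree.split_times[int(end_node)])
        else:
            end_node = f"tip_{seg}"
            member_t = [tree.landmark_time[i]
                        for i, s in enumerate(tree.landmark_segment)
                        if s == seg]
            end_t = max(member_t) if member_t else max_time
        start_t = tree.segment_start(seg)
        end_t = max(end_t, start_t)
        length = max(end_t - start_t, 1e-9)
        G.add_edge(start_node, end_node, length=length)
        seg_edge[seg] = (start_node, end_node)
        seg_span[seg] = (start_t, end_t)

    cell_segments, cell_times = assign_cells_to_tree(tree, landmarks)
    ids = list(landmarks.cell_ids) if cell_ids is None else list(cell_ids)
    placement, branches = {}, {}
    for cid, seg, t in zip(ids, cell_segments, cell_times):
        start_t, end_t = seg_span[seg]
        span = max(end_t - start_t, 1e-9)
        frac = float(np.clip((t - start_t) / span, 0.0, 1.0))
        placement[cid] = (seg_edge[seg], frac)
        branches[cid] = seg
    return TrajectoryGraph(milestone_graph=G, cell_placement=placement,
                           branch_assignment=branches,
                           feature_importance=dict(feature_importance)
                           if feature_importance is not None else None)
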