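"""Merging independent bifurcation processes into one consensus tree.

Trajectories are sorted by bifurcation time; the earliest defines the
initial split of the root segment "0" into branches "1-1"/"1-2", and each
subsequent trajectory adds its split to the existing segment holding the
majority of its post-branch landmarks.  Segments are labeled "n-m": the
m-th branch (m = 1 is the larger one) from branching point n.  The result
is a rooted binary tree with at most L branching points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .bifurcation import ModelState
from .downsample import LandmarkSet, map_landmarks_to_cells

__all__ = ["ConsensusTree", "sort_bifurcations", "merge_consensus",
           "assign_cells_to_tree", "export_newick", "tree_to_dict"]

logger = logging.getLogger(__name__)


@dataclass
class ConsensusTree:
    """Rooted binary diffusion tree over pseudotime.

    ``children`` maps a segment label to its two child segments (empty for
    terminal segments); ``split_times`` maps branching point number (as
    int) to the bifurcation time that created it; ``landmark_segment`` and
    ``landmark_time`` give per-landmark placement; ``trajectory_of_split``
    records which trajectory created each branching point.
    """

    children: Dict[str, List[str]]
    split_times: Dict[int, float]
    landmark_segment: List[str]
    landmark_time: np.ndarray
    trajectory_of_split: Dict[int, int]
    routing_conflicts: List[dict] = field(default_factory=list)

    @property
    def segments(self) -> List[str]:
        segs = set(self.children)
        for kids in self.children.values():
            segs.update(kids)
        return sorted(segs)

    @property
    def terminal_segments(self) -> List[str]:
        return [s for s in self.segments if not self.children.get(s)]

    def parent_of(self, segment: str) -> Optional[str]:
        for parent, kids in self.children.items():
            if segment in kids:
                return parent
        return None

    def segment_start(self, segment: str) -> float:
        """Pseudotime at which a segment begins (0 for the root segment)."""
        if segment == "0":
            return 0.0
        n = int(segment.split("-")[0])
        return float(self.split_times[n])


def sort_bifurcations(estimate: ModelState) -> List[int]:
    """Trajectory indices ordered by ascending bifurcation time; ties keep
    the original index order."""
    bs = [(st.b, l) for l, st in enumerate(estimate.trajectories)]
    return [l for _, l in sorted(bs, key=lambda t: (t[0], t[1]))]


def merge_consensus(estimate: ModelState) -> ConsensusTree:
    """Merge the trajectories of a point estimate into one binary tree.

    A trajectory with no post-branch landmarks contributes no split (a
    warning is logged).  Landmarks whose label disagrees with the majority
    segment of their trajectory keep their position and are recorded as
    routing conflicts.
    """
    estimate.check_consistent()
    T = np.asarray(estimate.T, dtype=float)
    M = T.shape[0]
    seg = np.array(["0"] * M, dtype=object)
    children: Dict[str, List[str]] = {"0": []}
    split_times: Dict[int, float] = {}
    traj_of_split: Dict[int, int] = {}
    conflicts: List[dict] = []
    # deterministic creation order of segments for tie-breaking
    creation_order: Dict[str, int] = {"0": 0}

    n_split = 0
    for l in sort_bifurcations(estimate):
        st = estimate.trajectories[l]
        post = np.where(st.labels != 0)[0]
        if post.size == 0:
            logger.warning("trajectory %d has no post-branch landmarks; "
                           "skipped in consensus", l + 1)
            continue
        n_split += 1
        # existing segment holding the majority of post-branch landmarks;
        # ties -> segment created earlier
        segs, counts = np.unique(seg[post], return_counts=True)
        best = sorted(zip(segs, counts),
                      key=lambda t: (-t[1], creation_order[t[0]]))[0][0]
        host = str(best)
        kid1, kid2 = f"{n_split}-1", f"{n_split}-2"
        children[host] = [kid1, kid2]
        children[kid1] = []
        children[kid2] = []
        creation_order[kid1] = len(creation_order)
        creation_order[kid2] = len(creation_order)
        split_times[n_split] = float(st.b)
        traj_of_split[n_split] = l

        # branch 1 = branch with more landmarks (among hosted ones)
        hosted = post[seg[post] == host]
        n1 = int(np.sum(st.labels[hosted] == 1))
        n2 = int(np.sum(st.labels[hosted] == 2))
        big, small = (1, 2) if n1 >= n2 else (2, 1)
        for x in hosted:
            seg[x] = kid1 if st.labels[x] == big else kid2
        # landmarks with this trajectory's post-branch label outside the
        # host segment: routed by their current segment, logged
        for x in post[seg[post] != host]:
            if seg[x] not in (kid1, kid2):
                conflicts.append(dict(landmark=int(x), trajectory=l + 1,
                                      label=int(st.labels[x]),
                                      segment=str(seg[x])))

    return ConsensusTree(children=children, split_times=split_times,
                         landmark_segment=[str(s) for s in seg],
                         landmark_time=T.copy(),
                         trajectory_of_split=traj_of_split,
                         routing_conflicts=conflicts)


def assign_cells_to_tree(tree: ConsensusTree, landmarks: LandmarkSet
                         ) -> Tuple[List[str], np.ndarray]:
    """Per-cell (terminal segment, pseudotime) inherited from the assigned
    landmark."""
    if len(tree.landmark_segment) != landmarks.M:
        raise ValueError("tree and landmark set have different M")
    segs = map_landmarks_to_cells(landmarks,
                                  np.asarray(tree.landmark_segment,
                                             dtype=object))
    times = map_landmarks_to_cells(landmarks, tree.landmark_time)
    return [str(s) for s in segs], np.asarray(times, dtype=float)


def _segment_extent(tree: ConsensusTree, segment: str,
                    max_time: float) -> float:
    start = tree.segment_start(segment)
    if tree.children.get(segment):
        n_child = int(tree.children[segment][0].split("-")[0])
        end = float(tree.split_times[n_child])
    else:
        member_t = [tree.landmark_time[i]
                    for i, s in enumerate(tree.landmark_segment)
                    if s == segment]
        end = max(member_t) if member_t else max_time
        end = max(end, start)
    return max(end - start, 0.0)


def export_newick(tree: ConsensusTree) -> str:
    """Rooted Newick string: leaves are terminal segments, internal nodes
    are branching points, branch lengths are pseudotime extents."""
    max_time = float(tree.landmark_time.max()) if tree.landmark_time.size \
        else 1.0

    def render(segment: str) -> str:
        length = _segment_extent(tree, segment, max_time)
        kids = tree.children.get(segment)
        if kids:
            inner = ",".join(render(k) for k in kids)
            label = kids[0].split("-")[0]
            return f"({inner}){label}:{length:.6g}"
        return f"{segment}:{length:.6g}"

    if not tree.children.get("0"):
        return f"({render('0')});"
    # root segment "0" carries the first branching point as its end node
    return render("0") + ";"


def tree_to_dict(tree: ConsensusTree) -> dict:
    """JSON-serializable full tree annotation."""
    return dict(
        children={k: list(v) for k, v in tree.children.items()},
        split_times={str(k): float(v) for k, v in tree.split_times.items()},
        trajectory_of_split={str(k): int(v) + 1
                             for k, v in tree.trajectory_of_split.items()},
        landmark_segment=list(tree.landmark_segment),
        landmark_time=[float(t) for t in tree.landmark_time],
        routing_conflicts=list(tree.routing_conflicts),
    )


def tree_from_dict(d: dict) -> ConsensusTree:
    return ConsensusTree(
        children={k: list(v) for k, v in d["children"].items()},
        split_times={int(k): float(v) for k, v in d["split_times"].items()},
        landmark_segment=list(d["landmark_segment"]),
        landmark_time=np.asarray(d["landmark_time"], dtype=float),
        trajectory_of_split={int(k): int(v) - 1
                             for k, v in d["trajectory_of_split"].items()},
        routing_conflicts=list(d.get("routing_conflicts", [])),
    )
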