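"""Scoring a fit against simulation ground truth.

Used in simulation studies: matches fitted trajectories to generating
trajectories (by per-cell branch agreement), and reports pseudotime rank
correlation, per-trajectory branch ARI, bifurcation-time errors and —
for planted-module simulations — the gene-weight AUROC.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import kendalltau
from sklearn.metrics import adjusted_rand_score, roc_auc_score

from .downsample import map_landmarks_to_cells
from .simulate import TrajectoryDataset

__all__ = ["evaluate_recovery", "gene_weight_auroc"]


def evaluate_recovery(data: TrajectoryDataset, result) -> Dict:
    """Compare a :class:`~fatefactor.model.TrajectoryResults` fit with the
    generating truth.

    Pseudotime is scored by per-cell Kendall |tau| (orientation-free);
    branch labels by per-cell adjusted Rand index per trajectory after
    optimally matching fitted to true trajectories (ARI is itself
    invariant to the 1<->2 branch swap); bifurcation times by |b_hat -
    b_true| of the matched pairs.
    """
    est = result.estimate
    L_fit = est.L
    L_true = data.b_true.shape[0]

    t_cell = result.cell_pseudotime
    tau = kendalltau(t_cell, data.T_cell).statistic
    tau = 0.0 if not np.isfinite(tau) else float(tau)

    true_cell_labels = [data.c_true[k][data.landmark_of_cell]
                        for k in range(L_true)]
    fit_cell_labels = [result.cell_branch_labels(l) for l in range(L_fit)]
    ari = np.zeros((L_fit, L_true))
    for l in range(L_fit):
        for k in range(L_true):
            ari[l, k] = adjusted_rand_score(true_cell_labels[k],
                                            fit_cell_labels[l])
    rows, cols = linear_sum_assignment(-ari)
    matched = sorted(zip(cols, rows))  # (true index, fitted index)
    ari_matched = [float(ari[l, k]) for k, l in matched]
    b_err = [float(abs(est.trajectories[l].b - data.b_true[k]))
             for k, l in matched]
    return dict(
        abs_kendall_tau=abs(tau),
        branch_ari=ari_matched,
        b_abs_error=b_err,
        matching={int(k): int(l) for k, l in matched},
    )


def gene_weight_auroc(data: TrajectoryDataset, result,
                      loaded_genes: Optional[int] = None) -> float:
    """AUROC of |gene weight| for the planted module's trajectory.

    The fitted trajectory is matched to the module-bearing trajectory
    (index 0) by branch agreement; genes 0..loaded_genes-1 are positives.
    """
    lg = loaded_genes if loaded_genes is not None \
        else data.params.get("loaded_genes")
    if not lg:
        raise ValueError("dataset has no planted gene module")
    rec = evaluate_recovery(data, result)
    l = rec["matching"][0]
    labels = np.zeros(data.expr.n_genes)
    labels[:lg] = 1
    return float(roc_auc_score(labels, np.abs(result.factors.U[:, l])))
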