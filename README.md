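# fatefactor

Factorization of single-cell expression trajectories into independent
**bifurcating Gaussian processes** over pseudotime, with gene-module
extraction by factor rotation and assembly of the separate bifurcation
events into one consensus cell-fate tree.

## Who this is for

Trajectory inference on scRNA-seq usually returns a single tree and a
single pseudotime.  When a differentiating population undergoes several
distinct fate decisions, it is often more informative to model each
decision separately and then merge them.  `fatefactor` is for analysts
who want exactly that: a cells × genes log-normalized matrix goes in;
out come L independent bifurcation processes — each with a pseudotime
axis, a bifurcation time b_l, per-cell branch phases c_l ∈ {0, 1, 2} and
a ranked list of highly weighted genes — plus a merged binary consensus
tree, and metrics (branch F1, HIM, cordist, wcorfeatures) for comparing
any two trajectories.

## The model

Cells are first collapsed to M landmark metacells (seeded k-means) and
the landmark matrix projected onto L principal components,
y*_l = (Y′ − μ)v_l.  Each column is modelled as a zero-mean Gaussian
process over pseudotime T ∈ [0, 1]^M whose covariance is the sum of L
bifurcation kernels plus noise:

    p(Y*) = ∏_l N(y*_l | 0, Σ_k s_k + σ_S² I)

    [s_l]_{xy} = k_rbf(t_x, t_y) + k_pl(t_x, t_y)                    both pre-branch
               = k_rbf(t_x, t_y) + k_pl(t_x − b_l, t_y − b_l)        same branch
               = k_rbf(t_x, b_l) k_rbf(b_l, t_y) / k_rbf(b_l, b_l)   different branches

with k_rbf(t, t′) = λ e^{−α(t−t′)²} and k_pl(t, t′) = (λ_pl t t′ + c)^d.
Pseudotime, bifurcation times, branch labels and kernel hyperparameters
are sampled by MCMC (adaptive Metropolis-within-Gibbs for T, slice
sampling for continuous parameters, exact Gibbs for labels).  An
orthogonal rotation R then attributes embedding columns to trajectories;
U = VR gives per-gene weights, and |u| > 0.05 defines each trajectory's
highly weighted genes.  Sorting trajectories by b_l and nesting each
split inside the segment holding most of its post-branch landmarks
yields the consensus tree, with segments labeled "n-m" (m-th branch of
branching point n).  See `docs/methods.md` for priors, inference details
and limitations.

## Worked example

```python
import numpy as np
from fatefactor import RunConfig, MCMCConfig, TrajectoryModel
from fatefactor.simulate import simulate_toy_trajectory
from fatefactor.metrics import compare_trajectories

truth, expr, _ = simulate_toy_trajectory("bifurcation", 600, seed=3)
cfg = RunConfig(L=2, M=40,
                mcmc=MCMCConfig(iterations=800, burn_in=400, thinning=5),
                seed=5)
res = TrajectoryModel(expr, cfg).fit()
print(res.summary())
print(compare_trajectories(truth, res.to_trajectory_graph(), seed=0).to_dict())
```

prints:

```
Trajectory factorization results
========================================
cells: 600   genes: 50   landmarks: 40
trajectories (L): 2   MCMC samples kept: 80
observation noise sigma_S: 0.0399   rotation error sigma: 0.2031

trajectory  bifurcation_time  branch1/branch2/pre  n_HWG
         1             0.276       20/10/10           33
         2             0.692       11/10/19           33

consensus tree: 2 branching point(s), 3 terminal segment(s)
mean pseudotime acceptance rate: 0.47

{'him': 0.89, 'f1_branches': 0.69, 'cordist': 0.89,
 'wcorfeatures': 0.46, 'overall': 0.71}
```

Trajectory 1 finds the planted split (b ≈ 0.28 on the rescaled axis)
and divides the post-split landmarks 20/10 between its branches.
Trajectory 2 places a weaker second split late on the axis — the
simulation contains only one bifurcation, so this split fragments one
branch and costs some branch F1 in the comparison against truth (him
0.89, f1_branches 0.69; fitting with `L=1` or ignoring the later split
recovers the cleaner picture).  `res.save(outdir)` writes pseudotime
tables, branch labels, gene weights, HWG lists, and the tree as
Newick + JSON.

The same pipeline is available from a shell:

```sh
fatefactor simulate --topology bifurcation --n-cells 600 --seed 3 -o sim/
fatefactor fit sim/expression.csv -L 2 -M 40 --seed 5 -o fit/
fatefactor evaluate sim/truth.json fit/trajectory.json
```

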