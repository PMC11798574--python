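# Methods

## Model

`fatefactor` models a preprocessed cells × genes expression matrix Y as a
mixture of L independent *bifurcating Gaussian processes* over a latent
pseudotime.  The pipeline is:

1. **Landmark downsampling.** Cells are partitioned into M metacells
   ("landmarks") by seeded k-means (k-means++ initialization, 10
   restarts); the landmark matrix Y′ (M × N) holds cluster-mean
   expression.  This reduces the GP problem from thousands of cells to
   tens of landmarks while preserving trajectory geometry.
2. **Embedding.** Y′ is column-centered and projected onto its first L
   principal components, Y\* = (Y′ − μ)V with VᵀV = I.  One component is
   retained per trajectory.
3. **Probabilistic core.** Each trajectory l has a pseudotime-indexed
   covariance s_l built from a piecewise kernel with a bifurcation time
   b_l ∈ [0, 1] and per-landmark phase labels c_l ∈ {0, 1, 2} (0 before
   the split, i.e. t < b_l; 1/2 = the two branches for t ≥ b_l):

   * both pre-branch: k_rbf(t, t′) + k_pl(t, t′)
   * same branch post-split: k_rbf(t, t′) + k_pl(t − b, t′ − b)
   * different branches: k_rbf(t, b)·k_rbf(b, t′)/k_rbf(b, b)

   with k_rbf(t, t′) = λ_rbf·exp(−α_rbf (t − t′)²) and
   k_pl(t, t′) = (λ_pl t t′ + c_pl)^d.  The cross-branch product form
   routes all covariance through the branch point, decorrelating the two
   branches while both remain correlated with the trunk.  Every column
   of Y\* is scored against the one summed covariance
   Σ_l s_l + σ_S² I (zero mean), so the marginal likelihood is a sum of
   L multivariate-normal log-densities sharing a single Cholesky
   factorization.
4. **Factor rotation.** An orthogonal rotation R (Givens-parameterized,
   so orthogonality is structural) attributes embedding columns to
   trajectories: factor scores W = Y\*R are scored column-wise against
   their *own* trajectory kernel s_l + σ_error² I, and R is chosen to
   maximize that likelihood by multi-start Nelder–Mead over the Givens
   angles and log σ_error.  Gene weights are U = V R; genes with
   |u| > 0.05 (default) form the highly weighted gene (HWG) set of a
   trajectory.  The rotation is fitted post hoc on the posterior point
   estimate, keeping the MCMC state low-dimensional.
5. **Consensus tree.** Trajectories are sorted by bifurcation time; the
   earliest splits the root segment "0" into "1-1"/"1-2" (branch 1 = the
   larger one), and each later trajectory adds its split to the existing
   segment holding the majority of its post-branch landmarks.  Landmarks
   whose label disagrees with the majority segment keep their position
   and are recorded as routing conflicts rather than silently re-routed.
   Cells inherit the placement of their landmark.

## Priors and inference

The model is fitted by MCMC.  Priors (weakly informative, chosen for
support and scale rather than information): pseudotimes and bifurcation
times iid Uniform(0, 1); branch choices uniform on {1, 2}; log λ_rbf,
log α_rbf, log λ_pl and c_pl standard normal; σ_S half-normal(1).  λ_pl
is kept positive so the polynomial kernel stays PSD for even degree; the
degree d (default 2) is fixed, not sampled, to avoid a transdimensional
posterior.  Because the priors assume O(1) data, the embedding scores are
standardized once (divided by their global RMS) before inference; gene
weights are unaffected and factor scores simply inherit the scale.

One sweep updates:

* **Pseudotime** — adaptive Metropolis-within-Gibbs: per-coordinate
  Gaussian proposals reflected into [0, 1], visited in random order,
  with per-coordinate scales adapted every 50 sweeps toward 44%
  acceptance by a Robbins–Monro step (min(0.25, 1/√batch)) on the log
  scale.
* **Bifurcation times** — univariate slice sampling (stepping-out +
  shrinkage; on exhaustion the width is doubled once, then the update
  errors out).
* **Branch labels** — exact two-point Gibbs from the renormalized
  likelihoods.
* **Kernel hyperparameters and σ_S** — slice sampling on log scale
  (natural scale for c_pl), with the half-normal prior's log-scale
  Jacobian included for σ_S.

Labels are handled by *augmentation*: every landmark carries a latent
branch identity in {1, 2} for every trajectory, and the observable label
is 0 where t < b and the identity otherwise.  The uniform prior over
identities marginalizes exactly to the uniform prior on post-branch
labels, while making the slice density of b well-defined on all of
[0, 1] (moving b only re-derives labels deterministically) and making
pseudotime proposals that cross a bifurcation boundary symmetric.
Pre-branch identities are refreshed from their prior each sweep; they do
not affect the likelihood.

Initialization: T = rank transform of the first embedding column (this
also fixes the pseudotime direction convention — corr(T, PC1) ≥ 0 — at
the start; a post-hoc T → 1 − T flip is deliberately *not* applied at
summary time because it would turn bifurcations into convergences and
violate the label constraint), b_l = median(T), identities uniform,
hyperparameters at their prior medians.  Defaults: 5000 sweeps, 2500
burn-in, thinning 5.

The point estimate takes per-coordinate posterior medians (pseudotime
min–max rescaled to [0, 1] with the same affine map applied to b), with
the per-trajectory 1↔2 label symmetry canonicalized against the
highest-posterior sample before the per-landmark majority vote, and
branch 1 defined as the larger branch.

The likelihood evaluation (kernel assembly, Cholesky with escalating
diagonal jitter, triangular solves) has a numba-compiled fast path that
mirrors the plain-numpy reference implementation; the two are asserted
equal in the test suite.  A covariance that fails Cholesky is repaired
by diagonal jitter doubling from 1e-8 (at most 10 doublings), then
eigenvalue clipping at 1e-10 as a last resort.

## Synthetic data

`simulate_from_model` draws from the model's own generative process:
sorted-uniform landmark pseudotimes, labels per the phase constraint with
uniform branch choice, score columns from N(0, Σ_l s_l + σ_S² I), genes
from an orthonormal loading matrix plus iid Gaussian noise, and
per-landmark cell replication with further iid noise.  Defaults: M = 60
landmarks × 10 cells, 200 genes, L = 2, b = (0.4, 0.7), λ_rbf = 1,
α_rbf = 2, λ_pl = 0.5, c_pl = 0.1, d = 2, σ_S = 0.3, gene noise 0.2.

Because all score columns share one covariance in that process, they are
exchangeable and the rotation R is *not identified* from such data; the
`factor_scores=True` variant draws column l from N(0, s_l + σ_S² I) —
the generative counterpart of the factor-rotation model — under which
gene-module recovery is meaningful.  The `loaded_genes` option plants a
module: the first trajectory's loading column is supported on the first
k genes only (equal magnitudes, random signs).

`simulate_toy_trajectory` places cells uniformly on a declared topology
(linear, one or two bifurcations) with branch-specific mean shifts of
twice the noise SD, giving labeled fixtures whose structure is easily
recoverable — useful for end-to-end smoke runs and metric tests.  Neither
simulator attempts library-size effects, dropout, or count noise of real
scRNA-seq, so passing recovery tests demonstrates correctness of the
inference machinery, not robustness to real-data artifacts.

## Identifiability limits at small L

With L = 2 score columns and M = 60 landmarks the data comprise ~120
numbers while the model has a comparable number of free parameters
(60 pseudotimes, 120 labels, 2 split times, kernel scales).  The
posterior over *orderings* is well concentrated (shuffling pseudotime
costs hundreds of nats), but branch labels and bifurcation times are
weakly informed at the default kernel amplitudes: flipping all labels of
one trajectory changes the log-likelihood by only ~1–2 nats, and the
profile likelihood of b can be nearly flat over much of [0, 1].  Exact
oracle experiments (all other parameters held at truth) give
per-trajectory label ARIs between 0.46 and 0.98 across replicate seeds.
Recovery therefore improves sharply with more trajectories/genes-per-
factor, stronger branch-specific covariance (larger α_rbf or λ_pl), or
lower noise, and users should treat branch assignments at desk-scale
simulation settings as posterior tendencies, not point facts.  The same
limit applies to gene-weight rankings: with 200 noisy genes and 60
landmarks the second PCA loading sits near the Marchenko–Pastur bulk
edge, bounding the achievable module-recovery AUROC regardless of the
rotation.

## Trajectory metrics

* **HIM similarity** = 1 − sqrt((H² + IM²)/2) on the union milestone
  set: H is the normalized Hamming distance between length-weighted
  adjacency matrices (both normalized by the larger graph's maximum edge
  weight), IM the Ipsen–Mikhailov distance between Lorentzian-smoothed
  Laplacian spectral densities (one zero mode dropped; width γ
  calibrated per graph size so the empty/complete distance is 1;
  3000-point trapezoidal integration).
* **Branch F1** = harmonic mean of Recovery and Relevance, each the mean
  best Jaccard between branch cell-sets.
* **cordist** = (Spearman ρ + 1)/2 between geodesic waypoint-to-cell
  distances (100 seeded waypoint cells by default; cells live at
  fractional positions on milestone edges).  Spearman is used for
  distances, weighted Pearson for features, following the trajectory-
  benchmarking conventions this metric family comes from.
* **wcorfeatures** = (weighted Pearson r + 1)/2 between per-gene
  importance vectors, weights defaulting to the normalized reference
  importance; undefined (zero-variance) cases are excluded from the
  overall score rather than imputed.
* **overall** = geometric mean of the defined components.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the generative-recovery
study at its default scale (M = 60, 600 cells, 5000 sweeps; 5 replicate
seeds in the suite, one per invocation in the script), the planted-module
study at 2000 sweeps, and the end-to-end smoke run on 600 cells with 40
landmarks and 800 sweeps — sizes chosen so a single-CPU run of the whole
suite stays comfortably interactive while the chains are long past the
point where their summaries stop moving.

## Known limitations

* One principal component per trajectory couples the embedding dimension
  to the trajectory count.
* The consensus merge resolves contradictory bifurcation processes by
  majority occupancy and logs the conflicts; it does not model them.
* No sparse-kernel approximations: cost is O(M³) per likelihood
  evaluation, so M beyond a few hundred landmarks becomes slow.
* Metrics follow the cited conventions but are not bit-identical to any
  external implementation (integration grids, γ calibration and waypoint
  sampling differ).
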