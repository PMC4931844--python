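# Methods

This note records the models, estimators, numerical choices, and known
limitations behind `crnet`. It is written for users who need to judge
what the pipeline's outputs — and the passing tests — do and do not
establish.

## Similarity estimation

**Binned mutual information.** Each gene's profile is discretized into
`B` bins; the default `B = max(2, ⌊√n⌋)` is the usual compromise between
resolution and counting noise for MI estimation at small n. Two schemes
are provided: `equal_frequency` (near-equal occupancy by rank, ties
broken by original sample order so the map is deterministic) and
`equal_width` (B equal intervals over `[min, max]`; a constant gene
collapses to bin 0). Entropies use the Miller-Madow corrected estimator
`Ĥ = Ĥ_emp + (m̂−1)/(2n)` (nats), with `m̂` the number of occupied
cells, and `I = Ĥ(X) + Ĥ(Y) − Ĥ(X,Y)` from the 1-D and 2-D contingency
tables. The correction can drive `I` slightly negative; estimates are
clamped to 0 so they can serve as edge weights (`clamp=False` recovers
the raw value).

*Calibration.* For a bivariate Gaussian with ρ = 0.8 (analytic MI
−½ln(1−ρ²) = 0.5108 nats), at n = 5000 and B = ⌊√n⌋ = 70 the median
estimate over 50 seeds is +14.5 % with equal-width bins but +33.6 % with
equal-frequency bins: equal-frequency marginals force every joint cell
into the ~1-count regime (70² cells for 5000 samples), where the
first-order Miller-Madow correction undercorrects. Large-n consistency
checks therefore use equal-width binning. The pipeline default remains
equal-frequency, which is the better-behaved choice at the pipeline's
actual per-group sample sizes (n = 5–8, B = 2, where the schemes nearly
coincide). Per-group estimation at n = 5–8 is intrinsically noisy; the
pipeline accepts this, as the design it mirrors does.

**Spearman proxy.** The parallel correlation network uses pairwise
Spearman ρ (Pearson on average ranks, which is robust to constant genes)
mapped to the Gaussian-MI scale, `−½ln(1−ρ²)` nats, so both estimators
produce comparable edge weights. `|ρ| = 1` maps to infinity and is capped
at the maximum finite similarity plus one, preserving rank order.
Constant genes get similarity 0 with a warning.

## Network inference

ARACNE applies the data-processing inequality: for each triplet with all
three MI values positive, edge (i,j) is marked for removal iff
`I(i,j) < min(I(i,k), I(j,k)) − ε`. All marks are evaluated against the
original matrix and applied simultaneously, so the operation is
deterministic and idempotent (re-running on its own output is a no-op).
`ε = 0` (the canonical DPI) is the default; larger ε makes removal
*harder*, so the surviving edge set grows with ε. The Spearman-proxy
matrix is pruned with the identical step before any comparison — whether
the original correlation networks of such studies were DPI-pruned is not
documented, so cross-study comparisons of the correlation columns should
be made cautiously.

## Topology diagnostics

- **Strength** `s_i = Σ_j w_ij` (row sums of the similarity matrix
  restricted to surviving edges).
- **Weighted clustering** is Barrat's strength-normalized form,
  `c_i = 1/(s_i(k_i−1)) Σ_{j,h} (w_ij+w_ih)/2 · a_ij a_ih a_jh` over
  ordered neighbour pairs, giving `c_i = 1` for any fully closed
  neighbourhood and 0 for `k_i < 2`. (The geometric-mean alternative can
  be swapped in; the choice is recorded in output metadata.)
- **Hierarchy verdict**: Spearman ρ of `c_i` vs `s_i` over nodes with
  `k_i ≥ 2`; hierarchical iff ρ < 0 with p < 0.05; fewer than 10
  eligible nodes or a degenerate correlation yields "inconclusive", not
  an error.
- **Scale-free verdict** combines three requirements: R² ≥ 0.9 for the
  OLS fit of log survival vs log strength over the fitted tail; a
  continuous power-law MLE (`α = 1 + n/Σln(x/xmin)`, `xmin` chosen to
  minimize the KS distance over ≤ 50 candidates keeping ≥ 10 tail
  points) whose parametric KS bootstrap (100 seeded replicates,
  `p = (1+#{KS_boot ≥ KS_obs})/(B+1)`) gives p ≥ 0.1; and a fitted tail
  spanning at least a 3× strength range. Integer-valued strengths
  (unit-weight degree sequences) are jittered with U[0,1) noise before
  the continuous fit — without this continuity correction, ties inflate
  the observed KS distance relative to the continuous replicates and
  genuinely scale-free degree sequences are rejected; without the span
  requirement, bounded distributions (e.g. uniform strengths) pass on a
  degenerate ~10-point sliver of their upper tail. The bootstrap fixes
  `xmin` at its fitted value rather than re-scanning per replicate,
  which is slightly anti-conservative but 50× cheaper; the span and R²
  requirements provide the compensating specificity.
- **Eigenvector centrality** is the dominant eigenpair of the symmetric
  weighted adjacency (dense `eigh`), sign-fixed to the non-negative
  Perron vector and scaled to max = 1. On a disconnected graph it is
  computed on the component with the largest dominant eigenvalue
  (Perron–Frobenius applies per component); all other nodes get 0 with a
  warning, making the choice visible. **Central genes** are those with
  centrality ≥ τ; τ = 0.9 by default, since "the absolute maximum" rule
  used in practice returns 1–4 genes and is not fully operationalized.
  Centralities are compared across treatments on the per-network max = 1
  scale, because eigenvector centrality is only defined up to scale
  within a network.

## Modularity

`Q = (1/2W) Σ_ij (w_ij − s_i s_j/2W) δ(c_i,c_j)` on the weighted pruned
network; communities come from seeded Louvain maximization (networkx),
with cluster ids renumbered by smallest member index so output is stable.
Louvain starts from singletons and only accepts improving moves, so the
returned partition never scores below the one-cluster or all-singleton
baselines. Reported cluster counts include singletons. Cross-level
cluster flows are contingency tables plus the adjusted Rand index.

*Resolution caveat.* DPI pruning thins each planted module to a tree (or,
around a hub, a star): within a module all pairs share one factor, so the
weakest edge of almost every triangle is removable. Modularity
maximization splits tree-like communities whose internal weight exceeds
the resolution scale (~√2W). Measured consequence: 15-gene modules are
recovered essentially exactly (median ARI 1.0 over 10 seeds at noise
0.3), while a 30-gene hub module splits into ~3 sub-communities
(ARI ≈ 0.6) even though the hub itself remains the top-centrality node.
Module recovery and hub recovery are therefore validated under separate
study designs (below).

## O-PLS-DA

X is autoscaled (per-gene mean 0, variance 1) and y one-hot encoded and
centered. Orthogonal signal correction removes `n_ortho` components
(default 1): the first PLS2 weight `w` is computed, the loading `p` of
the corresponding score is projected off `w`, and the resulting
orthogonal score/loading pair is deflated from X. A NIPALS PLS2 with 2
predictive components (sklearn's PLSRegression) is then fitted; with
`n_ortho = 0` the procedure is exactly PLS-DA (asserted to 1e-8 in
tests). `Xvar` is the percentage of the *original* scaled-X sum of
squares captured by the predictive components, so orthogonal filtering
cannot inflate it. Validation permutes class labels:
`p = (1+#{permuted Xvar ≥ observed})/(n_perm+1)`, lower bound
1/(n_perm+1); a fold-wise `cv_sd` of Xvar is reported separately and
labeled as such. Note that Xvar is only a sharp permutation statistic
when the class signal is low-dimensional relative to the number of
predictive components: with many classes and an overwhelming signal, any
labeling captures similar X variance. Calibration tests use a binary
design (n = 40) for this reason.

## The synthetic generator

Each treatment level draws one latent factor per module,
`f_c ~ N(0,1)` per sample; on the log scale a monotone gene is
`λ_g f_c + ε`, a quadratic (U-shaped) gene is `λ_g · std(f_c²) + ε`, and
a hub is `m λ_g (f_own + 0.05 Σ f_other)/‖·‖ + ε`, with
`λ_g ~ ±U(0.7, 1.0)` (optionally shrunk per module by
`cluster_loading_scale`), `ε ~ N(0, noise_sd)` (default 0.3), and
`m = hub_strength` (default 3). Values are exponentiated to a positive
normalized-count-like scale. Defaults mirror the emulated design: 408
genes, levels 24AL/12AL/10CR/20CR/30CR/40CR with 6/6/7/5/5/8 samples.
Rewiring reassigns a seeded random gene subset (fraction per level,
relative to the level-0 assignment) to new modules. Ground truth
(per-level assignments, hub identities, planted non-monotone pairs) is
returned alongside the matrix, and generation is byte-deterministic
given the spec.

Design notes, fixed once during development:

- **Hubs.** The amplification must dominate and the cross-module
  loadings stay small: cross-loadings add variance quadratically, which
  washes out the hub's within-module correlation, and a hub whose edges
  are weaker than member–member edges is itself removed by the DPI. With
  the chosen form the hub's correlation with each module member
  approaches the member's own noise ceiling `λ/√(λ²+σ²)`, strictly above
  any member–member correlation, so the hub survives pruning as the
  module's star centre. Because eigenvector centrality concentrates on
  the subgraph with the largest spectral radius, a hub is reliably
  top-ranked when planted in the largest module (40/40 seeds with
  modules 30/15/15 at noise 0.25); in equal-size modules another
  module's denser remnant wins the spectrum in ~30 % of seeds.
- **Non-monotone pairs.** Quadratic genes have population Spearman ≈ 0
  against their module partners (symmetric function of a symmetric
  factor) but high binned MI. The number of quadratic genes per module is
  chosen so the fraction of within-module links that are U-shaped best
  matches `nonmonotone_fraction`; only full-strength modules receive
  them. The discrimination study (two strong 10-gene modules with ~45 %
  U-links, one 70-gene weak module at loading scale 0.25, 10 independent
  genes, n = 200) is shaped by two opposing constraints: the MI 0.95
  quantile must sit below the U-pair MI values, which requires few
  strong monotone pairs (< ~5 % of all pairs), while the Spearman median
  must sit above the U-pairs' null-like similarities, which requires a
  substantial mass of genuinely (if weakly) correlated pairs. The weak
  background module satisfies the second constraint without violating
  the first, because its pair similarities are visible to rank
  correlation but its MI stays below the U-pair range.

What the generator does **not** emulate: read counts and library-size
effects, sequencing noise, mean-expression differences between treatment
levels (so O-PLS-DA on the default study is a true negative control),
heavy-tailed expression distributions beyond log-normality, or any
specific mouse gene. Passing recovery tests show the estimators work on
modular latent-factor data of the study's shape — not that real
hypothalamic data has this structure.

## Problem sizes and determinism

Recovery studies use 45–100 genes with 100–200 samples per level, sizes
at which each check runs in seconds while leaving the estimators in
their realistic small-sample regime; the end-to-end determinism check
runs the full 408-gene, 6-level study twice (~15 s per run) and compares
a SHA-256 over all report tables. Every stochastic step (generation,
Louvain, bootstraps, permutations) takes an explicit seed; identical
config + seed reproduces identical artifacts, and each run directory is
stamped with the config hash, seed, and report hash.

## Known limitations

- Per-treatment networks at n = 5–8 samples (B = 2 bins) are unstable by
  construction; the pipeline reproduces the design faithfully rather
  than fixing it. Treat single-treatment edges as exploratory.
- The DPI prunes valid triangle interactions along with indirect ones
  (any module collapses toward a tree), which interacts with the Louvain
  resolution limit as described above.
- The continuous power-law machinery applied to jittered integer degrees
  is an approximation; for publication-grade power-law claims use a
  dedicated discrete fit.
- The Spearman-network comparison depends on pruning both matrices
  identically; other thresholding conventions would change edge counts
  and modularity, so absolute values are not comparable across
  conventions.
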