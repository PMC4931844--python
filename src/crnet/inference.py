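"""Network inference: ARACNE pruning of the MI matrix and the parallel
Spearman-correlation similarity.

ARACNE applies the data-processing inequality: for a Markov chain
X - Y - Z, I(X;Z) <= min(I(X;Y), I(Y;Z)), so the weakest edge of every
triangle is an indirect-interaction candidate.  Pruning is a single
simultaneous pass against the original matrix, which makes it
deterministic and idempotent.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import (
    ExpressionMatrix,
    GeneNetwork,
    MIMatrix,
    ValidationError,
    connected_components,
    warn,
)


def mim_from_entries(n: int, entries: dict, estimator: str = "miller_madow",
                     gene_ids: list[str] | None = None) -> MIMatrix:
    """Build a small MIMatrix from {(i, j): weight} upper-triangle entries."""
    m = np.zeros((n, n))
    for (i, j), w in entries.items():
        m[i, j] = m[j, i] = w
    return MIMatrix(m, gene_ids or [f"g{k}" for k in range(n)], estimator)


def aracne(mim: MIMatrix, epsilon: float = 0.0) -> GeneNetwork:
    """Prune indirect edges from an MI matrix via the data-processing
    inequality.

    For every triplet (i, j, k) with all three MI values positive, edge
    (i, j) is marked for removal iff
    ``mim[i,j] < min(mim[i,k], mim[j,k]) - epsilon``.  All marks are
    evaluated against the original matrix and applied at once; surviving
    edges keep their MI weight.
    """
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    m = np.asarray(mim.mim, dtype=float)
    if not np.array_equal(m, m.T):
        raise ValidationError("MI matrix must be symmetric")
    n = m.shape[0]
    pruned = m.copy()
    pos = m > 0
    for i in range(n):
        # bound[j, k] = min(m[i, k], m[j, k]); invalid k masked out
        bound = np.minimum(m[i][None, :], m)
        valid = pos[i][None, :] & pos
        bound = np.where(valid, bound, -np.inf)
        bound[:, i] = -np.inf
        np.fill_diagonal(bound, -np.inf)  # k == j
        best = bound.max(axis=1)
        remove = pos[i] & (m[i] < best - epsilon)
        pruned[i, remove] = 0.0
        pruned[remove, i] = 0.0
    provenance = "spearman" if mim.estimator.startswith("spearman") else "cmi"
    return GeneNetwork(list(mim.gene_ids), pruned, provenance=provenance,
                       dpi_epsilon=epsilon)


def spearman_similarity(mat: ExpressionMatrix, cap: float | None = None) -> MIMatrix:
    """Pairwise Spearman-rank similarity on the Gaussian-MI scale.

    similarity = -1/2 ln(1 - rho^2) in nats, the mutual information of a
    bivariate Gaussian with correlation rho, so that rank-correlation
    networks are directly comparable with MI networks.  |rho| = 1 maps to
    infinity and is capped at the maximum finite similarity plus one
    (or at ``cap`` when given).  Constant genes get similarity 0 with a
    warning.
    """
    if mat.n_samples < 4:
        raise ValidationError("need at least 4 samples for Spearman similarity")
    vals = mat.values.to_numpy(dtype=float)
    constant = vals.std(axis=1) == 0
    if constant.any():
        warn(f"{int(constant.sum())} constant gene(s); similarities set to 0")
    # Spearman = Pearson on average ranks; explicit form is robust to
    # constant rows (scipy's matrix API degrades on them)
    ranks = np.apply_along_axis(stats.rankdata, 1, vals)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 0.0)
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    with np.errstate(divide="ignore"):
        sim = -0.5 * np.log1p(-rho ** 2)
    finite = np.isfinite(sim)
    if cap is None:
        cap = (sim[finite].max() + 1.0) if finite.any() and (~finite).any() else np.inf
        if not finite.any():
            cap = 1.0
    sim[~finite] = cap
    sim = (sim + sim.T) / 2.0  # enforce exact symmetry
    np.fill_diagonal(sim, 0.0)
    return MIMatrix(sim, mat.gene_ids, "spearman_gaussian")


def network_summary(net: GeneNetwork) -> dict:
    """Edge count, mean degree, mean edge weight, component count."""
    adj = net.adjacency
    n_edges = net.n_edges
    weights = adj[np.triu_indices_from(adj, 1)]
    weights = weights[weights > 0]
    return {
        "n_nodes": net.n_nodes,
        "n_edges": n_edges,
        "mean_degree": float(net.degrees().mean()) if net.n_nodes else 0.0,
        "mean_weight": float(weights.mean()) if n_edges else 0.0,
        "n_components": len(connected_components(adj)),
    }
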