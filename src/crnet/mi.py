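"""Discretization, Miller-Madow entropy, and pairwise mutual information.

Pairwise dependence between genes is estimated in two steps: each gene's
expression profile is discretized into ``B`` bins, and mutual information
is computed between all gene pairs from the binned contingency tables
using the Miller-Madow bias-corrected empirical entropy estimator

    H_MM = H_emp + (m - 1) / (2 n)

where ``m`` is the number of occupied cells and ``n`` the sample count.
All entropies and MI values are in nats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionMatrix, MIMatrix, ValidationError

log = logging.getLogger(__name__)

SCHEMES = ("equal_frequency", "equal_width")


def default_bins(n_samples: int) -> int:
    """floor(sqrt(n)) bins, never fewer than 2 — the usual heuristic for
    MI estimation on small samples."""
    return max(2, int(np.floor(np.sqrt(n_samples))))


def discretize(x, B: int, scheme: str = "equal_frequency") -> np.ndarray:
    """Map a real vector to integer bin indices in [0, B-1].

    ``equal_frequency`` assigns near-equal occupancy by rank, ties broken
    by original order (stable sort); ``equal_width`` splits [min, max]
    into B equal intervals.  A constant vector under equal_width collapses
    to bin 0.
    """
    x = np.asarray(x, dtype=float)
    if B < 2:
        raise ValidationError("B must be >= 2")
    if scheme not in SCHEMES:
        raise ValidationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    n = x.size
    if scheme == "equal_frequency":
        if n < B:
            raise ValidationError(f"need at least B={B} samples for equal_frequency")
        order = np.argsort(x, kind="stable")
        ranks = np.empty(n, dtype=int)
        ranks[order] = np.arange(n)
        return (ranks * B) // n
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros(n, dtype=int)
    bins = np.floor((x - lo) / (hi - lo) * B).astype(int)
    return np.clip(bins, 0, B - 1)


def entropy_miller_madow(counts) -> float:
    """Miller-Madow corrected entropy (nats) of a count vector."""
    c = np.asarray(counts, dtype=float).ravel()
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    n = c.sum()
    if n <= 0:
        raise ValidationError("empty distribution")
    p = c[c > 0] / n
    h_emp = float(-(p * np.log(p)).sum())
    m_hat = int((c > 0).sum())
    return h_emp + (m_hat - 1) / (2.0 * n)


def mutual_information_mm(xb, yb, clamp: bool = True) -> float:
    """Miller-Madow MI (nats) between two bin vectors.

    I = H_MM(X) + H_MM(Y) - H_MM(X, Y) from the 1-D and 2-D contingency
    tables.  The MM correction can push the estimate negative; by default
    such values are clamped to 0 so they can serve as edge weights
    (pass ``clamp=False`` to recover the raw value).
    """
    xb = np.asarray(xb, dtype=int)
    yb = np.asarray(yb, dtype=int)
    if xb.shape != yb.shape:
        raise ValidationError("bin vectors must have equal length")
    if xb.size < 2:
        raise ValidationError("need at least 2 samples")
    bx, by = xb.max() + 1, yb.max() + 1
    joint = np.bincount(xb * by + yb, minlength=bx * by)
    hx = entropy_miller_madow(np.bincount(xb, minlength=bx))
    hy = entropy_miller_madow(np.bincount(yb, minlength=by))
    hxy = entropy_miller_madow(joint)
    mi = hx + hy - hxy
    if clamp:
        mi = max(mi, 0.0)
    return float(mi)


@dataclass
class DiscretizedMatrix:
    """Genes x samples integer bin indices, one common B and scheme."""

    bins: np.ndarray
    gene_ids: list[str]
    B: int
    scheme: str

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=int)
        if b.min(initial=0) < 0 or b.max(initial=0) >= self.B:
            raise ValidationError("bin indices out of range [0, B-1]")
        self.bins = b


def discretize_matrix(mat: ExpressionMatrix, B: int | None = None,
                      scheme: str = "equal_frequency") -> DiscretizedMatrix:
    """Discretize every gene of an expression matrix with a common B."""
    if B is None:
        B = default_bins(mat.n_samples)
    vals = mat.values.to_numpy(dtype=float)
    bins = np.vstack([discretize(row, B, scheme) for row in vals])
    return DiscretizedMatrix(bins, mat.gene_ids, B, scheme)


def build_mim(disc: DiscretizedMatrix) -> MIMatrix:
    """Pairwise Miller-Madow MI over all unordered gene pairs."""
    bins = disc.bins
    n_genes = bins.shape[0]
    if n_genes < 2:
        raise ValidationError("need at least 2 genes")
    mim = np.zeros((n_genes, n_genes))
    # precompute marginal entropies once per gene
    h = np.array(
        [entropy_miller_madow(np.bincount(bins[g], minlength=disc.B))
         for g in range(n_genes)]
    )
    n_pairs = n_genes * (n_genes - 1) // 2
    step = max(1, n_pairs // 10)
    done = 0
    B = disc.B
    joint_len = B * B
    for i in range(n_genes):
        xi = bins[i] * B
        for j in range(i + 1, n_genes):
            joint = np.bincount(xi + bins[j], minlength=joint_len)
            hxy = entropy_miller_madow(joint)
            mim[i, j] = mim[j, i] = max(h[i] + h[j] - hxy, 0.0)
            done += 1
            if done % step == 0:
                log.info("MI matrix: %d/%d pairs", done, n_pairs)
    return MIMatrix(mim, disc.gene_ids, "miller_madow")


def expression_to_mim(mat: ExpressionMatrix, B: int | None = None,
                      scheme: str = "equal_frequency") -> MIMatrix:
    """Convenience wrapper: discretize then build the MI matrix."""
    return build_mim(discretize_matrix(mat, B, scheme))
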