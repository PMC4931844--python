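"""Modularity-based clustering of gene networks.

The modularity coefficient of a weighted partition is

    Q = (1 / 2W) sum_ij (w_ij - s_i s_j / 2W) delta(c_i, c_j)

with W the total edge weight and s_i the node strengths: within-cluster
weight minus its expectation under a random (strength-preserving) null.
Communities are found by seeded Louvain modularity maximization.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .datatypes import GeneNetwork, ValidationError


@dataclass
class Partition:
    """Cluster assignment per gene with its modularity coefficient."""

    gene_ids: list[str]
    labels: np.ndarray
    modularity: float
    algorithm: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.gene_ids),):
            raise ValidationError("labels must assign every gene exactly one cluster")

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.gene_ids, name="cluster")


def modularity_coefficient(net: GeneNetwork, labels) -> float:
    """Weighted modularity Q of a partition."""
    labels = np.asarray(labels)
    if labels.shape != (net.n_nodes,):
        raise ValidationError("partition must cover all nodes")
    w = net.adjacency
    two_w = w.sum()  # == 2W for a symmetric matrix with zero diagonal
    if two_w <= 0:
        raise ValidationError("empty network")
    s = w.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    q = ((w - np.outer(s, s) / two_w) * same).sum() / two_w
    return float(q)


def detect_communities(net: GeneNetwork, seed: int = 0,
                       resolution: float = 1.0) -> Partition:
    """Seeded Louvain modularity maximization on the weighted network.

    Isolated nodes become singleton clusters.  The returned partition
    never scores below the one-cluster or all-singletons baselines
    (Louvain starts from singletons and only accepts improving moves).
    """
    if net.adjacency.sum() <= 0:
        raise ValidationError("empty network")
    g = net.to_networkx()
    comms = nx.community.louvain_communities(
        g, weight="weight", seed=seed, resolution=resolution
    )
    label_of: dict[str, int] = {}
    # stable cluster ids: order communities by smallest member index
    pos = {n: i for i, n in enumerate(net.nodes)}
    comms = sorted(comms, key=lambda c: min(pos[n] for n in c))
    for cid, comm in enumerate(comms):
        for node in comm:
            label_of[node] = cid
    labels = np.array([label_of[n] for n in net.nodes])
    q = modularity_coefficient(net, labels)
    return Partition(list(net.nodes), labels, q, "louvain", seed)


def cluster_crosstab(partitions: list[Partition]) -> list[dict]:
    """Cluster-membership flow between consecutive partitions.

    For each consecutive pair returns a contingency table of cluster
    co-membership plus the adjusted Rand index.
    """
    if len(partitions) < 2:
        raise ValidationError("need at least 2 partitions")
    genes0 = partitions[0].gene_ids
    for p in partitions[1:]:
        if p.gene_ids != genes0:
            missing = sorted(set(genes0) ^ set(p.gene_ids))
            raise ValidationError(f"gene sets differ between partitions: {missing[:10]}")
    flows = []
    for a, b in zip(partitions, partitions[1:]):
        tab = pd.crosstab(
            pd.Series(a.labels, name="from"), pd.Series(b.labels, name="to")
        )
        flows.append({
            "table": tab,
            "ari": float(adjusted_rand_score(a.labels, b.labels)),
        })
    return flows
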