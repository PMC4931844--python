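"""Core in-memory containers shared across the pipeline.

The pipeline's entry point is a normalized genes x samples expression
matrix with a treatment label per sample.  All similarity estimation
produces a symmetric gene x gene matrix (:class:`MIMatrix`), and network
pruning produces a weighted undirected graph (:class:`GeneNetwork`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """Raised when an input container violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values for genes x samples.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample;
        non-negative normalized expression (e.g. normalized counts).
    treatment
        Series mapping sample id -> treatment label, aligned to columns.
    """

    values: pd.DataFrame
    treatment: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValidationError("gene_ids are not unique")
        if self.values.columns.duplicated().any():
            raise ValidationError("sample_ids are not unique")
        missing = set(self.values.columns) - set(self.treatment.index)
        if missing:
            raise ValidationError(f"samples without treatment label: {sorted(missing)}")
        self.treatment = self.treatment.loc[self.values.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(self, treatment: str) -> "ExpressionMatrix":
        """Return the sub-matrix of samples belonging to one treatment group."""
        keep = self.treatment.index[self.treatment == treatment]
        if len(keep) == 0:
            raise ValidationError(f"no samples with treatment {treatment!r}")
        return ExpressionMatrix(self.values[list(keep)], self.treatment.loc[list(keep)])

    @classmethod
    def from_tsv(cls, expression_path, metadata_path) -> "ExpressionMatrix":
        """Load a genes x samples TSV and a (sample_id, treatment) metadata TSV."""
        values = pd.read_csv(expression_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t")
        if "sample_id" not in meta.columns or "treatment" not in meta.columns:
            raise ValidationError("metadata must have sample_id and treatment columns")
        treatment = meta.set_index("sample_id")["treatment"]
        return cls(values, treatment)

    def to_tsv(self, expression_path, metadata_path) -> None:
        self.values.to_csv(expression_path, sep="\t", index_label="gene_id")
        pd.DataFrame(
            {"sample_id": self.sample_ids, "treatment": self.treatment.values}
        ).to_csv(metadata_path, sep="\t", index=False)


@dataclass
class MIMatrix:
    """Symmetric gene x gene similarity matrix in nats.

    ``estimator`` records how it was built: ``miller_madow`` for binned
    mutual information, ``spearman_gaussian`` for the rank-correlation
    Gaussian-MI proxy -1/2 ln(1 - rho^2).
    """

    mim: np.ndarray
    gene_ids: list[str]
    estimator: str

    def __post_init__(self) -> None:
        m = np.asarray(self.mim, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValidationError("mim must be square")
        if m.shape[0] != len(self.gene_ids):
            raise ValidationError("gene_ids length does not match matrix")
        if not np.allclose(m, m.T, atol=0, rtol=0):
            raise ValidationError("mim must be exactly symmetric")
        if (m < 0).any():
            raise ValidationError("mim entries must be non-negative")
        if np.diagonal(m).any():
            raise ValidationError("mim diagonal must be zero")
        self.mim = m

    @property
    def n_genes(self) -> int:
        return self.mim.shape[0]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.mim, index=self.gene_ids, columns=self.gene_ids).to_csv(
            path, sep="\t", index_label="gene_id"
        )

    @classmethod
    def from_tsv(cls, path, estimator: str = "miller_madow") -> "MIMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), list(df.index), estimator)


@dataclass
class GeneNetwork:
    """Weighted undirected gene network (zero weight = no edge)."""

    nodes: list[str]
    adjacency: np.ndarray
    provenance: str = "cmi"
    dpi_epsilon: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or a.shape[0] != len(self.nodes):
            raise ValidationError("adjacency shape does not match nodes")
        if not np.allclose(a, a.T):
            raise ValidationError("adjacency must be symmetric")
        if (a < 0).any():
            raise ValidationError("edge weights must be non-negative")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))

    def degrees(self) -> np.ndarray:
        return (self.adjacency > 0).sum(axis=1)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        for i, j in zip(ii, jj):
            g.add_edge(self.nodes[i], self.nodes[j], weight=float(self.adjacency[i, j]))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, provenance: str = "cmi",
                      dpi_epsilon: float = 0.0) -> "GeneNetwork":
        nodes = list(g.nodes())
        idx = {n: i for i, n in enumerate(nodes)}
        adj = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w = float(data.get("weight", 1.0))
            adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = w
        return cls([str(n) for n in nodes], adj, provenance, dpi_epsilon)

    def write_edgelist(self, path) -> None:
        ii, jj = np.nonzero(np.triu(self.adjacency, 1))
        pd.DataFrame(
            {
                "gene_a": [self.nodes[i] for i in ii],
                "gene_b": [self.nodes[j] for j in jj],
                "weight": self.adjacency[ii, jj],
            }
        ).to_csv(path, sep="\t", index=False)

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "GeneNetwork":
        return cls.from_networkx(nx.read_graphml(path))


def connected_components(adjacency: np.ndarray) -> list[np.ndarray]:
    """Index arrays of connected components of a symmetric adjacency matrix."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components as _cc

    n_comp, labels = _cc(csr_matrix(adjacency != 0), directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=3)
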