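"""Synthetic expression-matrix generator with planted network structure.

Emulates a graded feeding/restriction study: ~400 genes measured in 6
ordered treatment levels with 5-8 animals each.  Genes are organized in
modules (clusters) driven by latent factors; cluster membership can
rewire gradually across levels; designated hub genes load on every
cluster's factor; and a fraction of within-cluster links is generated as
U-shaped (quadratic) dependencies that rank correlation cannot see.
Every downstream stage of the pipeline therefore has a known ground
truth (cluster assignment per level, hub identity, planted non-monotone
pairs).

Generative model, per treatment level, on the log scale:

    monotone gene g in cluster c:   z_g = lambda_g * f_c + eps
    quadratic gene g in cluster c:  z_g = lambda_g * std(f_c^2) + eps
    hub gene g in cluster c:        z_g = m * lambda_g * (f_c + w sum_{c'!=c} f_c') / norm + eps

with a small cross-module weight w (default 0.05).  The hub's amplified
loading (default m = 3) saturates its correlation with every gene of its
own module — the partner gene's own noise then dominates, so hub-member
dependence exceeds member-member dependence and the hub survives DPI
pruning as the module's star centre — while the secondary loadings tie
it weakly to every neighbouring module.  Cross-module weights must stay
small: they inflate the hub's variance quadratically and would otherwise
wash out its within-module correlations.  A hub is most detectable by
eigenvector centrality when planted in the largest module, whose star
dominates the network spectrum.

with f_c ~ N(0,1) i.i.d. per sample, eps ~ N(0, noise_sd), and the
output exponentiated to a positive normalized-count-like scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, GeneNetwork, ValidationError

#: treatment levels of the emulated design, ordered by restriction
#: (24 h / 12 h ad libitum feeding, then 10-40 % restriction)
DEFAULT_LEVELS = ("24AL", "12AL", "10CR", "20CR", "30CR", "40CR")
#: animals per level in the emulated design
DEFAULT_SAMPLES = (6, 6, 7, 5, 5, 8)


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic study design."""

    n_genes: int = 408
    cluster_sizes: tuple[int, ...] = (136, 136, 136)
    treatment_levels: tuple[str, ...] = DEFAULT_LEVELS
    samples_per_level: tuple[int, ...] = DEFAULT_SAMPLES
    rewire_fraction_per_level: tuple[float, ...] = (0.0, 0.05, 0.10, 0.15, 0.20, 0.25)
    hub_genes: tuple[int, ...] = ()
    hub_strength: float = 3.0
    hub_cross_weight: float = 0.05
    nonmonotone_fraction: float = 0.0
    cluster_loading_scale: tuple[float, ...] | None = None
    noise_sd: float = 0.3
    seed: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def validate(self) -> None:
        if sum(self.cluster_sizes) != self.n_genes:
            raise ValidationError(
                f"cluster_sizes sum to {sum(self.cluster_sizes)}, "
                f"but n_genes={self.n_genes}"
            )
        if len(self.samples_per_level) != len(self.treatment_levels):
            raise ValidationError(
                "samples_per_level length does not match treatment_levels"
            )
        if len(self.rewire_fraction_per_level) != len(self.treatment_levels):
            raise ValidationError(
                "rewire_fraction_per_level length does not match treatment_levels"
            )
        for name, frac in (("rewire_fraction_per_level",
                            min(self.rewire_fraction_per_level)),
                           ("rewire_fraction_per_level",
                            max(self.rewire_fraction_per_level)),
                           ("nonmonotone_fraction", self.nonmonotone_fraction)):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if any(g < 0 or g >= self.n_genes for g in self.hub_genes):
            raise ValidationError("hub_genes indices out of range")
        if self.cluster_loading_scale is not None:
            if len(self.cluster_loading_scale) != self.n_clusters:
                raise ValidationError(
                    "cluster_loading_scale length does not match cluster_sizes"
                )
            if min(self.cluster_loading_scale) <= 0:
                raise ValidationError("cluster_loading_scale must be > 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated matrix."""

    cluster_assignment: dict[str, np.ndarray]  # level -> cluster id per gene
    hub_genes: dict[str, tuple[int, ...]]      # level -> hub indices
    nonmonotone_pairs: list[tuple[int, int]]   # planted U-shaped pairs
    quadratic_genes: tuple[int, ...]

    def to_json_dict(self) -> dict:
        return {
            "cluster_assignment": {k: v.tolist()
                                   for k, v in self.cluster_assignment.items()},
            "hub_genes": {k: list(v) for k, v in self.hub_genes.items()},
            "nonmonotone_pairs": [list(p) for p in self.nonmonotone_pairs],
            "quadratic_genes": list(self.quadratic_genes),
        }


def _base_assignment(spec: SyntheticSpec) -> np.ndarray:
    return np.repeat(np.arange(spec.n_clusters), spec.cluster_sizes)


def _pick_quadratic_genes(spec: SyntheticSpec, base: np.ndarray,
                          rng: np.random.Generator) -> np.ndarray:
    """Choose per cluster the number of quadratic genes whose links best
    match the requested fraction of non-monotone within-cluster links.

    Only full-strength clusters (loading scale >= 1) receive quadratic
    genes; down-scaled background modules are too weak for their
    U-shaped links to be meaningfully planted.
    """
    if spec.nonmonotone_fraction == 0:
        return np.array([], dtype=int)
    scales = spec.cluster_loading_scale or (1.0,) * spec.n_clusters
    quad = []
    for c in range(spec.n_clusters):
        if scales[c] < 1.0:
            continue
        members = np.flatnonzero(base == c)
        m = members.size
        if m < 3:
            continue
        total_links = m * (m - 1) / 2
        target = spec.nonmonotone_fraction * total_links
        best_q = min(range(m), key=lambda q: abs(q * (m - q) - target))
        if best_q > 0:
            chosen = rng.choice(members, size=best_q, replace=False)
            quad.extend(int(g) for g in chosen)
    return np.array(sorted(quad), dtype=int)


def generate_expression(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate an expression matrix plus its planted ground truth.

    Deterministic given the spec (including its seed): identical specs
    produce byte-identical outputs.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    base = _base_assignment(spec)
    n, k = spec.n_genes, spec.n_clusters

    loadings = rng.uniform(0.7, 1.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    scales = spec.cluster_loading_scale or (1.0,) * k
    loadings = loadings * np.asarray(scales)[base]
    quad_genes = _pick_quadratic_genes(spec, base, rng)
    is_quad = np.zeros(n, dtype=bool)
    is_quad[quad_genes] = True
    is_hub = np.zeros(n, dtype=bool)
    is_hub[list(spec.hub_genes)] = True
    is_quad[is_hub] = False  # hubs stay monotone

    nonmono_pairs = []
    for g in quad_genes:
        for h in np.flatnonzero((base == base[g]) & ~is_quad & ~is_hub):
            nonmono_pairs.append((min(int(g), int(h)), max(int(g), int(h))))
    nonmono_pairs = sorted(set(nonmono_pairs))

    assignments: dict[str, np.ndarray] = {}
    blocks, sample_ids, treatments = [], [], []
    for lvl_idx, level in enumerate(spec.treatment_levels):
        assign = base.copy()
        frac = spec.rewire_fraction_per_level[lvl_idx]
        n_rewire = int(round(frac * n)) if k > 1 else 0
        if n_rewire > 0:
            movers = rng.choice(n, size=n_rewire, replace=False)
            for g in movers:
                others = [c for c in range(k) if c != base[g]]
                assign[g] = rng.choice(others)
        assignments[level] = assign

        n_s = spec.samples_per_level[lvl_idx]
        factors = rng.standard_normal((k, n_s))
        z = np.empty((n, n_s))
        for g in range(n):
            f = factors[assign[g]]
            if is_hub[g]:
                weights = np.full(k, spec.hub_cross_weight)
                weights[assign[g]] = 1.0
                mix = weights @ factors / np.linalg.norm(weights)
                signal = spec.hub_strength * loadings[g] * mix
            elif is_quad[g]:
                fq = f ** 2
                fq = (fq - fq.mean()) / (fq.std() or 1.0)
                signal = loadings[g] * fq
            else:
                signal = loadings[g] * f
            z[g] = signal
        z += rng.normal(0.0, spec.noise_sd, size=z.shape)
        blocks.append(np.exp(z))
        sample_ids.extend(f"{level}_s{i + 1}" for i in range(n_s))
        treatments.extend([level] * n_s)

    values = pd.DataFrame(
        np.hstack(blocks),
        index=[f"gene{g:04d}" for g in range(n)],
        columns=sample_ids,
    )
    mat = ExpressionMatrix(values, pd.Series(treatments, index=sample_ids))
    truth = SyntheticTruth(
        cluster_assignment=assignments,
        hub_genes={lvl: tuple(spec.hub_genes) for lvl in spec.treatment_levels},
        nonmonotone_pairs=nonmono_pairs,
        quadratic_genes=tuple(int(g) for g in quad_genes),
    )
    return mat, truth


REFERENCE_KINDS = ("scale_free", "random", "two_cliques", "nested_cliques")


def generate_reference_networks(kind: str, n_nodes: int, param: float = 2,
                                seed: int = 0) -> GeneNetwork:
    """Reference topologies for the network diagnostics.

    ``scale_free``
        Barabasi-Albert preferential attachment with ``param`` edges per
        new node.
    ``random``
        Erdos-Renyi G(n, p) with edge probability ``param`` (or, when
        ``param > 1``, mean degree ``param``).
    ``two_cliques``
        Two equal disconnected cliques — the canonical perfectly modular
        graph (Q = 1/2 under the natural split).
    ``nested_cliques``
        Deterministic hierarchical construction: a clique of size
        ``param`` replicated recursively, peripheral nodes wired to the
        root hub, giving the classic negative clustering-vs-degree
        relationship.

    All edges have unit weight; generation is deterministic given seed.
    """
    if kind not in REFERENCE_KINDS:
        raise ValidationError(f"unknown kind {kind!r}; valid kinds: {REFERENCE_KINDS}")
    if n_nodes < 3:
        raise ValidationError("n_nodes must be >= 3")
    if kind == "scale_free":
        g = nx.barabasi_albert_graph(n_nodes, int(param), seed=seed)
    elif kind == "random":
        p = param / (n_nodes - 1) if param > 1 else param
        g = nx.gnp_random_graph(n_nodes, p, seed=seed)
    elif kind == "two_cliques":
        half = n_nodes // 2
        g = nx.disjoint_union(nx.complete_graph(half), nx.complete_graph(n_nodes - half))
    else:
        g = _nested_cliques(n_nodes, int(param) if param and param >= 3 else 5)
    g = nx.relabel_nodes(g, {v: f"gene{v:04d}" for v in g.nodes()})
    return GeneNetwork.from_networkx(g, provenance=kind)


def _nested_cliques(n_nodes: int, module: int = 5) -> nx.Graph:
    """Hierarchical (Ravasz-style) network grown to at least n_nodes."""
    g = nx.complete_graph(module)  # node 0 is the root hub
    periph = [v for v in range(1, module)]
    while g.number_of_nodes() < n_nodes:
        size = g.number_of_nodes()
        base_edges = list(g.edges())
        new_periph = []
        for rep in range(1, module):
            offset = size * rep
            g.add_edges_from((u + offset, v + offset) for u, v in base_edges)
            # peripheral nodes of each replica attach to the root hub
            for v in periph:
                g.add_edge(v + offset, 0)
            new_periph.extend(v + offset for v in periph)
        periph = new_periph
    return g
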