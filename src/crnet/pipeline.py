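"""End-to-end orchestration: one network per treatment level and
estimator, topology and modularity characterization, centrality
trajectories across the ordered levels, and the CMI-vs-correlation
comparison table.

Per-treatment networks are built independently from that treatment's
samples only, mirroring a one-network-per-group design; eigenvector
centralities are compared across treatments on the per-network max=1
scale, since centrality is only defined up to scale within a network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import community, inference, mi, topology
from .datatypes import ExpressionMatrix, GeneNetwork, ValidationError, warn

ESTIMATORS = ("cmi", "spearman")


@dataclass
class PipelineConfig:
    """Every tunable of a pipeline run, loadable from one YAML file."""

    expression: str
    metadata: str
    treatment_levels: list[str]
    reference_level: str
    estimators: list[str] = field(default_factory=lambda: ["cmi", "spearman"])
    bins: int | None = None            # None -> floor(sqrt(n)) per treatment
    scheme: str = "equal_frequency"
    epsilon: float = 0.0
    tau: float = 0.9
    seed: int = 0
    min_samples: int = 3
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ComparisonReport:
    """Cross-treatment, cross-estimator summary of a pipeline run."""

    summary: pd.DataFrame                  # treatment x estimator table
    centrality: dict[str, pd.DataFrame]    # estimator -> genes x levels
    trends: dict[str, pd.DataFrame]        # estimator -> per-gene trend stats
    flows: dict[str, list[dict]]           # estimator -> consecutive-level flows
    central_genes: dict[tuple[str, str], list[str]]
    central_overlap: pd.DataFrame          # per-treatment CMI vs Spearman overlap
    config_hash: str
    seed: int

    def report_hash(self) -> str:
        """Stable content hash of the report for determinism checks."""
        h = hashlib.sha256()
        h.update(self.summary.round(12).to_csv().encode())
        for est in sorted(self.centrality):
            h.update(self.centrality[est].round(12).to_csv().encode())
            h.update(self.trends[est].round(12).to_csv().encode())
            for flow in self.flows[est]:
                h.update(flow["table"].to_csv().encode())
                h.update(f"{flow['ari']:.12f}".encode())
        for key in sorted(self.central_genes):
            h.update(",".join(self.central_genes[key]).encode())
        return h.hexdigest()


def similarity_matrix(mat: ExpressionMatrix, estimator: str,
                      bins: int | None = None, scheme: str = "equal_frequency"):
    if estimator == "cmi":
        return mi.expression_to_mim(mat, B=bins, scheme=scheme)
    if estimator == "spearman":
        return inference.spearman_similarity(mat)
    raise ValidationError(f"unknown estimator {estimator!r}; valid: {ESTIMATORS}")


def centrality_trend(trajectories: pd.DataFrame, level_order: list[str],
                     min_levels: int = 3) -> pd.DataFrame:
    """Per-gene Spearman trend of centrality across ordered levels.

    Genes observed in fewer than ``min_levels`` levels are excluded;
    undefined correlations (constant trajectories) classify as flat.
    """
    if len(level_order) < 3:
        raise ValidationError("need at least 3 treatment levels for a trend")
    rows = []
    ranks = np.arange(len(level_order), dtype=float)
    for gene, row in trajectories[level_order].iterrows():
        vals = row.to_numpy(dtype=float)
        mask = ~np.isnan(vals)
        if mask.sum() < min_levels:
            continue
        if np.ptp(vals[mask]) == 0:
            rows.append((gene, np.nan, "flat"))
            continue
        rho = stats.spearmanr(ranks[mask], vals[mask]).statistic
        if np.isnan(rho) or rho == 0:
            cls = "flat"
        else:
            cls = "graded-up" if rho > 0 else "graded-down"
        rows.append((gene, float(rho) if not np.isnan(rho) else np.nan, cls))
    return pd.DataFrame(rows, columns=["gene_id", "rho", "trend"]).set_index("gene_id")


def analyze_treatment(mat: ExpressionMatrix, estimator: str, *, bins=None,
                      scheme="equal_frequency", epsilon=0.0, tau=0.9, seed=0):
    """Single-treatment analysis: similarity -> ARACNE -> topology,
    partition, centrality, central genes."""
    mim = similarity_matrix(mat, estimator, bins, scheme)
    net = inference.aracne(mim, epsilon)
    summary = inference.network_summary(net)
    part = community.detect_communities(net, seed=seed)
    try:
        profile = topology.eigenvector_centrality(net)
        centrality = profile.as_series()
    except ValidationError:
        profile, centrality = None, pd.Series(np.nan, index=net.nodes)
    central = topology.identify_central_genes(profile, tau) if profile else []
    topo = topology.topology_report(net, seed=seed)
    return {
        "network": net,
        "summary": summary,
        "partition": part,
        "centrality": centrality,
        "central_genes": central,
        "topology": topo,
    }


def run_pipeline(config: PipelineConfig,
                 mat: ExpressionMatrix | None = None) -> ComparisonReport:
    """Run the full per-treatment, per-estimator analysis and assemble
    the comparison report.  Artifacts are written when ``config.out_dir``
    is set."""
    if mat is None:
        mat = ExpressionMatrix.from_tsv(config.expression, config.metadata)
    present = set(mat.treatment)
    missing = [t for t in config.treatment_levels if t not in present]
    if missing:
        raise ValidationError(f"treatment level(s) not found in metadata: {missing}")
    if config.reference_level not in config.treatment_levels:
        raise ValidationError(
            f"reference level {config.reference_level!r} not in treatment_levels"
        )
    for est in config.estimators:
        if est not in ESTIMATORS:
            raise ValidationError(f"unknown estimator {est!r}; valid: {ESTIMATORS}")

    levels = []
    for t in config.treatment_levels:
        n_t = int((mat.treatment == t).sum())
        if n_t < config.min_samples:
            warn(f"treatment {t!r} has only {n_t} samples; skipped")
            continue
        levels.append(t)

    results: dict[tuple[str, str], dict] = {}
    for est in config.estimators:
        for t in levels:
            results[(t, est)] = analyze_treatment(
                mat.subset(t), est, bins=config.bins, scheme=config.scheme,
                epsilon=config.epsilon, tau=config.tau, seed=config.seed,
            )

    rows = []
    for est in config.estimators:
        for t in levels:
            r = results[(t, est)]
            rows.append({
                "treatment": t,
                "estimator": est,
                "modularity_q": r["partition"].modularity,
                "n_clusters": r["partition"].n_clusters,
                "n_edges": r["summary"]["n_edges"],
                "mean_degree": r["summary"]["mean_degree"],
                "central_genes": ";".join(r["central_genes"]),
            })
    summary = pd.DataFrame(rows)

    centrality, trends, flows = {}, {}, {}
    for est in config.estimators:
        traj = pd.DataFrame(
            {t: results[(t, est)]["centrality"] for t in levels},
            index=mat.gene_ids,
        )
        centrality[est] = traj
        trends[est] = centrality_trend(traj, levels) if len(levels) >= 3 \
            else pd.DataFrame(columns=["rho", "trend"])
        flows[est] = community.cluster_crosstab(
            [results[(t, est)]["partition"] for t in levels]
        ) if len(levels) >= 2 else []

    central_genes = {k: v["central_genes"] for k, v in results.items()}
    overlap_rows = []
    if set(config.estimators) >= {"cmi", "spearman"}:
        for t in levels:
            a = set(results[(t, "cmi")]["central_genes"])
            b = set(results[(t, "spearman")]["central_genes"])
            union = a | b
            overlap_rows.append({
                "treatment": t,
                "n_cmi": len(a),
                "n_spearman": len(b),
                "n_shared": len(a & b),
                "jaccard": len(a & b) / len(union) if union else np.nan,
            })
    central_overlap = pd.DataFrame(overlap_rows)

    report = ComparisonReport(
        summary=summary,
        centrality=centrality,
        trends=trends,
        flows=flows,
        central_genes=central_genes,
        central_overlap=central_overlap,
        config_hash=config.content_hash(),
        seed=config.seed,
    )
    if config.out_dir:
        _write_artifacts(config, results, report)
    return report


def _write_artifacts(config: PipelineConfig, results: dict,
                     report: ComparisonReport) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (t, est), r in results.items():
        stem = out / f"{t}_{est}"
        r["network"].write_edgelist(f"{stem}_edges.tsv")
        r["network"].write_graphml(f"{stem}.graphml")
        r["partition"].as_series().to_csv(f"{stem}_clusters.tsv", sep="\t")
        with open(f"{stem}_topology.json", "w") as fh:
            json.dump(r["topology"].to_dict(), fh, indent=1, default=float)
    report.summary.to_csv(out / "summary_table.tsv", sep="\t", index=False)
    for est, traj in report.centrality.items():
        traj.to_csv(out / f"centrality_{est}.tsv", sep="\t")
        report.trends[est].to_csv(out / f"centrality_trend_{est}.tsv", sep="\t")
    if len(report.central_overlap):
        report.central_overlap.to_csv(out / "central_gene_overlap.tsv",
                                      sep="\t", index=False)
    flow_rows = []
    for est, flow_list in report.flows.items():
        for i, flow in enumerate(flow_list):
            tab = flow["table"].stack().rename("n_genes").reset_index()
            tab["estimator"], tab["transition"], tab["ari"] = est, i, flow["ari"]
            flow_rows.append(tab)
    if flow_rows:
        pd.concat(flow_rows).to_csv(out / "cluster_flows.tsv", sep="\t", index=False)
    with open(out / "run_info.json", "w") as fh:
        json.dump({"config_hash": report.config_hash, "seed": report.seed,
                   "report_hash": report.report_hash()}, fh, indent=1)
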