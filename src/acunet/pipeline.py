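"""End-to-end orchestration: ingest -> stats -> cluster -> networks.

Every stage writes its artifacts under the configured output directory and
the final machine-readable run report ties them together. The run is fully
deterministic given the configuration (including the seed when simulating),
apart from the timestamps recorded in the report.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import yaml

from . import __version__
from .cluster import cut_tree, export_dendrogram, ward_linkage
from .errors import ConfigError
from .ingest import (AliasTable, build_count_matrix, build_records,
                     read_prescriptions)
from .network import (build_network, cluster_networks, eigenvector_centrality,
                      filter_edges, top_edges)
from .stats import (chance_level, compute_probabilities, compute_zscores,
                    select_top_k, significant_acupoints)
from .synthetic import SyntheticConfig, generate, planted_truth_report, records_to_csv

__all__ = ["PipelineConfig", "load_config", "run_all"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the study's defaults."""

    outdir: str = "acunet_out"
    input: str | None = None        # prescriptions CSV; None => simulate
    simulate: bool = False
    aliases: str | None = None      # alias TSV; None => bundled table
    seed: int = 0
    top_k: int = 30
    n_clusters: int = 3
    z_threshold: float = 1.96
    zscore_axis: str = "case"
    unknown_policy: str = "batch"   # "strict" aborts on unknown tokens
    token_delimiter: str = ";"
    top_edges_m: int = 30

    def validate(self) -> None:
        if not self.simulate and not self.input:
            raise ConfigError("configuration needs an input file or simulate: true")
        if self.unknown_policy not in ("strict", "batch"):
            raise ConfigError(
                f"unknown_policy must be 'strict' or 'batch', got {self.unknown_policy!r}")
        if self.zscore_axis not in ("case", "acupoint"):
            raise ConfigError(
                f"zscore_axis must be 'case' or 'acupoint', got {self.zscore_axis!r}")


def load_config(path) -> PipelineConfig:
    """Read a YAML config file; unknown keys are rejected."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    return PipelineConfig(**payload)


def _network_summary(net: nx.Graph, m: int) -> dict:
    cent = nx.get_node_attributes(net, "centrality")
    ranked = sorted(cent.items(), key=lambda item: (-item[1], item[0]))
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "top_edges": [
            {"pair": list(pair), "weight": w} for pair, w in top_edges(net, m)
        ],
        "top_centralities": [
            {"acupoint": a, "centrality": round(c, 2)} for a, c in ranked[:10]
        ],
    }


def _write_network(net: nx.Graph, outdir: Path, stem: str) -> None:
    rows = sorted(
        ((min(a, b), max(a, b), d["weight"]) for a, b, d in net.edges(data=True)),
        key=lambda r: (-r[2], r[0], r[1]),
    )
    with open(outdir / f"{stem}_edges.csv", "w", encoding="utf-8") as fh:
        fh.write("node_a,node_b,weight\n")
        for a, b, w in rows:
            fh.write(f"{a},{b},{w:.10g}\n")
    cent = nx.get_node_attributes(net, "centrality")
    with open(outdir / f"{stem}_centrality.csv", "w", encoding="utf-8") as fh:
        fh.write("acupoint,centrality\n")
        for a, c in sorted(cent.items(), key=lambda item: (-item[1], item[0])):
            fh.write(f"{a},{c:.6f}\n")
    nx.write_graphml(net, outdir / f"{stem}.graphml")


def run_all(config: PipelineConfig | str | Path) -> dict:
    """Run the full pipeline and return the run report (also written to disk).

    Stages execute in order (simulate/ingest, probability & z-score
    statistics, Ward clustering, global and per-cluster networks); a failure
    in one stage leaves the artifacts of the earlier stages on disk.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    # --- ingest ------------------------------------------------------------
    if config.simulate:
        syn = SyntheticConfig(seed=config.seed)
        records, truth = generate(syn)
        records_to_csv(records, outdir / "prescriptions.csv",
                       token_delimiter=config.token_delimiter)
        with open(outdir / "planted_truth.json", "w", encoding="utf-8") as fh:
            json.dump(planted_truth_report(records, truth), fh, indent=2)
    else:
        aliases = (AliasTable.from_tsv(config.aliases) if config.aliases
                   else AliasTable.default())
        raw = read_prescriptions(config.input,
                                 token_delimiter=config.token_delimiter)
        on_unknown = "error" if config.unknown_policy == "strict" else "drop"
        records, report = build_records(raw, aliases, on_unknown=on_unknown)
        report.to_json(outdir / "normalization_report.json")
    counts = build_count_matrix(records)
    counts.to_csv(outdir / "counts.csv")

    # --- stats -------------------------------------------------------------
    top = select_top_k(counts, config.top_k)
    P = compute_probabilities(counts, top)
    Z = compute_zscores(P, axis=config.zscore_axis)
    P.to_csv(outdir / "probabilities.csv")
    Z.to_csv(outdir / "zscores.csv")
    significant = significant_acupoints(Z, config.z_threshold)
    with open(outdir / "significant_acupoints.json", "w", encoding="utf-8") as fh:
        json.dump(
            {case: [{"acupoint": a, "z": round(z, 2)} for a, z in hits]
             for case, hits in significant.items()},
            fh, indent=2)

    # --- cluster -----------------------------------------------------------
    tree = ward_linkage(Z)
    tree.to_dataframe().to_csv(outdir / "merge_tree.csv", index=False)
    assignment = cut_tree(tree, config.n_clusters)
    with open(outdir / "cluster_assignments.csv", "w", encoding="utf-8") as fh:
        fh.write("case_id,cluster_label\n")
        for case in counts.index:
            fh.write(f"{case},{assignment[str(case)]}\n")
    export_dendrogram(tree, outdir / "dendrogram.nwk")

    # --- network -----------------------------------------------------------
    global_net = filter_edges(build_network(records))
    cent = eigenvector_centrality(global_net)
    nx.set_node_attributes(global_net, cent, "centrality")
    _write_network(global_net, outdir, "network_global")
    per_cluster = cluster_networks(records, assignment)
    for label, net in per_cluster.items():
        _write_network(net, outdir, f"network_cluster_{label}")

    # --- report ------------------------------------------------------------
    per_case_counts = {c: sum(1 for r in records if r.case_id == c)
                       for c in counts.index}
    report = {
        "tool": "acunet",
        "version": __version__,
        "seed": config.seed,
        "started": started,
        "finished": _dt.datetime.now(_dt.timezone.utc).isoformat(),
        "input_digest": {
            "n_records": len(records),
            "n_cases": int(counts.shape[0]),
            "n_acupoints": int(counts.shape[1]),
            "records_per_case": per_case_counts,
        },
        "top_k": top,
        "chance_level": round(chance_level(len(top)), 3),
        "significant_acupoints": {
            case: [{"acupoint": a, "z": round(z, 2)} for a, z in hits]
            for case, hits in significant.items()},
        "cluster_assignment": assignment,
        "n_clusters": config.n_clusters,
        "network_global": _network_summary(global_net, config.top_edges_m),
        "network_clusters": {
            label: _network_summary(net, config.top_edges_m)
            for label, net in per_cluster.items()},
    }
    with open(outdir / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report
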