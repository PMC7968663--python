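"""One-call orchestration of the full network landscape analysis.

``run_all`` executes the stages in order -- io -> graph -> topology ->
centrality -> communities -> coregulation -> covering-set reduction (and
enrichment when an annotation table is supplied) -- persisting each stage's
tabular output under the run directory and returning a machine-readable
report.  Every stochastic element (generator, community detection,
reduction) is seeded from the config, so two runs with identical config
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import centrality as ct
from . import communities as cm
from . import coregulation as cr
from . import topology as tp
from .enrichment import enrich, read_annotation_table
from .graph_core import build_network, check_bipartite, extract_component, weak_components
from .io_formats import InteractionTable, read_edge_table, write_edge_table
from .synthetic import SyntheticParams, generate


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one analysis run.

    Exactly one of ``edge_table``, ``xml``, ``synthetic`` must be set.
    """

    output_dir: str
    edge_table: str | None = None
    xml: str | None = None
    synthetic: SyntheticParams | None = None
    annotations: str | None = None
    merge_dual_roles: bool = True
    resolution: float = 1.0
    louvain_seed: int = 0
    reduction_seed: int = 0
    reduction_iterations: int = 100_000
    minimality_sweep: bool = True
    fit_method: str = "loglog_ls"
    closeness_sense: str = "directed_in"
    betweenness_sense: str = "directed_out"
    compute_path_centralities: bool = True
    top_k: int = 10

    def __post_init__(self) -> None:
        sources = [
            s for s in (self.edge_table, self.xml, self.synthetic) if s is not None
        ]
        if len(sources) != 1:
            raise ValueError("exactly one input source must be configured")


def _load_table(config: RunConfig) -> InteractionTable:
    if config.edge_table is not None:
        return read_edge_table(config.edge_table)
    if config.xml is not None:
        from .io_formats import parse_drugbank_xml

        return parse_drugbank_xml(config.xml)
    assert config.synthetic is not None
    return generate(config.synthetic)


def run_all(config: RunConfig) -> dict:
    """Run every stage and return the landscape report (also written as JSON)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = _load_table(config)
    write_edge_table(table, out / "edge_table.tsv")

    net = build_network(table, merge_dual_roles=config.merge_dual_roles)
    bip = check_bipartite(net)
    decomposition = weak_components(net)
    giant = extract_component(net, decomposition.giant_index, decomposition)

    with open(out / "components.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\trole\tcomponent_index\n")
        for node in net.nodes:
            role = "+".join(sorted(net.roles[node]))
            fh.write(f"{node}\t{role}\t{decomposition.component_of[node]}\n")

    deg = tp.degrees(net)
    deg.to_csv(out / "degrees.tsv", sep="\t", lineterminator="\n")
    fits = {}
    for which, nodes in (("in", None), ("out", None)):
        dist = tp.empirical_distribution(deg, which, nodes)
        fit = tp.fit_power_law(dist, method=config.fit_method, k_min=1)
        fits[which] = fit
    clustering_profile = tp.clustering(net)

    metrics: dict[str, ct.CentralityScores] = {
        "degree_in": ct.degree_centrality(net, "in"),
        "degree_out": ct.degree_centrality(net, "out"),
        "eigenvector": ct.eigenvector_centrality(net),
    }
    if config.compute_path_centralities:
        metrics["closeness"] = ct.closeness_centrality(
            net, config.closeness_sense
        )
        metrics["betweenness"] = ct.betweenness_centrality(
            net, config.betweenness_sense
        )
    rankings = {}
    for name, scores in metrics.items():
        ranked = ct.top_k(scores, min(config.top_k, net.n_nodes))
        rankings[name] = [
            {"node": net.display[n], "value": v} for n, v in ranked
        ]
        with open(out / f"centrality_{name}.tsv", "w", encoding="utf-8",
                  newline="\n") as fh:
            fh.write("node_id\trole\tvalue\trank\n")
            ordered = sorted(
                scores.values.items(), key=lambda kv: (-kv[1], kv[0])
            )
            for rank, (node, value) in enumerate(ordered, start=1):
                role = "+".join(sorted(net.roles[node]))
                fh.write(f"{node}\t{role}\t{value:.12g}\t{rank}\n")

    partition = cm.louvain(
        net, resolution=config.resolution, seed=config.louvain_seed
    )
    stats = cm.size_stats(partition)
    with open(out / "partition.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("node_id\tcommunity_label\n")
        for node in net.nodes:
            fh.write(f"{node}\t{partition.assignment[node]}\n")

    projection = cr.drug_projection(net)
    with open(out / "coregulation.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug_a\tdrug_b\tshared_targets\n")
        for (a, b), w in sorted(projection.weights.items()):
            fh.write(f"{a}\t{b}\t{w}\n")

    reduction = cr.dominating_set_reduction(
        giant,
        iterations=config.reduction_iterations,
        seed=config.reduction_seed,
        minimality_sweep=config.minimality_sweep,
    )
    with open(out / "reduction.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "seed": reduction.seed,
                "iterations": reduction.iterations,
                "retained": sorted(reduction.retained),
                "removed_count": len(reduction.removed),
                "coverage_check": reduction.coverage_check,
            },
            fh,
            indent=2,
            sort_keys=True,
        )

    enrichment_rows = None
    if config.annotations is not None:
        ann = read_annotation_table(config.annotations)
        query = set(giant.target_nodes()) & ann.background
        result = enrich(query, ann)
        result.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                      lineterminator="\n")
        enrichment_rows = int(len(result))

    report = {
        "counts": {
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "n_drugs": len(net.drug_nodes()),
            "n_targets": len(net.target_nodes()),
            "n_dual_role": len(net.dual_role_nodes()),
        },
        "bipartiteness": {
            "role_disjoint": bip.role_disjoint,
            "two_colorable": bip.two_colorable,
            "dual_role_nodes": [net.display[n] for n in bip.dual_role_nodes],
        },
        "components": {
            "n_components": len(decomposition.sizes),
            "giant_size": decomposition.sizes[0],
            "giant_fraction": decomposition.sizes[0] / net.n_nodes,
            "n_size_2": decomposition.size_histogram.get(2, 0),
        },
        "topology": {
            "mean_degree": tp.mean_degree(net),
            "mean_clustering": clustering_profile.mean_c,
            "gamma_in": fits["in"].gamma,
            "gamma_out": fits["out"].gamma,
            "fit_method": config.fit_method,
        },
        "centrality_top": rankings,
        "communities": {
            "Q": partition.q,
            "n_communities": partition.n_communities,
            "largest": stats.largest,
            "frac_over_100": stats.frac_over_100,
            "frac_size_2": stats.frac_size_2,
            "resolution": config.resolution,
            "seed": config.louvain_seed,
        },
        "coregulation_top": [
            {"drug": net.display[d], "partners": c}
            for d, c in cr.top_coregulated(projection, config.top_k)
        ],
        "reduction": {
            "n_retained": len(reduction.retained),
            "n_drugs_in_giant": len(giant.drug_nodes()),
            "iterations": reduction.iterations,
            "seed": reduction.seed,
            "coverage_check": reduction.coverage_check,
        },
        "enrichment_rows": enrichment_rows,
        "config": {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(config).items()
        },
    }
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
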