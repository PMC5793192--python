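"""End-to-end orchestration: simulate -> cluster -> network -> centrality
-> motifs -> modules -> enrich, with a machine-readable run report.

Each stage reads and writes plain-text files under its own subdirectory of
the output directory, so every stage can equally be run standalone through
the CLI.  A stage whose outputs already exist is skipped unless ``force``
is set.  All randomness flows through the seeds recorded in the report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import centrality as ct
from . import clustering as cl
from . import enrichment as en
from . import io
from . import modules as md
from . import motifs as mt
from . import network as nw
from . import synthetic as syn

log = logging.getLogger("eetnet")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    The thresholds, cluster count, fuzzifier, 2% selection rule, top-20
    aggregation and motif-call quorum are the published analysis settings;
    the motif-null size is a desk-scale choice exposed here.
    """

    thresholds: tuple[float, ...] = nw.DEFAULT_THRESHOLDS
    c: int = 4
    m: float = 1.5
    sharp_ratio: float = 2.0
    percent: float = 0.02
    top_n: int = 20
    motif_n_random: int = 100
    motif_n_swaps: int | None = None
    quorum: int = 5
    conserved: tuple[str, ...] = (
        "Co-regulated PPI", "Protein Clique", "Co-regulated Proteins",
        "PPI Regulating")
    seed: int = 0
    force: bool = False
    scenario: syn.ScenarioConfig | None = None

    def __post_init__(self) -> None:
        ts = tuple(self.thresholds)
        if list(ts) != sorted(ts):
            raise ValueError("thresholds must be sorted ascending")
        if any(not 0.0 <= t <= 1.0 for t in ts):
            raise ValueError("thresholds must lie in [0, 1]")
        self.thresholds = ts


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _done(paths: list[Path], force: bool) -> bool:
    return not force and all(p.exists() for p in paths)


def run_all(config: RunConfig, outdir) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        k: v for k, v in asdict(config).items() if k != "scenario"},
        "seeds": {}, "counts": {}, "warnings": [], "checksums": {}}

    # --- simulate ---------------------------------------------------------
    sim = outdir / "inputs"
    sim.mkdir(exist_ok=True)
    paths = {name: sim / fname for name, fname in [
        ("expression", "expression.tsv"), ("edges", "edges.tsv"),
        ("arcs", "arcs.tsv"), ("annotations", "annotations.gmt"),
        ("truth", "truth.json")]}
    if not _done(list(paths.values()), config.force):
        scenario_cfg = config.scenario or syn.ScenarioConfig(seed=config.seed)
        scenario = syn.simulate_study(scenario_cfg)
        io.write_expression(scenario.expression, paths["expression"])
        io.write_edges(scenario.edges, paths["edges"])
        io.write_arcs(scenario.arcs, paths["arcs"])
        io.write_gmt(scenario.annotations, paths["annotations"])
        io.write_json(scenario.truth.to_json_dict(), paths["truth"])
        report["seeds"]["simulate"] = scenario_cfg.seed
        log.info("simulate: %d proteins, %d edges, %d arcs",
                 len(scenario.expression), len(scenario.edges),
                 len(scenario.arcs))

    expression = io.read_expression(paths["expression"])
    edges = io.read_edges(paths["edges"])
    arcs = io.read_arcs(paths["arcs"])
    annotations = io.read_gmt(paths["annotations"])

    # --- cluster ----------------------------------------------------------
    clu = outdir / "clustering"
    clu.mkdir(exist_ok=True)
    filtered = cl.filter_unexpressed(expression)
    standard = cl.standardize(filtered)
    fit = cl.fuzzy_cmeans(standard, cl.ClusteringConfig(
        c=config.c, m=config.m, seed=config.seed))
    active = cl.identify_active_clusters(fit, sharp_ratio=config.sharp_ratio)
    fit.to_frame().to_csv(clu / "memberships.tsv", sep="\t")
    io.write_id_list(active.down_set, clu / "down_set.txt")
    io.write_id_list(active.up_set, clu / "up_set.txt")
    io.write_id_list(active.union, clu / "active_set.txt")
    report["seeds"]["cluster"] = config.seed
    report["counts"]["proteins_input"] = int(len(expression))
    report["counts"]["proteins_expressed"] = int(len(filtered))
    report["counts"]["active_down"] = len(active.down_set)
    report["counts"]["active_up"] = len(active.up_set)
    report["counts"]["active_total"] = len(active.union)
    if not fit.converged:
        report["warnings"].append("fuzzy c-means did not converge")
    log.info("cluster: %d active proteins (%d down, %d up)",
             len(active.union), len(active.down_set), len(active.up_set))

    # --- network ----------------------------------------------------------
    netdir = outdir / "networks"
    netdir.mkdir(exist_ok=True)
    networks = nw.build_thresholded_networks(
        edges, arcs, active.union, thresholds=config.thresholds)
    table = nw.stats_table(networks)
    table.to_csv(netdir / "network_stats.tsv", sep="\t")
    for t, net in networks.items():
        label = f"CS_{t}"
        io.write_edges(net.ppi_edges, netdir / f"{label}_edges.tsv")
        io.write_arcs(net.reg_arcs, netdir / f"{label}_arcs.tsv")
        io.write_id_list(net.nodes | net.isolated_nodes,
                         netdir / f"{label}_nodes.txt")
    report["counts"]["network_stats"] = {
        row: {k: int(v) for k, v in rec.items()}
        for row, rec in table.to_dict(orient="index").items()}

    # --- centrality -------------------------------------------------------
    cen = outdir / "centrality"
    cen.mkdir(exist_ok=True)
    sizes = [nw.summarize(net).n_proteins_with_isolates
             for net in networks.values()]
    k = ct.selection_size(min(sizes), config.percent)
    key_tables: dict[str, list[str]] = {}
    for t, net in networks.items():
        records = ct.compute_centralities(net)
        label = f"CS_{t}"
        ct.centrality_table(records).to_csv(cen / f"{label}_centrality.tsv",
                                            sep="\t")
        key_tables[label] = ct.rank_and_select(records, k=k)
    ranking = ct.aggregate_frequencies(key_tables, top_n=config.top_n)
    ranking.to_csv(cen / "key_protein_ranking.tsv", sep="\t")
    report["counts"]["key_proteins_per_network"] = k
    report["counts"]["top_ranked"] = list(ranking.index[:config.top_n])

    # --- motifs -----------------------------------------------------------
    mot = outdir / "motifs"
    mot.mkdir(exist_ok=True)
    per_network: dict[str, list[mt.MotifStatistics]] = {}
    for i, (t, net) in enumerate(sorted(networks.items())):
        label = f"CS_{t}"
        stats = mt.motif_significance(
            net, n_random=config.motif_n_random,
            n_swaps=config.motif_n_swaps, seed=config.seed + 100 + i)
        per_network[label] = stats
        rows = [f"{s.name}\t{s.real_count}\t{s.null_mean:.3f}\t"
                f"{s.null_sd:.3f}\t{s.z_score:.3f}\t{s.p_value:.4f}\n"
                for s in stats]
        (mot / f"{label}_motifs.tsv").write_text(
            "name\treal\tnull_mean\tnull_sd\tz\tp\n" + "".join(rows))
    calls = mt.call_motifs(per_network, conserved={
        mt.CLASS_BY_NAME[n].code for n in config.conserved},
        quorum=min(config.quorum, len(networks)))
    report["seeds"]["motifs"] = config.seed + 100
    report["counts"]["active_motifs"] = sorted(
        mt.CLASS_BY_CODE[c].name for c in calls.active)
    report["counts"]["exclusive_motifs"] = sorted(
        mt.CLASS_BY_CODE[c].name for c in calls.exclusive)
    io.write_json({
        "active": sorted(mt.CLASS_BY_CODE[c].name for c in calls.active),
        "conserved": sorted(mt.CLASS_BY_CODE[c].name for c in calls.conserved),
        "exclusive": sorted(mt.CLASS_BY_CODE[c].name for c in calls.exclusive),
        "times_significant": {mt.CLASS_BY_CODE[c].name: n
                              for c, n in calls.times_significant.items()},
    }, mot / "motif_calls.json")

    # --- modules ----------------------------------------------------------
    mod = outdir / "modules"
    mod.mkdir(exist_ok=True)
    focus_codes = calls.exclusive or calls.active or set(
        s.code for stats in per_network.values() for s in stats)
    base_label = f"CS_{min(networks)}"
    base_net = networks[min(networks)]
    members = mt.motif_nodes(base_net, focus_codes)
    graph = ct.ppi_graph(base_net).subgraph(members).copy()
    report["counts"]["motif_proteins"] = len(members)
    if graph.number_of_edges() > 0:
        comp = md.largest_component(graph)
        n = comp.number_of_nodes()
        schedule = md.AnnealSchedule(
            moves_per_temp=min(n * n, 2000), patience=30)
        partition = md.anneal(comp, seed=config.seed + 200,
                              schedule=schedule)
        lines = [f"{node}\t{modidx}\n"
                 for node, modidx in sorted(partition.assignment.items())]
        (mod / "assignment.tsv").write_text("node\tmodule\n" + "".join(lines))
        io.write_json({"M": partition.M, "seed": partition.seed,
                       "n_nodes": n,
                       "n_modules": len(partition.modules()),
                       "network": base_label},
                      mod / "module_report.json")
        report["seeds"]["modules"] = config.seed + 200
        report["counts"]["modules"] = len(partition.modules())
        report["counts"]["modularity"] = partition.M
    else:
        report["warnings"].append("motif-protein PPI graph has no edges; "
                                  "module detection skipped")

    # --- enrich -----------------------------------------------------------
    enr = outdir / "enrichment"
    enr.mkdir(exist_ok=True)
    background = set(filtered.index)
    records, skipped = en.hypergeom_enrich(
        active.union & background, annotations, background)
    en.enrichment_table(records).to_csv(enr / "enrichment.tsv", sep="\t")
    significant = [r.term for r in records if r.fdr is not None
                   and r.fdr < 0.05]
    report["counts"]["enriched_terms_fdr05"] = significant
    report["counts"]["terms_skipped"] = len(skipped)

    for name, p in paths.items():
        report["checksums"][name] = _checksum(p)
    io.write_json(report, outdir / "run_report.json")
    return report
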