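"""Confidence-thresholded PPI networks, active subnetworks and mixed-graph integration.

A background interactome is a list of scored undirected edges (STRING-style
combined confidence in [0, 1]).  The analysis filters it at each threshold in
0.4..0.9, induces the subnetwork on the active proteins, restricts the
transcription-factor -> target regulon to the same node set, and integrates
PPI and regulatory layers into one mixed graph.  Arc accounting follows the
convention that a PPI edge contributes two directed arcs while a regulatory
interaction contributes one, so ``total_arcs = 2*|ppi| + |reg|``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

#: The confidence cutoffs compared throughout the analysis.
DEFAULT_THRESHOLDS = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass(frozen=True)
class ScoredEdge:
    """Undirected PPI edge with an evidence-based confidence score."""

    a: str
    b: str
    confidence: float

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-interaction {self.a!r} not allowed")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


@dataclass(frozen=True)
class RegArc:
    """Directed transcriptional-regulatory interaction TF -> target."""

    tf: str
    target: str


def dedupe_edges(edges: list[ScoredEdge]) -> list[ScoredEdge]:
    """Collapse duplicate unordered pairs; the last occurrence wins."""
    by_pair: dict[frozenset[str], ScoredEdge] = {}
    dupes = 0
    for e in edges:
        if e.pair in by_pair:
            dupes += 1
        by_pair[e.pair] = e
    if dupes:
        warnings.warn(f"{dupes} duplicate edges collapsed (last wins)",
                      stacklevel=2)
    return list(by_pair.values())


@dataclass
class IntegratedNetwork:
    """Mixed graph: undirected scored PPI edges plus directed regulatory arcs.

    ``isolated_nodes`` tracks active proteins with no incident interaction;
    they count toward the with-isolates protein totals but not the connected
    node set.
    """

    ppi_edges: list[ScoredEdge] = field(default_factory=list)
    reg_arcs: list[RegArc] = field(default_factory=list)
    isolated_nodes: set[str] = field(default_factory=set)
    threshold: float | None = None

    @property
    def ppi_nodes(self) -> set[str]:
        nodes: set[str] = set()
        for e in self.ppi_edges:
            nodes.add(e.a)
            nodes.add(e.b)
        return nodes

    @property
    def reg_genes(self) -> set[str]:
        genes: set[str] = set()
        for arc in self.reg_arcs:
            genes.add(arc.tf)
            genes.add(arc.target)
        return genes

    @property
    def nodes(self) -> set[str]:
        """Connected node set: every endpoint of an edge or arc."""
        return self.ppi_nodes | self.reg_genes

    def total_arcs(self) -> int:
        """A PPI edge counts as two bidirectional arcs, a regulation as one."""
        return 2 * len(self.ppi_edges) + len(self.reg_arcs)


@dataclass
class NetworkStats:
    """One row of the per-threshold network summary table."""

    threshold: float | None
    n_proteins_connected: int
    n_proteins_with_isolates: int
    n_ppi_edges: int
    n_reg_genes: int
    n_reg_arcs: int
    n_nodes_total: int
    n_arcs_total: int


def filter_by_confidence(edges: list[ScoredEdge],
                         threshold: float) -> list[ScoredEdge]:
    """Keep edges with confidence >= threshold (inclusive cutoff)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    return [e for e in edges if e.confidence >= threshold]


def induce_active_subnetwork(background: list[ScoredEdge],
                             active: set[str],
                             threshold: float | None = None,
                             ) -> IntegratedNetwork:
    """Subnetwork on the active proteins: edges with both endpoints active.

    Active proteins incident to no surviving edge are recorded as isolates
    (the with-isolates column of the summary table).
    """
    kept = [e for e in background if e.a in active and e.b in active]
    connected = {n for e in kept for n in (e.a, e.b)}
    return IntegratedNetwork(
        ppi_edges=kept,
        isolated_nodes=set(active) - connected,
        threshold=threshold,
    )


def extract_active_regulon(arcs: list[RegArc],
                           network_nodes: set[str]) -> list[RegArc]:
    """Keep arcs whose TF and target are both members of the network.

    Duplicated ordered pairs collapse to one arc.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[RegArc] = []
    for arc in arcs:
        key = (arc.tf, arc.target)
        if key in seen:
            continue
        if arc.tf in network_nodes and arc.target in network_nodes:
            seen.add(key)
            kept.append(arc)
    return kept


def integrate(ppi: IntegratedNetwork, reg: list[RegArc]) -> IntegratedNetwork:
    """Overlay the regulatory arcs on the PPI network.

    The layers stay distinct: a pair interacting in both layers keeps its two
    PPI arcs and its regulatory arc in the accounting, so the total-arc
    identity ``2*|ppi| + |reg|`` always holds.
    """
    reg_nodes = {n for a in reg for n in (a.tf, a.target)}
    return IntegratedNetwork(
        ppi_edges=list(ppi.ppi_edges),
        reg_arcs=list(reg),
        isolated_nodes=ppi.isolated_nodes - reg_nodes,
        threshold=ppi.threshold,
    )


def summarize(network: IntegratedNetwork) -> NetworkStats:
    """Per-network statistics with the arc-accounting identity asserted."""
    n_ppi_nodes = len(network.ppi_nodes)
    stats = NetworkStats(
        threshold=network.threshold,
        n_proteins_connected=n_ppi_nodes,
        n_proteins_with_isolates=n_ppi_nodes + len(network.isolated_nodes),
        n_ppi_edges=len(network.ppi_edges),
        n_reg_genes=len(network.reg_genes),
        n_reg_arcs=len(network.reg_arcs),
        n_nodes_total=len(network.nodes),
        n_arcs_total=network.total_arcs(),
    )
    if stats.n_arcs_total != 2 * stats.n_ppi_edges + stats.n_reg_arcs:
        raise AssertionError("arc accounting identity violated")
    return stats


def build_thresholded_networks(
    background: list[ScoredEdge],
    arcs: list[RegArc],
    active: set[str],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> dict[float, IntegratedNetwork]:
    """Full construction sweep: filter, induce, extract regulon, integrate."""
    networks: dict[float, IntegratedNetwork] = {}
    for t in thresholds:
        filtered = filter_by_confidence(background, t)
        ppi = induce_active_subnetwork(filtered, active, threshold=t)
        scope = ppi.ppi_nodes | ppi.isolated_nodes
        reg = extract_active_regulon(arcs, scope)
        networks[t] = integrate(ppi, reg)
    return networks


def stats_table(networks: dict[float, IntegratedNetwork]) -> pd.DataFrame:
    """Summary rows for all thresholds, indexed CS_0.4 .. CS_0.9."""
    rows = []
    for t in sorted(networks):
        s = summarize(networks[t])
        rows.append({
            "confidence_score": f"CS_{t}",
            "proteins_connected": s.n_proteins_connected,
            "proteins_with_isolates": s.n_proteins_with_isolates,
            "ppi_interactions": s.n_ppi_edges,
            "reg_genes": s.n_reg_genes,
            "reg_interactions": s.n_reg_arcs,
            "total_nodes": s.n_nodes_total,
            "total_arcs": s.n_arcs_total,
        })
    return pd.DataFrame(rows).set_index("confidence_score")
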