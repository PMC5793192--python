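"""Key-protein ranking by degree (hubs) and betweenness (bottlenecks).

Each active PPI network is ranked twice — by incident-edge count and by
unweighted shortest-path betweenness — and every protein receives the mean of
its two fractional ranks (rank 1 = most central).  The top 2% per network are
its key proteins; aggregating how often a protein is a key protein across the
six thresholded networks gives the final frequency ranking.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import rankdata

from .network import IntegratedNetwork


@dataclass
class CentralityRecord:
    node: str
    degree: int
    betweenness: float
    degree_rank: float
    betweenness_rank: float

    @property
    def avg_rank(self) -> float:
        return (self.degree_rank + self.betweenness_rank) / 2.0


def ppi_graph(network: IntegratedNetwork) -> nx.Graph:
    """Undirected graph of the PPI layer (connected nodes only)."""
    g = nx.Graph()
    for e in network.ppi_edges:
        g.add_edge(e.a, e.b, confidence=e.confidence)
    return g


def compute_centralities(network: IntegratedNetwork) -> list[CentralityRecord]:
    """Degree and betweenness with fractional (average-tie) ranks.

    Betweenness is the Brandes count of shortest paths transiting the node:
    unweighted, endpoints excluded, each unordered pair counted once.
    Isolated proteins are excluded — they can be neither hubs nor bottlenecks.
    """
    g = ppi_graph(network)
    if g.number_of_edges() == 0:
        raise ValueError("network has no PPI edges; centralities undefined")
    nodes = sorted(g.nodes)
    degree = [g.degree(n) for n in nodes]
    btw = nx.betweenness_centrality(g, normalized=False)
    betweenness = [btw[n] for n in nodes]
    # rankdata ranks ascending; negate so rank 1 = most central, ties averaged
    deg_rank = rankdata([-d for d in degree], method="average")
    btw_rank = rankdata([-b for b in betweenness], method="average")
    return [
        CentralityRecord(node=n, degree=d, betweenness=b,
                         degree_rank=float(dr), betweenness_rank=float(br))
        for n, d, b, dr, br in zip(nodes, degree, betweenness,
                                   deg_rank, btw_rank)
    ]


def selection_size(n_min: int, percent: float = 0.02) -> int:
    """Number of key proteins: round(percent * smallest network size), >= 1.

    With the published minimum network size of 1118 nodes and the 2% rule
    this gives 22 proteins per network.
    """
    if not 0 < percent < 1:
        raise ValueError("percent must be a fraction in (0, 1)")
    return max(1, round(percent * n_min))


def rank_and_select(records: list[CentralityRecord],
                    k: int | None = None,
                    percent: float = 0.02) -> list[str]:
    """Top-k proteins by ascending average rank; id breaks residual ties."""
    if k is None:
        k = selection_size(len(records), percent)
    if k > len(records):
        raise ValueError(f"k={k} exceeds the {len(records)} ranked proteins")
    ordered = sorted(records, key=lambda r: (r.avg_rank, r.node))
    return [r.node for r in ordered[:k]]


def aggregate_frequencies(tables: dict[str, list[str]],
                          top_n: int = 20,
                          mean_ranks: dict[str, float] | None = None,
                          ) -> pd.DataFrame:
    """Frequency of key-protein status across networks, truncated to top_n.

    ``tables`` maps a network label (e.g. ``CS_0.4``) to its ordered key list.
    Frequency is the number of lists containing the protein.  Sorting is by
    frequency descending; ties break by the mean within-list position (or the
    supplied ``mean_ranks``), then by protein id.
    """
    if not tables:
        return pd.DataFrame(columns=["protein", "frequency", "mean_rank"]
                            ).set_index("protein")
    positions: dict[str, list[int]] = {}
    for column in tables.values():
        for pos, protein in enumerate(column, start=1):
            positions.setdefault(protein, []).append(pos)
    rows = []
    for protein, pos in positions.items():
        mean_rank = (mean_ranks[protein] if mean_ranks is not None
                     else sum(pos) / len(pos))
        rows.append({"protein": protein, "frequency": len(pos),
                     "mean_rank": mean_rank})
    df = pd.DataFrame(rows)
    df = df.sort_values(["frequency", "mean_rank", "protein"],
                        ascending=[False, True, True])
    df["final_rank"] = range(1, len(df) + 1)
    return df.head(top_n).set_index("protein")


def centrality_table(records: list[CentralityRecord]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "node": [r.node for r in records],
            "degree": [r.degree for r in records],
            "betweenness": [r.betweenness for r in records],
            "degree_rank": [r.degree_rank for r in records],
            "betweenness_rank": [r.betweenness_rank for r in records],
            "avg_rank": [r.avg_rank for r in records],
        }
    ).set_index("node")
    return df.sort_values(["avg_rank", "node"])
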