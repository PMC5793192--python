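"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
summation) and stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest

from eetnet.network import IntegratedNetwork, RegArc, ScoredEdge


def brute_force_betweenness(graph: nx.Graph) -> dict:
    """Pair-summed betweenness from scratch: own BFS layering + path DP.

    For every unordered pair (s, t), shortest paths are counted by dynamic
    programming over BFS distance layers; each intermediate node v
    accumulates sigma_st(v) / sigma_st.
    """
    nodes = list(graph.nodes)
    btw = {v: 0.0 for v in nodes}

    def bfs(source):
        dist = {source: 0}
        sigma = {source: 1}
        queue = deque([source])
        while queue:
            u = queue.popleft()
            for w in graph[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0
                    queue.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        return dist, sigma

    info = {v: bfs(v) for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sigma_s = info[s]
        if t not in dist_s:
            continue
        d = dist_s[t]
        dist_t, sigma_t = info[t]
        total = sigma_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                btw[v] += sigma_s[v] * sigma_t[v] / total
    return btw


_PAIRS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))


def oracle_triad_canonical(arcs: set[tuple[int, int]]) -> int:
    """Canonical 6-bit code by explicit minimisation over node orderings."""
    best = None
    for perm in itertools.permutations(range(3)):
        relabeled = {(perm[i], perm[j]) for i, j in arcs}
        code = 0
        for idx, pair in enumerate(_PAIRS):
            if pair in relabeled:
                code |= 1 << idx
        if best is None or code < best:
            best = code
    return best


def oracle_census(network: IntegratedNetwork) -> dict[int, int]:
    """All-triples census: classify every connected induced 3-node subgraph
    directly from the raw edge and arc lists."""
    arcset = set()
    for e in network.ppi_edges:
        arcset.add((e.a, e.b))
        arcset.add((e.b, e.a))
    for a in network.reg_arcs:
        arcset.add((a.tf, a.target))
    nodes = sorted({u for u, _ in arcset} | {v for _, v in arcset})
    counts: dict[int, int] = {}
    for triple in itertools.combinations(nodes, 3):
        local = {n: i for i, n in enumerate(triple)}
        arcs = {(local[u], local[v]) for u, v in arcset
                if u in local and v in local}
        touched = {i for a in arcs for i in a}
        if len(touched) < 3 or not _weakly_connected(arcs):
            continue
        code = oracle_triad_canonical(arcs)
        counts[code] = counts.get(code, 0) + 1
    return counts


def _weakly_connected(arcs) -> bool:
    adj = {0: set(), 1: set(), 2: set()}
    for i, j in arcs:
        adj[i].add(j)
        adj[j].add(i)
    seen, stack = {0}, [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == 3


def best_label_agreement(pred, truth) -> float:
    """Fraction of items whose predicted cluster matches the truth under the
    best cluster-label permutation (Hungarian matching on the confusion
    matrix)."""
    from scipy.optimize import linear_sum_assignment

    pred = np.asarray(pred)
    truth_codes, truth_idx = np.unique(truth, return_inverse=True)
    pred_codes, pred_idx = np.unique(pred, return_inverse=True)
    confusion = np.zeros((len(truth_codes), len(pred_codes)), dtype=int)
    for t, p in zip(truth_idx, pred_idx):
        confusion[t, p] += 1
    rows, cols = linear_sum_assignment(-confusion)
    return confusion[rows, cols].sum() / len(pred)


@pytest.fixture
def small_mixed_network() -> IntegratedNetwork:
    """Hand-sized mixed graph: a PPI triangle, a PPI edge, three arcs."""
    return IntegratedNetwork(
        ppi_edges=[ScoredEdge("a", "b", 0.9), ScoredEdge("b", "c", 0.8),
                   ScoredEdge("a", "c", 0.7), ScoredEdge("d", "e", 0.6)],
        reg_arcs=[RegArc("a", "d"), RegArc("d", "f"), RegArc("f", "e")],
    )


@pytest.fixture
def random_mixed_network() -> IntegratedNetwork:
    """A reproducible 25-node mixed graph for oracle comparisons."""
    rng = np.random.default_rng(42)
    nodes = [f"n{i}" for i in range(25)]
    edges, pairs = [], set()
    while len(edges) < 40:
        u, v = rng.choice(25, size=2, replace=False)
        pair = frozenset((nodes[u], nodes[v]))
        if pair not in pairs:
            pairs.add(pair)
            edges.append(ScoredEdge(nodes[u], nodes[v],
                                    float(rng.uniform(0.4, 1.0))))
    arcs, seen = [], set()
    while len(arcs) < 30:
        u, v = rng.choice(25, size=2, replace=False)
        if (u, v) not in seen:
            seen.add((u, v))
            arcs.append(RegArc(nodes[u], nodes[v]))
    return IntegratedNetwork(ppi_edges=edges, reg_arcs=arcs)
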