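"""Three-node motif census and significance in mixed PPI/regulatory graphs.

The integrated network is treated as a directed graph in which an undirected
PPI edge is a *mutual* arc pair and a transcriptional-regulatory interaction
is a *single* arc.  Connected 3-node induced subgraphs fall into 13
isomorphism classes; each is counted exactly once, and significance is judged
against degree-preserving switching randomizations in which single arcs swap
only with single arcs and mutual pairs only with mutual pairs, so every
node's (single-in, single-out, mutual) degree triple is preserved exactly.
A class is a motif when its real count exceeds the null (z > 2, empirical
p < 0.05) in at least a quorum of the thresholded networks; motifs not on the
cross-species conserved list are the *exclusive* active motifs.
"""

from __future__ import annotations

import itertools
import math
import random
import warnings
from collections import Counter
from dataclasses import dataclass, field

from .network import IntegratedNetwork, RegArc, ScoredEdge

# ordered node pairs of a triad, the bit layout of a 6-bit arc pattern
_PAIRS = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))
_BIT = {p: 1 << i for i, p in enumerate(_PAIRS)}


def _pattern_code(arcs: frozenset[tuple[int, int]]) -> int:
    return sum(_BIT[a] for a in arcs)


def _permute(arcs, perm):
    return frozenset((perm[i], perm[j]) for i, j in arcs)


def _connected(arcs) -> bool:
    adj = {0: set(), 1: set(), 2: set()}
    for i, j in arcs:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for nb in adj[stack.pop()]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == 3


def _build_canonical_tables():
    """For every 6-bit arc pattern: its canonical (minimal) code, connectivity."""
    perms = list(itertools.permutations(range(3)))
    canon = [0] * 64
    connected = [False] * 64
    for code in range(64):
        arcs = frozenset(p for p in _PAIRS if code & _BIT[p])
        canon[code] = min(_pattern_code(_permute(arcs, perm))
                          for perm in perms)
        connected[code] = _connected(arcs)
    return canon, connected


_CANON, _CONNECTED = _build_canonical_tables()


@dataclass(frozen=True)
class TriadClass:
    """A connected 3-node isomorphism class of the mixed graph."""

    code: int                 # canonical 6-bit arc-pattern code
    name: str
    example: frozenset[tuple[int, int]]  # a representative arc set on {0,1,2}


def _cls(name: str, arcs: list[tuple[int, int]]) -> TriadClass:
    arcset = frozenset(arcs)
    return TriadClass(code=_CANON[_pattern_code(arcset)], name=name,
                      example=arcset)


#: The 13 connected triad classes.  Mutual (PPI) pairs are written as both
#: ordered arcs; the first ten carry the motif names used for this system.
TRIAD_CLASSES: tuple[TriadClass, ...] = (
    _cls("Co-regulated PPI", [(0, 1), (0, 2), (1, 2), (2, 1)]),
    _cls("Protein Clique",
         [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]),
    _cls("Co-regulated Proteins", [(0, 1), (0, 2)]),
    _cls("PPI Regulating", [(0, 1), (1, 0), (0, 2)]),
    _cls("Bi-feedforward Loop", [(0, 1), (1, 0), (0, 2), (1, 2)]),
    _cls("Regulatory Cascade with a Feedback", [(0, 1), (1, 2), (2, 0)]),
    _cls("Regulated PPI", [(0, 1), (1, 2), (2, 1)]),
    _cls("Feedback with a PPI", [(0, 1), (1, 0), (0, 2), (2, 1)]),
    _cls("Bi-regulated Protein", [(0, 2), (1, 2)]),
    _cls("Regulatory Cascade", [(0, 1), (1, 2)]),
    _cls("Feedforward Loop", [(0, 1), (0, 2), (1, 2)]),
    _cls("PPI Chain", [(0, 1), (1, 0), (1, 2), (2, 1)]),
    _cls("PPI Chain with Regulation",
         [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2)]),
)

CLASS_BY_CODE = {c.code: c for c in TRIAD_CLASSES}
CLASS_BY_NAME = {c.name: c for c in TRIAD_CLASSES}

if len(CLASS_BY_CODE) != 13:
    raise AssertionError("triad classes are not pairwise non-isomorphic")


def resolve_class(key: int | str | TriadClass) -> TriadClass:
    """Look up a triad class by canonical code, display name or identity."""
    if isinstance(key, TriadClass):
        return key
    if isinstance(key, str) and key in CLASS_BY_NAME:
        return CLASS_BY_NAME[key]
    if isinstance(key, int) and key in CLASS_BY_CODE:
        return CLASS_BY_CODE[key]
    raise KeyError(f"unknown triad class {key!r}")


def classify_triad(arcs) -> TriadClass:
    """Isomorphism class of a 3-node arc set over node labels {0, 1, 2}."""
    code = _pattern_code(frozenset(arcs))
    if not _CONNECTED[code]:
        raise ValueError("triad is not connected")
    return CLASS_BY_CODE[_CANON[code]]


class MixedDigraph:
    """Arc-level view of an integrated network used for motif work.

    Arcs are partitioned into mutual pairs (PPI edges, or reciprocal
    regulatory arcs) and single arcs.  A pair connected by both a PPI edge
    and a regulatory arc collapses to a mutual pair (PPI takes priority);
    the fraction of such hybrid pairs is recorded.
    """

    def __init__(self, mutual: set[frozenset], single: set[tuple],
                 hybrid_fraction: float = 0.0):
        self.mutual = set(mutual)
        self.single = set(single)
        self.hybrid_fraction = hybrid_fraction
        self._rebuild_adjacency()

    def _rebuild_adjacency(self) -> None:
        self.succ: dict = {}
        self.neighbors: dict = {}
        for u, v in self.arcs():
            self.succ.setdefault(u, set()).add(v)
            self.succ.setdefault(v, set())
            self.neighbors.setdefault(u, set()).add(v)
            self.neighbors.setdefault(v, set()).add(u)

    def arcs(self):
        for pair in self.mutual:
            u, v = sorted(pair)
            yield (u, v)
            yield (v, u)
        yield from self.single

    def has_arc(self, u, v) -> bool:
        return frozenset((u, v)) in self.mutual or (u, v) in self.single

    def degree_triple(self, node) -> tuple[int, int, int]:
        """(single-in, single-out, mutual) degree — invariant under switching."""
        sin = sum(1 for _, v in self.single if v == node)
        sout = sum(1 for u, _ in self.single if u == node)
        mut = sum(1 for pair in self.mutual if node in pair)
        return (sin, sout, mut)

    @classmethod
    def from_network(cls, network: IntegratedNetwork) -> "MixedDigraph":
        ppi_pairs = {e.pair for e in network.ppi_edges}
        arc_set = {(a.tf, a.target) for a in network.reg_arcs}
        mutual = set(ppi_pairs)
        single: set[tuple] = set()
        hybrid = 0
        for u, v in arc_set:
            pair = frozenset((u, v))
            if pair in ppi_pairs:
                hybrid += 1      # PPI priority: pair stays mutual
            elif (v, u) in arc_set:
                mutual.add(pair)  # reciprocal regulation is a mutual dyad
            else:
                single.add((u, v))
        n_pairs = len(ppi_pairs | {frozenset(a) for a in arc_set})
        frac = hybrid / n_pairs if n_pairs else 0.0
        if hybrid:
            warnings.warn(
                f"{hybrid} pairs carry both a PPI edge and a regulatory arc "
                f"({frac:.1%} of pairs); classified as PPI (mutual)",
                stacklevel=2)
        return cls(mutual, single, hybrid_fraction=frac)

    def copy(self) -> "MixedDigraph":
        return MixedDigraph(self.mutual, self.single, self.hybrid_fraction)


def triad_code(graph: MixedDigraph, triple) -> int:
    """Canonical class code of the induced subgraph on a 3-node tuple."""
    a, b, c = triple
    nodes = (a, b, c)
    code = 0
    for idx, (i, j) in enumerate(_PAIRS):
        u, v = nodes[i], nodes[j]
        if v in graph.succ.get(u, ()):  # noqa: SIM108 - hot loop
            code |= 1 << idx
    return _CANON[code]


def census(network: IntegratedNetwork | MixedDigraph) -> Counter:
    """Count every connected induced 3-node subgraph exactly once, by class."""
    graph = (network if isinstance(network, MixedDigraph)
             else MixedDigraph.from_network(network))
    counts: Counter = Counter()
    seen: set = set()
    for v, nbrs in graph.neighbors.items():
        nb = sorted(nbrs)
        for u, w in itertools.combinations(nb, 2):
            key = tuple(sorted((u, v, w)))
            if key in seen:
                continue
            seen.add(key)
            counts[triad_code(graph, key)] += 1
    return counts


def randomize(graph: MixedDigraph, n_swaps: int | None = None,
              seed: int = 0) -> MixedDigraph:
    """Degree-preserving switching null for the mixed graph.

    Single arcs are rewired only with single arcs ((a->b, c->d) becomes
    (a->d, c->b)) and mutual pairs only with mutual pairs; a proposal that
    would create a self-loop, a duplicate arc, or convert between single and
    mutual is skipped.  ``n_swaps`` counts swap *attempts* and defaults to
    100 per arc/edge.
    """
    rng = random.Random(seed)
    out = graph.copy()
    singles = list(out.single)
    mutuals = [tuple(sorted(p)) for p in out.mutual]
    n_single, n_mutual = len(singles), len(mutuals)
    if n_swaps is None:
        n_swaps = 100 * (n_single + n_mutual)

    def arc_blocked(u, v):
        return (u == v or (u, v) in out.single or (v, u) in out.single
                or frozenset((u, v)) in out.mutual)

    if n_single + n_mutual == 0:
        return out
    for _ in range(n_swaps):
        pick_single = rng.random() < n_single / (n_single + n_mutual)
        if pick_single and n_single >= 2:
            i, j = rng.sample(range(n_single), 2)
            a, b = singles[i]
            c, d = singles[j]
            if arc_blocked(a, d) or arc_blocked(c, b):
                continue
            out.single.discard((a, b))
            out.single.discard((c, d))
            out.single.add((a, d))
            out.single.add((c, b))
            singles[i] = (a, d)
            singles[j] = (c, b)
        elif not pick_single and n_mutual >= 2:
            i, j = rng.sample(range(n_mutual), 2)
            a, b = mutuals[i]
            c, d = mutuals[j]
            if rng.random() < 0.5:
                c, d = d, c
            new1, new2 = (a, d), (c, b)
            if (a == d or c == b or frozenset(new1) == frozenset(new2)
                    or arc_blocked(*new1) or arc_blocked(d, a)
                    or arc_blocked(*new2) or arc_blocked(b, c)):
                continue
            out.mutual.discard(frozenset((a, b)))
            out.mutual.discard(frozenset((c, d)))
            out.mutual.add(frozenset(new1))
            out.mutual.add(frozenset(new2))
            mutuals[i] = tuple(sorted(new1))
            mutuals[j] = tuple(sorted(new2))
    out._rebuild_adjacency()
    return out


def motif_nodes(network: IntegratedNetwork | MixedDigraph,
                codes: set[int]) -> set:
    """Nodes participating in at least one triad of any class in ``codes``."""
    graph = (network if isinstance(network, MixedDigraph)
             else MixedDigraph.from_network(network))
    members: set = set()
    seen: set = set()
    for v, nbrs in graph.neighbors.items():
        nb = sorted(nbrs)
        for u, w in itertools.combinations(nb, 2):
            key = tuple(sorted((u, v, w)))
            if key in seen:
                continue
            seen.add(key)
            if triad_code(graph, key) in codes:
                members.update(key)
    return members


@dataclass
class MotifStatistics:
    """Real vs null census statistics for one triad class."""

    code: int
    name: str
    real_count: int
    null_mean: float
    null_sd: float
    n_randomizations: int
    p_value: float          # fraction of null counts >= real (over-repr.)
    p_under: float          # fraction of null counts <= real

    @property
    def z_score(self) -> float:
        """(real - null mean) / null sd; +-inf when the null is degenerate."""
        if self.null_sd == 0:
            if self.real_count == self.null_mean:
                return 0.0
            return math.copysign(math.inf, self.real_count - self.null_mean)
        return (self.real_count - self.null_mean) / self.null_sd

    def is_significant(self, z_min: float = 2.0, p_max: float = 0.05) -> bool:
        return self.z_score > z_min and self.p_value < p_max


def motif_significance(network: IntegratedNetwork | MixedDigraph,
                       n_random: int = 1000,
                       n_swaps: int | None = None,
                       seed: int = 0) -> list[MotifStatistics]:
    """Census the real network and ``n_random`` switching nulls per class.

    Classes absent from both the real network and every null are omitted.
    The empirical p uses the >= convention (over-representation); the <=
    tail is reported alongside but never drives a motif call.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    graph = (network if isinstance(network, MixedDigraph)
             else MixedDigraph.from_network(network))
    real = census(graph)
    null_counts: dict[int, list[int]] = {}
    classes: set[int] = set(real)
    nulls: list[Counter] = []
    for r in range(n_random):
        rand = randomize(graph, n_swaps=n_swaps, seed=seed * n_random + r)
        c = census(rand)
        nulls.append(c)
        classes.update(c)
    for code in classes:
        null_counts[code] = [c.get(code, 0) for c in nulls]
    stats = []
    for code in sorted(classes):
        counts = null_counts[code]
        mean = sum(counts) / n_random
        var = sum((x - mean) ** 2 for x in counts) / (n_random - 1)
        rc = real.get(code, 0)
        stats.append(MotifStatistics(
            code=code,
            name=CLASS_BY_CODE[code].name,
            real_count=rc,
            null_mean=mean,
            null_sd=math.sqrt(var),
            n_randomizations=n_random,
            p_value=sum(x >= rc for x in counts) / n_random,
            p_under=sum(x <= rc for x in counts) / n_random,
        ))
    return stats


@dataclass
class MotifCallSet:
    """Active motifs across networks and the exclusive (non-conserved) calls."""

    active: set
    conserved: set
    times_significant: dict = field(default_factory=dict)

    @property
    def exclusive(self) -> set:
        return self.active - self.conserved


def call_motifs(per_network_stats: dict[str, list[MotifStatistics]],
                conserved, quorum: int = 5,
                z_min: float = 2.0, p_max: float = 0.05) -> MotifCallSet:
    """Classes significant in >= ``quorum`` networks; exclusive = active \\ conserved."""
    if quorum > len(per_network_stats):
        raise ValueError("quorum exceeds the number of networks")
    times: Counter = Counter()
    for stats in per_network_stats.values():
        for s in stats:
            if s.is_significant(z_min, p_max):
                times[s.code] += 1
    active = {code for code, t in times.items() if t >= quorum}
    return MotifCallSet(active=active, conserved=set(conserved),
                        times_significant=dict(times))


def plant_triads(network: IntegratedNetwork, triad_class,
                 extra_count: int, seed: int = 0,
                 id_prefix: str = "MOTIF") -> tuple[IntegratedNetwork, list]:
    """Embed ``extra_count`` disjoint instances of a triad class on fresh nodes.

    Mutual pairs of the class pattern become PPI edges (confidence 1.0),
    single arcs become regulatory arcs.  Returns the augmented network and
    the list of planted node triples.  Disjoint embedding on fresh nodes
    makes the census of the planted class additive.
    """
    if extra_count < 0:
        raise ValueError("extra_count must be >= 0")
    cls_ = resolve_class(triad_class)
    ppi = list(network.ppi_edges)
    reg = list(network.reg_arcs)
    planted = []
    for k in range(extra_count):
        nodes = [f"{id_prefix}_{k}_{i}" for i in range(3)]
        arcs = set(cls_.example)
        for i, j in sorted(arcs):
            if (j, i) in arcs:
                if i < j:
                    ppi.append(ScoredEdge(nodes[i], nodes[j], 1.0))
            else:
                reg.append(RegArc(nodes[i], nodes[j]))
        planted.append(tuple(nodes))
    out = IntegratedNetwork(ppi_edges=ppi, reg_arcs=reg,
                            isolated_nodes=set(network.isolated_nodes),
                            threshold=network.threshold)
    return out, planted
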