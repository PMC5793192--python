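"""Synthetic study generators: proteomics, interactome, regulon, annotations.

Every generator emulates the statistical structure the analysis assumes —
six-sample abundance trajectories falling into the four temporal archetypes
of the O2-shift experiment, never-detected (all-zero) proteins, a scored
interactome, a sparse TF -> target regulon, planted triad excesses, planted
communities and planted enriched terms — and returns the ground truth
alongside, so every downstream stage can be scored for parameter recovery.
All randomness flows through an explicit seed.

The abundance model is ``baseline + scale * (template + N(0, noise_sd))``
per sample, truncated at zero; ``noise_sd`` is therefore expressed on the
template scale, where the S3->S4 activation step of the sharp archetypes has
height 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import networkx as nx
import numpy as np
import pandas as pd

from .clustering import SAMPLES
from .motifs import plant_triads, resolve_class
from .network import IntegratedNetwork, RegArc, ScoredEdge

#: Pre-noise trajectory templates over S1..S6.  The S3->S4 step dominates
#: only for the two sharp archetypes.
PATTERN_TEMPLATES: dict[str, tuple[float, ...]] = {
    "sharp_decrease": (1.0, 1.0, 1.0, -1.0, -1.0, -1.0),
    "sharp_increase": (-1.0, -1.0, -1.0, 1.0, 1.0, 1.0),
    "fast_then_slow_decrease": (1.5, 0.5, 0.0, -0.2, -0.4, -0.5),
    "late_increase": (0.0, 0.0, 0.0, 0.0, 0.2, 1.5),
    "flat": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
    "all_zero": (0.0, 0.0, 0.0, 0.0, 0.0, 0.0),
}

#: Interaction-confidence thresholds every synthetic interactome must survive.
_THRESHOLD_GRID = (0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class SyntheticTruth:
    """Ground truth emitted next to every synthetic dataset."""

    pattern_labels: dict[str, str] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    planted_motif_class: str | None = None
    planted_motif_count: int = 0
    enriched_term: str | None = None
    query: set[str] = field(default_factory=set)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict[str, Any]:
        return {
            "pattern_labels": self.pattern_labels,
            "module_labels": self.module_labels,
            "planted_motif_class": self.planted_motif_class,
            "planted_motif_count": self.planted_motif_count,
            "enriched_term": self.enriched_term,
            "query": sorted(self.query),
            "seeds": self.seeds,
        }


def generate_proteomics(n_per_pattern: dict[str, int],
                        noise_sd: float = 0.2,
                        seed: int = 0,
                        baseline: float = 10.0,
                        scale: float = 2.0,
                        ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Protein x six-sample abundance matrix from archetype templates.

    ``all_zero`` rows are exactly zero in all six samples (never-detected
    proteins); every other row is its template plus iid Gaussian noise,
    mapped to the abundance scale and truncated at zero.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    for pattern, count in n_per_pattern.items():
        if pattern not in PATTERN_TEMPLATES:
            raise ValueError(f"unknown pattern {pattern!r}")
        if count < 0:
            raise ValueError(f"negative count for pattern {pattern!r}")
    rng = np.random.default_rng(seed)
    rows, ids, labels = [], [], {}
    i = 0
    for pattern in PATTERN_TEMPLATES:          # fixed order for determinism
        count = n_per_pattern.get(pattern, 0)
        template = np.asarray(PATTERN_TEMPLATES[pattern])
        for _ in range(count):
            pid = f"SYN_{i:04d}"
            if pattern == "all_zero":
                row = np.zeros(6)
            else:
                row = baseline + scale * (
                    template + rng.normal(0.0, noise_sd, size=6))
                row = np.clip(row, 0.0, None)
            rows.append(row)
            ids.append(pid)
            labels[pid] = pattern
            i += 1
    matrix = pd.DataFrame(rows, index=ids, columns=SAMPLES)
    matrix.index.name = "protein_id"
    return matrix, SyntheticTruth(pattern_labels=labels,
                                  seeds={"proteomics": seed})


def _ensure_threshold_coverage(confidences: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """Guarantee a non-empty edge subset at every standard threshold."""
    conf = confidences.copy()
    for t in sorted(_THRESHOLD_GRID, reverse=True):
        if not (conf >= t).any():
            conf[rng.integers(len(conf))] = rng.uniform(t, 1.0)
    return conf


def generate_interactome(n_nodes: int, mean_degree: float, seed: int = 0,
                         node_ids: list[str] | None = None,
                         degree_model: str = "poisson",
                         ) -> list[ScoredEdge]:
    """Simple scored undirected interactome with no self-loops.

    ``degree_model='poisson'`` draws an Erdos-Renyi graph with edge
    probability ``mean_degree/(n-1)``; ``'scale_free'`` grows a
    Barabasi-Albert graph with ``m = mean_degree/2`` attachments, giving the
    heavy-tailed degree distribution typical of curated interactomes.
    Confidence scores are Beta(2, 2), nudged so that every threshold in
    0.4..0.9 keeps at least one edge.
    """
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if mean_degree > n_nodes - 1:
        raise ValueError("mean_degree cannot exceed n_nodes - 1")
    if node_ids is not None and len(node_ids) != n_nodes:
        raise ValueError("node_ids length must equal n_nodes")
    rng = np.random.default_rng(seed)
    graph_seed = int(rng.integers(2 ** 31))
    if degree_model == "poisson":
        g = nx.fast_gnp_random_graph(
            n_nodes, mean_degree / (n_nodes - 1), seed=graph_seed)
    elif degree_model == "scale_free":
        m = max(1, round(mean_degree / 2))
        g = nx.barabasi_albert_graph(n_nodes, m, seed=graph_seed)
    else:
        raise ValueError(f"unknown degree_model {degree_model!r}")
    if node_ids is None:
        node_ids = [f"SYN_{i:04d}" for i in range(n_nodes)]
    edges = sorted(g.edges)
    if not edges:
        raise ValueError("generated graph has no edges; raise mean_degree")
    conf = _ensure_threshold_coverage(rng.beta(2.0, 2.0, size=len(edges)), rng)
    return [ScoredEdge(node_ids[u], node_ids[v], float(c))
            for (u, v), c in zip(edges, conf)]


def generate_regulon(n_tfs: int, n_targets_per_tf: int,
                     node_pool: list[str], seed: int = 0) -> list[RegArc]:
    """Sparse TF -> target arc list; TFs drawn from the pool, arcs distinct."""
    if n_tfs == 0:
        return []
    if not node_pool:
        raise ValueError("node pool is empty")
    if n_tfs > len(node_pool):
        raise ValueError("pool too small for the requested TFs")
    if n_targets_per_tf > len(node_pool) - 1:
        raise ValueError("pool too small for the requested targets per TF")
    rng = np.random.default_rng(seed)
    pool = np.asarray(sorted(node_pool))
    tfs = rng.choice(pool, size=n_tfs, replace=False)
    arcs: list[RegArc] = []
    for tf in tfs:
        candidates = pool[pool != tf]
        targets = rng.choice(candidates, size=n_targets_per_tf, replace=False)
        arcs.extend(RegArc(str(tf), str(t)) for t in targets)
    return arcs


def plant_motifs(network: IntegratedNetwork, triad_class,
                 extra_count: int, seed: int = 0,
                 ) -> tuple[IntegratedNetwork, SyntheticTruth]:
    """Embed disjoint extra instances of a triad class on fresh nodes."""
    cls_ = resolve_class(triad_class)
    augmented, planted = plant_triads(network, cls_, extra_count, seed=seed)
    truth = SyntheticTruth(
        planted_motif_class=cls_.name,
        planted_motif_count=len(planted),
        seeds={"plant_motifs": seed},
    )
    return augmented, truth


def generate_annotations(n_terms: int, planted_term_size: int,
                         planted_overlap: int, background: list[str],
                         seed: int = 0,
                         query: set[str] | None = None,
                         term_size_range: tuple[int, int] = (5, 40),
                         ) -> tuple[dict[str, set[str]], SyntheticTruth]:
    """Annotation collection with one term enriched in a designated query.

    The planted term contains exactly ``planted_overlap`` members of the
    query plus random non-query fill; the remaining ``n_terms - 1`` terms
    are uniform draws from the background.
    """
    background = sorted(set(background))
    rng = np.random.default_rng(seed)
    if query is None:
        q_size = max(planted_overlap, len(background) // 10)
        query = set(rng.choice(background, size=q_size, replace=False))
    query = set(query)
    if not query <= set(background):
        raise ValueError("query must be a subset of the background")
    if not planted_overlap <= planted_term_size <= len(background):
        raise ValueError("need planted_overlap <= planted_term_size <= |background|")
    if planted_overlap > len(query):
        raise ValueError("planted_overlap exceeds the query size")
    non_query = sorted(set(background) - query)
    fill = planted_term_size - planted_overlap
    if fill > len(non_query):
        raise ValueError("background too small for the non-query fill")
    planted = set(rng.choice(sorted(query), size=planted_overlap,
                             replace=False))
    planted |= set(rng.choice(non_query, size=fill, replace=False))
    annotations = {"TERM_planted": planted}
    lo, hi = term_size_range
    hi = min(hi, len(background))
    for t in range(n_terms - 1):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(background, size=size, replace=False))
        annotations[f"TERM_{t:03d}"] = members
    truth = SyntheticTruth(enriched_term="TERM_planted", query=query,
                           seeds={"annotations": seed})
    return annotations, truth


def generate_modular_graph(sizes: list[int], p_in: float = 0.9,
                           p_out: float = 0.05, seed: int = 0,
                           id_prefix: str = "MOD",
                           ) -> tuple[nx.Graph, SyntheticTruth]:
    """Planted-partition graph with string node ids and community truth."""
    g = nx.stochastic_block_model(
        sizes,
        [[p_in if i == j else p_out for j in range(len(sizes))]
         for i in range(len(sizes))],
        seed=seed)
    mapping = {i: f"{id_prefix}_{i:04d}" for i in g.nodes}
    labels = {mapping[i]: int(g.nodes[i]["block"]) for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for _, data in g.nodes(data=True):
        data.clear()
    truth = SyntheticTruth(module_labels=labels,
                           seeds={"modular_graph": seed})
    return g, truth


@dataclass
class ScenarioConfig:
    """Defaults for a full synthetic study at desk scale.

    The archetype mix mirrors the published proteome's shape — the two sharp
    S3->S4 clusters are the largest, a slower-decrease and a late-increase
    cluster complete the four patterns, and a small tranche of proteins is
    never detected.  The interactome is scale-free with Beta(2, 2) scores;
    the regulon averages about a dozen targets per TF, as in bacterial
    regulon databases.
    """

    n_per_pattern: dict[str, int] = field(default_factory=lambda: {
        "sharp_decrease": 250,
        "sharp_increase": 200,
        "fast_then_slow_decrease": 180,
        "late_increase": 160,
        "all_zero": 25,
    })
    noise_sd: float = 0.2
    mean_degree: float = 8.0
    degree_model: str = "scale_free"
    n_tfs: int = 12
    n_targets_per_tf: int = 13
    n_terms: int = 50
    planted_term_size: int = 40
    planted_overlap: int = 36
    seed: int = 0


@dataclass
class Scenario:
    expression: pd.DataFrame
    edges: list[ScoredEdge]
    arcs: list[RegArc]
    annotations: dict[str, set[str]]
    truth: SyntheticTruth
    config: ScenarioConfig


def simulate_study(config: ScenarioConfig | None = None) -> Scenario:
    """Generate one coherent study: proteomics, interactome, regulon, terms.

    The annotation query planted for enrichment is the true active set
    (sharp decrease + sharp increase proteins), so the enrichment stage has
    a recoverable signal.
    """
    config = config or ScenarioConfig()
    seed = config.seed
    expression, truth = generate_proteomics(
        config.n_per_pattern, noise_sd=config.noise_sd, seed=seed)
    expressed = [pid for pid, lab in truth.pattern_labels.items()
                 if lab != "all_zero"]
    edges = generate_interactome(
        len(expressed), config.mean_degree, seed=seed + 1,
        node_ids=expressed, degree_model=config.degree_model)
    arcs = generate_regulon(config.n_tfs, config.n_targets_per_tf,
                            expressed, seed=seed + 2)
    active_truth = {pid for pid, lab in truth.pattern_labels.items()
                    if lab in ("sharp_decrease", "sharp_increase")}
    annotations, ann_truth = generate_annotations(
        config.n_terms, config.planted_term_size, config.planted_overlap,
        expressed, seed=seed + 3, query=active_truth)
    truth.enriched_term = ann_truth.enriched_term
    truth.query = active_truth
    truth.seeds.update(ann_truth.seeds)
    truth.seeds.update({"interactome": seed + 1, "regulon": seed + 2})
    return Scenario(expression=expression, edges=edges, arcs=arcs,
                    annotations=annotations, truth=truth, config=config)
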