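"""Over-representation testing with BH-FDR and genome-proportion comparison.

Enrichment of a query protein set against annotation collections (GMT-style
term -> members) uses the one-sided hypergeometric upper tail
``P[X >= k]`` with ``k`` query hits among ``n`` drawn from a background of
``N`` containing ``K`` term members, followed by Benjamini-Hochberg step-up
adjustment.  A separate proportion comparison contrasts a category's share
of the query set with its share of the whole genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentRecord:
    term: str
    k: int        # query hits in the term
    K: int        # term size within the background
    n: int        # query size
    N: int        # background size
    p_value: float
    fdr: float | None = None


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P[X >= k] for X ~ Hypergeom(N, K, n)."""
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p_values = list(p_values)
    if not p_values:
        return []
    if any(not 0.0 <= p <= 1.0 for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p_values, method="fdr_bh")
    return [float(q) for q in adjusted]


def hypergeom_enrich(query: set[str],
                     annotations: dict[str, set[str]],
                     background: set[str],
                     min_term_size: int = 2,
                     max_term_fraction: float = 0.8,
                     ) -> tuple[list[EnrichmentRecord], list[str]]:
    """Hypergeometric over-representation of ``query`` in each term.

    Term members are intersected with the background before testing.  Terms
    smaller than ``min_term_size`` or covering more than
    ``max_term_fraction`` of the background are skipped and reported in the
    second return value.  Records come back sorted by (fdr, p, term).
    """
    stray = set(query) - set(background)
    if stray:
        raise ValueError(
            f"query ids outside the background: {sorted(stray)[:10]}")
    N, n = len(background), len(query)
    records: list[EnrichmentRecord] = []
    skipped: list[str] = []
    for term in sorted(annotations):
        members = annotations[term] & background
        K = len(members)
        if K < min_term_size or K > max_term_fraction * N:
            skipped.append(term)
            continue
        k = len(members & query)
        records.append(EnrichmentRecord(
            term=term, k=k, K=K, n=n, N=N,
            p_value=hypergeom_pvalue(k, K, n, N)))
    fdrs = bh_fdr([r.p_value for r in records])
    for r, q in zip(records, fdrs):
        r.fdr = q
    records.sort(key=lambda r: (r.fdr, r.p_value, r.term))
    return records, skipped


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"term": r.term, "k": r.k, "K": r.K, "n": r.n, "N": r.N,
          "p_value": r.p_value, "fdr": r.fdr} for r in records]
    ).set_index("term") if records else pd.DataFrame(
        columns=["k", "K", "n", "N", "p_value", "fdr"])


@dataclass
class ProportionComparison:
    """A category's share of the query set vs its share of the genome."""

    category: str
    query_count: int
    query_proportion: float
    genome_count: int
    genome_proportion: float

    @property
    def ratio(self) -> float:
        if self.genome_proportion == 0:
            return float("inf") if self.query_proportion > 0 else float("nan")
        return self.query_proportion / self.genome_proportion


def proportion_compare(query: set[str], category_members: set[str],
                       genome: set[str],
                       category: str = "category") -> ProportionComparison:
    if not query or not genome:
        raise ValueError("query and genome must be non-empty")
    stray = category_members - genome
    if stray:
        raise ValueError(
            f"category members outside the genome: {sorted(stray)[:10]}")
    q_hits = len(query & category_members)
    return ProportionComparison(
        category=category,
        query_count=q_hits,
        query_proportion=q_hits / len(query),
        genome_count=len(category_members),
        genome_proportion=len(category_members) / len(genome),
    )
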