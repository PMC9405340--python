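"""Hypergeometric over-representation analysis of gene lists.

For a query of n genes drawn from a universe of N genes, a term with K
annotated genes, and an observed intersection of k genes, the enrichment
p-value is the hypergeometric upper tail P(X >= k).  Terms are BH-corrected
across one collection and reported with their gene ratio k/K (the quantity
shown in enrichment bubble plots).  Terms are flat sets (GMT); no ontology
topology is traversed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ParameterError
from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's over-representation result."""

    term_id: str
    term_size: int
    query_size: int
    intersection_size: int
    universe_size: int
    p: float
    p_adj: float
    gene_ratio: float
    members: tuple[str, ...]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ParameterError(
            f"inconsistent counts: need 0 <= k <= min(K, n) <= N, "
            f"got k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora_enrich(
    query: set[str],
    gene_sets: dict[str, set[str]],
    universe: set[str] | str = "annotated",
) -> list[EnrichmentRow]:
    """Over-representation of ``query`` against every term in ``gene_sets``.

    ``universe="annotated"`` (default) uses the union of all term members;
    an explicit gene set restricts both terms and query.  Query genes
    outside the universe are dropped with a logged count.  One row is
    returned per term with a non-empty intersection, BH-corrected across
    tested terms and sorted by p then term id.
    """
    if universe == "annotated":
        universe_set = set().union(*gene_sets.values()) if gene_sets else set()
    else:
        universe_set = set(universe)
    if not universe_set:
        raise ConfigurationError("enrichment universe is empty")

    dropped = len(query - universe_set)
    if dropped:
        log.info("dropping %d query genes outside the universe", dropped)
    query_in = query & universe_set
    n = len(query_in)
    N = len(universe_set)

    tested = []
    for term_id in sorted(gene_sets):
        members = gene_sets[term_id] & universe_set
        overlap = members & query_in
        if not overlap:
            continue
        K = len(members)
        k = len(overlap)
        tested.append(
            {
                "term_id": term_id,
                "K": K,
                "k": k,
                "p": hypergeom_upper_tail(k, K, n, N),
                "members": tuple(sorted(overlap)),
            }
        )
    if not tested:
        return []
    adjusted = bh_adjust([t["p"] for t in tested])
    rows = [
        EnrichmentRow(
            term_id=t["term_id"],
            term_size=t["K"],
            query_size=n,
            intersection_size=t["k"],
            universe_size=N,
            p=t["p"],
            p_adj=float(q),
            gene_ratio=t["k"] / t["K"],
            members=t["members"],
        )
        for t, q in zip(tested, adjusted)
    ]
    rows.sort(key=lambda r: (r.p, r.term_id))
    return rows


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment rows as a DataFrame in reporting column order."""
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_size": r.term_size,
                "query_size": r.query_size,
                "intersection_size": r.intersection_size,
                "universe_size": r.universe_size,
                "p": r.p,
                "p_adj": r.p_adj,
                "gene_ratio": r.gene_ratio,
                "members": ";".join(r.members),
            }
            for r in rows
        ],
        columns=[
            "term_id", "term_size", "query_size", "intersection_size",
            "universe_size", "p", "p_adj", "gene_ratio", "members",
        ],
    )
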