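"""Inverse co-expression pair networks and overlapping community detection.

An *immunogenic pair* is a miRNA and a predicted target gene that (a) move
in opposite directions under the ICD treatments, (b) have a sequence-based
target relationship at or above the prediction-score threshold, and (c)
involve a gene annotated to the immune-system-process gene set.  Pairs form
a bipartite miRNA-gene graph.

Clustering follows the EAGLE scheme for overlapping communities: maximal
cliques of at least ``min_clique_size`` vertices seed the communities
(cliques whose vertices all belong to other, larger retained cliques are
subordinate and dropped); vertices in no retained clique enter as singleton
communities; the pair of communities with the largest modularity-style
similarity is merged repeatedly until one community remains; and the
returned cover is the dendrogram level with maximal extended modularity EQ,
which weights each node pair by the reciprocal product of the two nodes'
community membership counts.

Bipartite caveat: a miRNA-gene graph is triangle-free, so no clique of size
3 exists and every vertex would be subordinate.  For bipartite inputs the
default seed size is therefore 2 (edges as seed cliques); for general graphs
it is 3.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .errors import ConfigurationError
from .signature import ICDSignature, call_differential
from .targets import TargetPrediction

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImmunogenicPair:
    """One miRNA : target-gene pair satisfying the three defining criteria."""

    mirna_id: str
    gene_id: str
    mirna_direction: str
    gene_direction: str
    score: float
    in_go_term: bool = True


def build_pairs(
    mirna_signature: ICDSignature,
    mrna_records: pd.DataFrame,
    predictions: list[TargetPrediction],
    go_genes: set[str],
    fc_min: float = 1.3,
    alpha: float = 0.05,
    score_threshold: float = 0.9,
    use_adjusted: bool = True,
) -> list[ImmunogenicPair]:
    """Emit every pair satisfying the inverse-coexpression criteria.

    ``mrna_records`` is a per-gene contrast result (indexed by gene id, with
    ``signed_fc`` plus ``p``/``p_adj`` columns) from which gene directions
    are derived with the same thresholds used for the miRNA signature;
    up-miRNAs pair only with down-genes and vice versa.  Genes outside
    ``go_genes`` never form pairs.
    """
    if not go_genes:
        raise ConfigurationError(
            "go_genes is empty; the immune-term criterion would be vacuous"
        )
    pcol = "p_adj" if (use_adjusted and "p_adj" in mrna_records.columns) else "p"
    gene_direction = {
        gene: call_differential(
            row["signed_fc"], row[pcol], fc_min=fc_min, alpha=alpha
        )
        for gene, row in mrna_records.iterrows()
    }
    opposite = {"up": "down", "down": "up"}
    pairs = []
    for pred in predictions:
        if pred.score < score_threshold:
            continue
        dm = mirna_signature.direction_of(pred.mirna_id)
        if dm == "ns":
            continue
        dg = gene_direction.get(pred.gene_id, "ns")
        if dg != opposite[dm]:
            continue
        if pred.gene_id not in go_genes:
            continue
        pairs.append(
            ImmunogenicPair(pred.mirna_id, pred.gene_id, dm, dg, pred.score)
        )
    pairs.sort(key=lambda p: (p.mirna_id, p.gene_id))
    return pairs


def pairs_to_graph(pairs: list[ImmunogenicPair]) -> nx.Graph:
    """Bipartite miRNA-gene graph; nodes carry a ``kind`` attribute."""
    graph = nx.Graph()
    for p in pairs:
        graph.add_node(p.mirna_id, kind="miRNA")
        graph.add_node(p.gene_id, kind="gene")
        graph.add_edge(p.mirna_id, p.gene_id, score=p.score)
    return graph


# ---------------------------------------------------------------------------
# cliques and extended modularity
# ---------------------------------------------------------------------------

def maximal_cliques(graph: nx.Graph) -> list[tuple]:
    """All maximal cliques, each once, in deterministic order.

    Enumeration uses pivoting Bron-Kerbosch (via networkx); the result is
    normalized to sorted node tuples in lexicographic order.
    """
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    return sorted(cliques)


def extended_modularity(graph: nx.Graph, cover: list[set]) -> float:
    """Overlap-aware modularity EQ of a cover.

    EQ = (1/2m) sum_i sum_{v,w in C_i} [A_vw - k_v k_w / (2m)] / (O_v O_w),
    over ordered node pairs including v = w (A_vv = 0 for simple graphs).
    Returns 0.0 for an edgeless graph.
    """
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    two_m = 2.0 * m
    degree = dict(graph.degree())
    o_count: dict = {}
    for community in cover:
        for v in community:
            o_count[v] = o_count.get(v, 0) + 1
    eq = 0.0
    for community in cover:
        members = sorted(community)
        for v in members:
            for w in members:
                a_vw = 1.0 if graph.has_edge(v, w) else 0.0
                eq += (a_vw - degree[v] * degree[w] / two_m) / (
                    o_count[v] * o_count[w]
                )
    return eq / two_m


# ---------------------------------------------------------------------------
# EAGLE agglomeration
# ---------------------------------------------------------------------------

@dataclass
class MergeDendrogram:
    """Merge history of the agglomeration, with EQ at every level.

    ``levels[i]`` is the cover before the i-th merge (level 0 = initial
    communities); ``eq_levels[i]`` its extended modularity; ``steps[i]`` the
    pair merged at that level with its similarity.
    """

    levels: list[list[frozenset]] = field(default_factory=list)
    eq_levels: list[float] = field(default_factory=list)
    steps: list[tuple[frozenset, frozenset, float]] = field(default_factory=list)


@dataclass
class CommunityCover:
    """Overlapping communities covering every graph node, with their EQ."""

    communities: list[set] = field(default_factory=list)
    eq: float = 0.0

    def membership_counts(self) -> dict:
        counts: dict = {}
        for c in self.communities:
            for v in c:
                counts[v] = counts.get(v, 0) + 1
        return counts


def _seed_communities(graph: nx.Graph, min_clique_size: int) -> list[frozenset]:
    """Retained maximal cliques plus singletons for subordinate vertices."""
    big = [c for c in maximal_cliques(graph) if len(c) >= min_clique_size]
    # Subordinate cliques: every vertex also in another, larger retained clique.
    retained: list[tuple] = []
    by_size = sorted(big, key=lambda c: (len(c), c))
    for clique in by_size:
        others = [c for c in big if c != clique and len(c) > len(clique)]
        covered = all(any(v in c for c in others) for v in clique)
        if not covered:
            retained.append(clique)
    clique_nodes = set(itertools.chain.from_iterable(retained))
    communities = [frozenset(c) for c in sorted(retained)]
    for v in sorted(set(graph.nodes) - clique_nodes):
        communities.append(frozenset([v]))
    return communities


def _similarity(
    c1: frozenset, c2: frozenset, graph: nx.Graph, degree: dict, two_m: float
) -> float:
    """Modularity-style similarity between two communities.

    S = (1/2m) sum over v in C1, w in C2, v != w of [A_vw - k_v k_w / 2m].
    """
    s = 0.0
    for v in c1:
        for w in c2:
            if v == w:
                continue
            a_vw = 1.0 if graph.has_edge(v, w) else 0.0
            s += a_vw - degree[v] * degree[w] / two_m
    return s / two_m


def _sort_key(c: frozenset) -> tuple:
    return tuple(sorted(c))


def eagle_cluster(
    graph: nx.Graph, min_clique_size: int | None = None
) -> tuple[MergeDendrogram, CommunityCover]:
    """EAGLE-style overlapping clustering of ``graph``.

    ``min_clique_size`` defaults to 2 for bipartite graphs (which are
    triangle-free) and 3 otherwise.  Connected components are agglomerated
    independently and the union cover is scored globally; within the
    dendrogram, similarity ties break toward the lexicographically smallest
    community pair.  Returns the merge dendrogram and the EQ-maximizing
    cover (subordinate vertices are retained as singletons when that level
    wins).
    """
    if graph.number_of_nodes() == 0:
        return MergeDendrogram(), CommunityCover([], 0.0)
    if min_clique_size is None:
        min_clique_size = 2 if nx.is_bipartite(graph) else 3
        log.info(
            "eagle_cluster: min_clique_size defaulted to %d (%s graph)",
            min_clique_size,
            "bipartite" if min_clique_size == 2 else "general",
        )

    degree = dict(graph.degree())
    two_m = 2.0 * graph.number_of_edges()
    dendrogram = MergeDendrogram()
    chosen: list[set] = []

    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c))
    for component in components:
        sub = graph.subgraph(component)
        communities = _seed_communities(sub, min_clique_size)
        if two_m == 0:
            chosen.extend(set(c) for c in communities)
            continue
        # Record every level of this component's own dendrogram; EQ decomposes
        # additively over communities, so per-component argmax gives the
        # globally optimal cut combination.
        comp_levels: list[list[frozenset]] = []
        while True:
            comp_levels.append(list(communities))
            if len(communities) == 1:
                break
            best = None
            ordered = sorted(communities, key=_sort_key)
            for c1, c2 in itertools.combinations(ordered, 2):
                s = _similarity(c1, c2, graph, degree, two_m)
                if best is None or s > best[0] + 1e-12:
                    best = (s, c1, c2)
            s, c1, c2 = best
            dendrogram.steps.append((c1, c2, s))
            communities = [c for c in communities if c is not c1 and c is not c2]
            communities.append(c1 | c2)

        comp_eqs = [
            extended_modularity(graph, [set(c) for c in level])
            # Scored on the component alone: membership counts and degrees of
            # other components are unaffected by this component's cut.
            for level in comp_levels
        ]
        best_idx = max(range(len(comp_eqs)), key=lambda i: comp_eqs[i])
        chosen.extend(set(c) for c in comp_levels[best_idx])
        dendrogram.levels.extend(comp_levels)
        dendrogram.eq_levels.extend(comp_eqs)

    cover = CommunityCover(chosen, extended_modularity(graph, chosen))
    return dendrogram, cover


def select_top_clusters(cover: CommunityCover, graph: nx.Graph) -> pd.DataFrame:
    """Rank the cover's communities for reporting.

    Order: node count (descending), then induced edge count (descending),
    then sorted member names.  Columns mirror the published cluster tables:
    cluster rank, member miRNAs, member genes, node count, edge count, and
    the cover's EQ.
    """
    rows = []
    for community in cover.communities:
        members = sorted(community, key=str)
        induced = graph.subgraph(community)
        mirnas = [v for v in members if graph.nodes[v].get("kind") == "miRNA"]
        genes = [v for v in members if graph.nodes[v].get("kind") != "miRNA"]
        rows.append(
            {
                "mirnas": ";".join(str(v) for v in mirnas),
                "genes": ";".join(str(v) for v in genes),
                "nodes": len(members),
                "edges": induced.number_of_edges(),
                "modularity": cover.eq,
                "_members": tuple(str(v) for v in members),
            }
        )
    rows.sort(key=lambda r: (-r["nodes"], -r["edges"], r["_members"]))
    df = pd.DataFrame(rows).drop(columns="_members")
    df.insert(0, "cluster", range(1, len(rows) + 1))
    return df
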