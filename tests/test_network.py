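import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from icdmir.errors import ConfigurationError
from icdmir.network import (
    CommunityCover,
    ImmunogenicPair,
    build_pairs,
    eagle_cluster,
    extended_modularity,
    maximal_cliques,
    pairs_to_graph,
    select_top_clusters,
)
from icdmir.signature import ICDSignature
from icdmir.targets import TargetPrediction


def oracle_cliques(graph):
    """Exhaustive maximal-clique enumeration for n <= 10."""
    nodes = sorted(graph.nodes)
    cliques = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                cliques.append(set(subset))
    maximal = [
        tuple(sorted(c)) for c in cliques
        if not any(c < other for other in cliques)
    ]
    return sorted(maximal)


def oracle_eq(graph, cover):
    """Literal double-sum extended modularity."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    o = {}
    for c in cover:
        for v in c:
            o[v] = o.get(v, 0) + 1
    deg = dict(graph.degree())
    total = 0.0
    for c in cover:
        for v in c:
            for w in c:
                a = 1.0 if graph.has_edge(v, w) else 0.0
                total += (a - deg[v] * deg[w] / (2 * m)) / (o[v] * o[w])
    return total / (2 * m)


def two_triangles():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                      ("d", "e"), ("e", "f"), ("d", "f"), ("c", "d")])
    return g


class TestBuildPairs:
    SIG = ICDSignature(up={"m_up"}, down={"m_down"})
    MRNA = pd.DataFrame(
        {"signed_fc": [-2.0, 2.0, -2.0], "p": [0.01, 0.01, 0.01],
         "p_adj": [0.02, 0.02, 0.02]},
        index=["g_down", "g_up", "g_down_nogo"],
    )

    def _preds(self, score=0.95):
        return [
            TargetPrediction("m_up", "g_down", score),
            TargetPrediction("m_up", "g_down_nogo", score),
            TargetPrediction("m_down", "g_up", score),
            TargetPrediction("m_up", "g_up", score),  # same direction: no pair
        ]

    def test_emits_only_fully_qualified_pairs(self):
        pairs = build_pairs(
            self.SIG, self.MRNA, self._preds(), go_genes={"g_down", "g_up"}
        )
        assert {(p.mirna_id, p.gene_id) for p in pairs} == {
            ("m_up", "g_down"), ("m_down", "g_up")
        }
        for p in pairs:
            assert p.mirna_direction != p.gene_direction
            assert p.score >= 0.9
            assert p.in_go_term

    def test_go_term_filter_drops_unannotated_gene(self):
        pairs = build_pairs(self.SIG, self.MRNA, self._preds(), go_genes={"g_up"})
        assert {(p.mirna_id, p.gene_id) for p in pairs} == {("m_down", "g_up")}

    def test_score_threshold_enforced(self):
        pairs = build_pairs(
            self.SIG, self.MRNA, self._preds(score=0.8),
            go_genes={"g_down", "g_up"},
        )
        assert pairs == []

    def test_empty_go_genes_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_pairs(self.SIG, self.MRNA, self._preds(), go_genes=set())

    def test_synthetic_pairs_satisfy_all_criteria(self, default_dataset):
        ds = default_dataset
        from icdmir.targets import predict_targets

        preds = predict_targets(ds.mirna_fasta, ds.transcript_fasta)
        mrna = pd.DataFrame(
            {
                "signed_fc": [
                    4.0 if d == "up" else -4.0
                    for d in ds.truth_genes["direction"]
                ],
                "p": 1e-6,
            },
            index=ds.truth_genes["feature_id"].tolist(),
        )
        go = ds.gene_sets["GO:0002376"]
        pairs = build_pairs(ds.truth_mirna_signature, mrna, preds, go)
        assert pairs
        for p in pairs:
            assert p.mirna_direction != p.gene_direction
            assert p.gene_id in go
            assert p.score >= 0.9


class TestMaximalCliques:
    def test_complete_graph(self):
        assert maximal_cliques(nx.complete_graph(4)) == [(0, 1, 2, 3)]

    def test_path_graph(self):
        g = nx.Graph([("a", "b"), ("b", "c")])
        assert maximal_cliques(g) == [("a", "b"), ("b", "c")]

    def test_triangle_with_pendant(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4)])
        assert maximal_cliques(g) == [(1, 2, 3), (3, 4)]

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 11))
            p = float(rng.uniform(0.1, 0.9))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2 ** 31)))
            assert maximal_cliques(g) == oracle_cliques(g)


class TestExtendedModularity:
    def test_whole_graph_single_community_is_zero(self):
        g = two_triangles()
        assert extended_modularity(g, [set(g.nodes)]) == pytest.approx(0.0)

    def test_singleton_cover_matches_closed_form(self):
        g = two_triangles()
        cover = [{v} for v in g.nodes]
        m = g.number_of_edges()
        expected = -sum(d * d for _, d in g.degree()) / (2 * m) ** 2
        assert extended_modularity(g, cover) == pytest.approx(expected)
        assert extended_modularity(g, cover) == pytest.approx(oracle_eq(g, cover))

    def test_non_overlapping_cover_equals_newman_modularity(self):
        g = two_triangles()
        cover = [{"a", "b", "c"}, {"d", "e", "f"}]
        newman = nx.algorithms.community.modularity(g, cover)
        assert extended_modularity(g, cover) == pytest.approx(newman)
        assert newman == pytest.approx(6 / 7 - 0.5)

    def test_overlapping_cover_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            g = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(0, 2 ** 31)))
            if g.number_of_edges() == 0:
                continue
            nodes = sorted(g.nodes)
            cover = []
            for _ in range(3):
                size = int(rng.integers(1, 6))
                cover.append(set(rng.choice(nodes, size=size, replace=False)))
            for v in nodes:
                if not any(v in c for c in cover):
                    cover.append({v})
            assert extended_modularity(g, cover) == pytest.approx(
                oracle_eq(g, cover)
            )

    def test_empty_graph_convention(self):
        assert extended_modularity(nx.Graph(), []) == 0.0


class TestEagleCluster:
    def test_two_triangles_recovered_with_hand_eq(self):
        g = two_triangles()
        dendrogram, cover = eagle_cluster(g, min_clique_size=3)
        communities = sorted(tuple(sorted(c)) for c in cover.communities)
        assert communities == [("a", "b", "c"), ("d", "e", "f")]
        assert cover.eq == pytest.approx(6 / 7 - 0.5)

    def test_bipartite_defaults_to_edge_seeds(self):
        g = nx.Graph()
        edges = [("m1", "g1"), ("m1", "g2"), ("m2", "g2")]
        for u, v in edges:
            g.add_node(u, kind="miRNA")
            g.add_node(v, kind="gene")
            g.add_edge(u, v)
        _, cover = eagle_cluster(g)  # default min_clique_size = 2
        assert all(len(c) >= 2 for c in cover.communities) or len(
            cover.communities
        ) == 1
        covered = set().union(*cover.communities)
        assert covered == set(g.nodes)

    def test_bipartite_with_triangle_seed_size_yields_singletons(self):
        g = nx.Graph([("m1", "g1"), ("m1", "g2")])
        dendrogram, cover = eagle_cluster(g, min_clique_size=3)
        assert set().union(*cover.communities) == set(g.nodes)
        assert dendrogram.levels[0] == [
            frozenset({"g1"}), frozenset({"g2"}), frozenset({"m1"})
        ]

    def test_returned_cover_maximizes_eq_over_levels(self):
        g = nx.gnp_random_graph(30, 0.2, seed=0)
        dendrogram, cover = eagle_cluster(g, min_clique_size=3)
        assert dendrogram.eq_levels
        assert cover.eq >= max(dendrogram.eq_levels) - 1e-12
        # and every level's recorded EQ is the honest brute-force value
        idx = int(np.argmax(dendrogram.eq_levels))
        level_cover = [set(c) for c in dendrogram.levels[idx]]
        assert dendrogram.eq_levels[idx] == pytest.approx(
            oracle_eq(g, level_cover)
        )

    def test_every_node_covered(self):
        g = nx.gnp_random_graph(25, 0.15, seed=3)
        _, cover = eagle_cluster(g, min_clique_size=3)
        assert set().union(*cover.communities) == set(g.nodes)

    def test_empty_graph(self):
        dendrogram, cover = eagle_cluster(nx.Graph())
        assert cover.communities == [] and cover.eq == 0.0


class TestSelectTopClusters:
    def _graph(self):
        pairs = [
            ImmunogenicPair("m1", f"g{i}", "up", "down", 0.95) for i in range(4)
        ] + [ImmunogenicPair("m2", "h1", "down", "up", 0.95),
             ImmunogenicPair("m2", "h2", "down", "up", 0.95)]
        return pairs_to_graph(pairs)

    def test_larger_cluster_ranks_first(self):
        g = self._graph()
        cover = CommunityCover(
            [{"m1", "g0", "g1", "g2", "g3"}, {"m2", "h1", "h2"}], eq=0.4
        )
        df = select_top_clusters(cover, g)
        assert df.iloc[0]["nodes"] == 5
        assert df.iloc[0]["mirnas"] == "m1"
        assert (df["modularity"] == 0.4).all()

    def test_edge_count_breaks_node_ties(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6)])
        cover = CommunityCover([{1, 2, 3}, {4, 5, 6}], eq=0.1)
        df = select_top_clusters(cover, g)
        assert df.iloc[0]["edges"] == 3 and df.iloc[1]["edges"] == 2

    def test_synthetic_top_cluster_contains_planted_regulator(
        self, default_dataset
    ):
        ds = default_dataset
        from icdmir.targets import predict_targets

        preds = predict_targets(ds.mirna_fasta, ds.transcript_fasta)
        mrna = pd.DataFrame(
            {
                "signed_fc": [
                    4.0 if d == "up" else -4.0
                    for d in ds.truth_genes["direction"]
                ],
                "p": 1e-6,
            },
            index=ds.truth_genes["feature_id"].tolist(),
        )
        pairs = build_pairs(
            ds.truth_mirna_signature, mrna, preds, ds.gene_sets["GO:0002376"]
        )
        g = pairs_to_graph(pairs)
        _, cover = eagle_cluster(g)
        df = select_top_clusters(cover, g)
        planted = set(ds.truth_mirnas["feature_id"])
        assert set(df.iloc[0]["mirnas"].split(";")) & planted
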