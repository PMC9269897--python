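"""Co-occurrence, weighted Jaccard, Louvain, and PageRank."""

import networkx as nx
import networkx.algorithms.community as nxc
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import snowsem as ss
from snowsem.data import AssociationDataset
from snowsem.network import CooccurrenceMatrix, _modularity_array


def _dataset_from_level2(pairs, demo_ids=("p1",)):
    rows = [("p1", 1, "risk", pd.NA, 1, "a")]
    for i, (pid, cue, resp) in enumerate(pairs, start=1):
        rows.append((pid, 2, cue, 1, i, resp))
    records = pd.DataFrame(
        rows, columns=["participant_id", "level", "cue", "cue_position", "position", "response"]
    )
    demo = pd.DataFrame(
        {"participant_id": list(demo_ids), "age_bin": [1] * len(demo_ids),
         "gender": ["f"] * len(demo_ids)}
    )
    return AssociationDataset(records, demo)


class TestCooccurrence:
    def test_direct_counts(self):
        data = _dataset_from_level2(
            [("p1", "a", "b"), ("p1", "a", "b"), ("p1", "a", "c")]
        )
        C = ss.build_cooccurrence(data, ["a"])
        assert C.counts.loc["a", "b"] == 2
        assert C.counts.loc["a", "c"] == 1

    def test_additivity_over_participants(self):
        pairs = [("p1", "a", "b"), ("p2", "a", "b")]
        C = ss.build_cooccurrence(_dataset_from_level2(pairs, ("p1", "p2")), ["a"])
        assert C.counts.loc["a", "b"] == 2

    def test_ineligible_cues_dropped_and_logged(self):
        data = _dataset_from_level2([("p1", "a", "b"), ("p1", "zzz", "b")])
        C = ss.build_cooccurrence(data, ["a"])
        assert C.n_dropped == 1

    def test_row_sums_equal_retained_level2_tokens(self, small_study, small_network):
        C = small_network.cooccurrence
        l2 = small_network.dataset.level2()
        per_cue = l2[l2["cue"].isin(C.words)].groupby("cue").size()
        assert (C.counts.sum(axis=1).sort_index() == per_cue.sort_index()).all()

    def test_disjoint_components_have_disjoint_support(self):
        study = ss.generate_study(ss.default_config(n_participants=120, leakage=0.0, seed=6))
        net = ss.build_semantic_network(study.dataset, min_count=3, seed=6)
        home = study.lexicon["component"]
        C = net.cooccurrence.counts
        for w in C.index[:20]:
            support = C.columns[C.loc[w] > 0]
            assert set(home[support]) == {home[w]}


class TestWeightedJaccard:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([2, 1, 0], [1, 1, 1], 0.5),
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 0], [0, 2], 0.0),
            ([0, 0], [0, 0], 0.0),
        ],
    )
    def test_examples(self, x, y, expected):
        assert ss.weighted_jaccard(np.array(x), np.array(y)) == pytest.approx(expected)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            ss.weighted_jaccard(np.array([-1, 2]), np.array([1, 1]))

    @given(
        hnp.arrays(np.float64, 6, elements=st.floats(0, 50)),
        hnp.arrays(np.float64, 6, elements=st.floats(0, 50)),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bounds_and_symmetry(self, x, y):
        j = ss.weighted_jaccard(x, y)
        assert 0.0 <= j <= 1.0
        assert j == pytest.approx(ss.weighted_jaccard(y, x))


class TestSimilarityMatrix:
    def test_matches_bruteforce_loop(self, rng):
        X = rng.integers(0, 6, size=(10, 15))
        counts = pd.DataFrame(X, index=[f"w{i}" for i in range(10)])
        S = ss.similarity_matrix(CooccurrenceMatrix(counts))
        for i in range(10):
            for j in range(10):
                expected = 1.0 if i == j else ss.weighted_jaccard(X[i], X[j])
                assert S.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_duplicate_rows_fully_similar(self):
        counts = pd.DataFrame([[1, 2], [1, 2]], index=["a", "b"])
        S = ss.similarity_matrix(CooccurrenceMatrix(counts))
        assert S.loc["a", "b"] == 1.0

    def test_row_permutation_equivariance(self, rng):
        X = rng.integers(0, 5, size=(8, 10))
        words = [f"w{i}" for i in range(8)]
        S = ss.similarity_matrix(CooccurrenceMatrix(pd.DataFrame(X, index=words)))
        perm = rng.permutation(8)
        S2 = ss.similarity_matrix(
            CooccurrenceMatrix(pd.DataFrame(X[perm], index=[words[i] for i in perm]))
        )
        pd.testing.assert_frame_equal(
            S2.sort_index(axis=0).sort_index(axis=1),
            S.sort_index(axis=0).sort_index(axis=1),
        )


class TestBuildNetwork:
    def test_all_positive_gives_complete_graph(self):
        S = pd.DataFrame(0.5, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(S.values, 1.0)
        G = ss.build_network(S)
        assert G.number_of_edges() == 3

    def test_edge_count_matches_positive_upper_triangle(self, small_network):
        S = small_network.similarity.to_numpy()
        iu, ju = np.triu_indices(len(S), k=1)
        assert small_network.graph.number_of_edges() == int((S[iu, ju] > 0).sum())

    def test_threshold_one_keeps_only_duplicates(self):
        S = pd.DataFrame([[1.0, 1.0, 0.4], [1.0, 1.0, 0.4], [0.4, 0.4, 1.0]],
                         index=list("abc"), columns=list("abc"))
        G = ss.build_network(S, min_weight=0.999)
        assert set(map(frozenset, G.edges)) == {frozenset(("a", "b"))}

    def test_edgeless_graph_rejected(self):
        S = pd.DataFrame(np.eye(3), index=list("abc"), columns=list("abc"))
        with pytest.raises(ValueError):
            ss.build_network(S)


class TestModularity:
    def test_single_community_is_zero(self):
        G = nx.karate_club_graph()
        assert ss.modularity(G, {v: 0 for v in G}) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        G = nx.Graph()
        G.add_edges_from([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        labels = {v: v // 3 for v in G}
        assert ss.modularity(G, labels) == pytest.approx(0.5)

    def test_singletons_negative_on_loop_free_graph(self):
        G = nx.path_graph(5)
        assert ss.modularity(G, {v: v for v in G}) < 0

    def test_unlabeled_node_rejected(self):
        G = nx.path_graph(3)
        with pytest.raises(ValueError):
            ss.modularity(G, {0: 0, 1: 0})

    def test_agrees_with_networkx(self, small_network):
        part = small_network.partition
        comms = [set(ws) for ws in part.communities().values()]
        expected = nxc.modularity(small_network.graph, comms, weight="weight")
        assert part.modularity == pytest.approx(expected, abs=1e-10)


class TestLouvain:
    def test_two_cliques_bridged(self):
        G = nx.Graph()
        for base in (0, 4):
            for i in range(4):
                for j in range(i + 1, 4):
                    G.add_edge(base + i, base + j, weight=1.0)
        G.add_edge(0, 4, weight=1.0)
        part = ss.louvain(G, seed=0)
        groups = {frozenset(part.members(c)) for c in range(part.n_communities)}
        assert groups == {frozenset({0, 1, 2, 3}), frozenset({4, 5, 6, 7})}

    def test_complete_graph_single_community(self):
        part = ss.louvain(nx.complete_graph(4), seed=0)
        assert part.n_communities == 1
        assert part.modularity == pytest.approx(0.0)

    def test_seeded_determinism(self, small_network):
        again = ss.louvain(small_network.graph, seed=42, restarts=10)
        assert again.labels == small_network.partition.labels

    def test_never_below_trivial_partition(self, rng):
        for _ in range(10):
            G = nx.gnp_random_graph(12, 0.3, seed=int(rng.integers(1 << 16)))
            if G.number_of_edges() == 0:
                continue
            part = ss.louvain(G, seed=1)
            assert part.modularity >= -1e-12

    def test_quality_not_worse_than_networkx(self, small_network):
        ours = small_network.partition.modularity
        comms = nxc.louvain_communities(small_network.graph, weight="weight", seed=0)
        theirs = nxc.modularity(small_network.graph, comms, weight="weight")
        assert ours >= theirs - 1e-9

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            ss.louvain(nx.Graph(), seed=0)


class TestPagerank:
    def test_regular_graph_uniform(self):
        G = nx.cycle_graph(6)
        pr = ss.pagerank(G)
        for v in G:
            assert pr[v] == pytest.approx(1 / 6, abs=1e-10)

    def test_scores_sum_to_one(self, small_network):
        assert sum(small_network.pagerank.values()) == pytest.approx(1.0, abs=1e-12)

    def test_path_graph_matches_linear_solve(self):
        G = nx.path_graph(3)
        d = 0.85
        A = nx.to_numpy_array(G)
        M = A / A.sum(axis=0)
        x = np.linalg.solve(np.eye(3) - d * M, (1 - d) / 3 * np.ones(3))
        x /= x.sum()
        pr = ss.pagerank(G, damping=d)
        for v in G:
            assert pr[v] == pytest.approx(x[v], abs=1e-8)

    def test_edgeless_rejected(self):
        G = nx.Graph()
        G.add_nodes_from([1, 2])
        with pytest.raises(ValueError):
            ss.pagerank(G)
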