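"""Retrieval proportions, sentiment propagation, risk similarity,
and cross-language comparison."""

import numpy as np
import pandas as pd
import pytest

import snowsem as ss
from snowsem.data import AssociationDataset
from snowsem.network import CooccurrenceMatrix, Partition
from snowsem.profiles import (
    component_sentiment,
    crosslingual_compare,
    focal_profile,
    infer_sentiment,
    retrieval_proportions,
    risk_similarity,
    swow_profiles,
)


def _partition(labels):
    return Partition(labels=labels, modularity=0.0)


def _toy_l1(tokens):
    rows = [
        (f"p{i}", 1, "risk", pd.NA, 1, tok) for i, tok in enumerate(tokens)
    ]
    records = pd.DataFrame(
        rows, columns=["participant_id", "level", "cue", "cue_position", "position", "response"]
    )
    demo = pd.DataFrame(
        {"participant_id": [f"p{i}" for i in range(len(tokens))],
         "age_bin": [1 + i % 6 for i in range(len(tokens))],
         "gender": [("f", "m")[i % 2] for i in range(len(tokens))]})
    return AssociationDataset(records, demo)


class TestRetrievalProportions:
    def test_direct_counts(self):
        data = _toy_l1(["a", "a", "a", "b"])
        part = _partition({"a": 0, "b": 1})
        props = retrieval_proportions(data, part)
        assert props.loc["overall", "component_0"] == pytest.approx(0.75)
        assert props.loc["overall", "component_1"] == pytest.approx(0.25)

    def test_single_component_everywhere_one(self):
        data = _toy_l1(["a", "b", "a", "b"])
        part = _partition({"a": 0, "b": 0})
        props = retrieval_proportions(data, part, by="gender")
        assert np.allclose(props.to_numpy(), 1.0)

    def test_rows_sum_to_one_by_position(self, small_study, small_network):
        props = retrieval_proportions(
            small_study.dataset, small_network.partition, by="position"
        )
        assert np.allclose(props.sum(axis=1), 1.0, atol=1e-12)

    def test_out_of_network_tokens_conserved(self, small_study, small_network):
        props = retrieval_proportions(small_study.dataset, small_network.partition)
        total_l1 = len(small_study.dataset.level1())
        assert props.attrs["n_included"] + props.attrs["n_excluded"] == total_l1


class TestInferSentiment:
    def _C(self):
        counts = pd.DataFrame(
            [[2, 2, 0], [0, 0, 4]], index=["w1", "w2"], columns=["a", "b", "c"]
        )
        return CooccurrenceMatrix(counts)

    def test_average_of_own_and_associates(self):
        lex = pd.Series({"w1": 0.4, "a": 0.1, "b": 0.3})
        # assoc(w1) = (2*0.1 + 2*0.3)/4 = 0.2 -> (0.4 + 0.2)/2 = 0.3
        inferred = infer_sentiment(lex, self._C())
        assert inferred["w1"] == pytest.approx(0.3)

    def test_fallback_to_associates_only(self):
        lex = pd.Series({"a": 0.1, "b": 0.3})
        inferred = infer_sentiment(lex, self._C())
        assert inferred["w1"] == pytest.approx(0.2)

    def test_own_only_when_no_associate_covered(self):
        lex = pd.Series({"w2": -0.5})
        inferred = infer_sentiment(lex, self._C())
        assert inferred["w2"] == pytest.approx(-0.5)

    def test_missing_when_no_information(self):
        inferred = infer_sentiment(pd.Series(dtype=float), self._C())
        assert inferred.isna().all()

    def test_fixed_point_when_all_scores_equal(self):
        lex = pd.Series({"w1": 0.7, "a": 0.7, "b": 0.7, "c": 0.7})
        inferred = infer_sentiment(lex, self._C())
        assert inferred["w1"] == pytest.approx(0.7)

    def test_stays_in_unit_interval(self, small_study, small_network):
        inferred = infer_sentiment(
            small_study.lexicon["sentiment"], small_network.cooccurrence
        )
        assert inferred.dropna().between(-1, 1).all()


class TestComponentSentiment:
    def test_constant_scores_degenerate_ci(self):
        part = _partition({"a": 0, "b": 0, "c": 1})
        scores = pd.Series({"a": 0.4, "b": 0.4, "c": -0.2})
        table = component_sentiment(scores, part, B=100, seed=0)
        assert table.loc[0, "mean_sentiment"] == pytest.approx(0.4)
        assert table.loc[0, "ci_lo"] == pytest.approx(0.4)
        assert table.loc[0, "ci_hi"] == pytest.approx(0.4)

    def test_ci_brackets_point_estimate(self, small_study, small_network):
        inferred = infer_sentiment(
            small_study.lexicon["sentiment"], small_network.cooccurrence
        )
        table = component_sentiment(inferred, small_network.partition, B=200, seed=1)
        ok = table.dropna()
        assert (ok["ci_lo"] <= ok["mean_sentiment"] + 1e-12).all()
        assert (ok["ci_hi"] >= ok["mean_sentiment"] - 1e-12).all()

    def test_planted_means_recovered_without_noise(self):
        study = ss.generate_study(
            ss.default_config(n_participants=200, sentiment_means=(0.5, -0.5, 0.1, -0.1, 0.0),
                              sentiment_sd=0.0, leakage=0.0, seed=12)
        )
        net = ss.build_semantic_network(study.dataset, min_count=3, seed=12)
        inferred = infer_sentiment(study.lexicon["sentiment"], net.cooccurrence)
        table = component_sentiment(inferred, net.partition, B=50, seed=0)
        planted = study.lexicon["component"]
        for comp, members in net.partition.communities().items():
            k = planted[members[0]]
            expected = (0.5, -0.5, 0.1, -0.1, 0.0)[k]
            assert table.loc[comp, "mean_sentiment"] == pytest.approx(expected, abs=1e-9)


class TestRiskSimilarity:
    def test_identical_profile_similarity_one(self):
        counts = pd.DataFrame([[3, 1], [0, 5]], index=["w1", "w2"], columns=["a", "b"])
        C = CooccurrenceMatrix(counts)
        part = _partition({"w1": 0, "w2": 1})
        per_word, _ = risk_similarity(C, part, np.array([3.0, 1.0]), B=10, seed=0)
        assert per_word["w1"] == pytest.approx(1.0)

    def test_disjoint_support_zero(self):
        counts = pd.DataFrame([[0, 5]], index=["w"], columns=["a", "b"])
        per_word, _ = risk_similarity(
            CooccurrenceMatrix(counts), _partition({"w": 0}), np.array([2.0, 0.0]),
            B=10, seed=0,
        )
        assert per_word["w"] == 0.0

    def test_matches_bruteforce(self, small_study, small_network, rng):
        C = small_network.cooccurrence
        focal = focal_profile(small_study.dataset, C)
        per_word, _ = risk_similarity(C, small_network.partition, focal, B=10, seed=0)
        for w in rng.choice(C.words, size=5, replace=False):
            assert per_word[w] == pytest.approx(ss.weighted_jaccard(C.row(w), focal))

    def test_empty_projection_rejected(self, small_study, small_network):
        with pytest.raises(ValueError):
            empty = small_study.dataset.copy()
            empty.records = empty.records[empty.records["level"] == 2]
            focal_profile(empty, small_network.cooccurrence)


class TestCrosslingual:
    def test_self_comparison_is_exact(self, small_network):
        res = crosslingual_compare(
            small_network.similarity, small_network.similarity, small_network.partition
        )
        assert res.pairwise_correlation == 1.0
        pd.testing.assert_frame_equal(res.block_means_ref, res.block_means_other)

    def test_planted_structure_within_exceeds_between(self):
        sims = []
        for seed in (21, 22):
            study = ss.generate_study(
                ss.default_config(n_participants=400, words_per_component=20,
                                  leakage=0.05, seed=seed)
            )
            net = ss.build_semantic_network(study.dataset, min_count=3, seed=seed)
            sims.append((net.similarity, net.partition))
        (S1, part), (S2, _) = sims
        res = crosslingual_compare(S1, S2, part)
        for blocks in (res.block_means_ref, res.block_means_other):
            diag = np.diag(blocks.to_numpy())
            off = blocks.to_numpy()[~np.eye(len(blocks), dtype=bool)]
            assert np.nanmin(diag) > np.nanmax(off)
        assert res.pairwise_correlation > 0.5

    def test_term_map_restricts_pairs(self, small_network):
        S = small_network.similarity
        words = list(S.index)
        kept = words[: len(words) // 2]
        # other language uses prefixed names; map only half of them back
        renamed = S.rename(index=lambda w: "x_" + w, columns=lambda w: "x_" + w)
        term_map = {"x_" + w: w for w in kept}
        res = crosslingual_compare(S, renamed, small_network.partition, term_map=term_map)
        assert res.n_shared_terms == len(kept)
        assert res.n_pairs == len(kept) * (len(kept) - 1) // 2

    def test_too_few_shared_terms_rejected(self, small_network):
        S = small_network.similarity
        other = S.iloc[:2, :2]
        with pytest.raises(ValueError):
            crosslingual_compare(S, other, small_network.partition)

    def test_swow_profiles_flatten_counts(self):
        table = pd.DataFrame(
            {"cue": ["a", "a", "b"], "response": ["x", "y", "x"], "count": [3, 1, 2]}
        )
        prof = swow_profiles(table)
        assert prof.loc["a", "x"] == 3
        assert prof.loc["b", "y"] == 0
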