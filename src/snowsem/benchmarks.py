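"""Validation harnesses: oracle equivalence, planted-structure recovery,
and statistical calibration of the pipeline on synthetic data.

These functions regenerate data and recompute every quantity from scratch;
they exist so that the same checks can be run from the test suite and from
reporting scripts.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterator

import networkx as nx
import numpy as np
import pandas as pd

from . import simulate
from .data import AssociationDataset
from .network import _modularity_array, louvain, pagerank, similarity_matrix
from .network import CooccurrenceMatrix, weighted_jaccard
from .pipeline import build_semantic_network
from .prediction import component_features, cv_elastic_net, fit_item_regressions
from .preprocessing import filter_dataset
from .profiles import component_sentiment, infer_sentiment
from .group_diffs import group_effect_table
from .simulate import default_config, generate_study
from .stability import stability_analysis

__all__ = [
    "louvain_vs_exhaustive",
    "pagerank_vs_dense_solve",
    "similarity_vs_bruteforce",
    "planted_recovery_aris",
    "zero_leakage_exactness",
    "group_test_type1_rates",
    "regression_null_rejection_rate",
    "sentiment_rank_recovery",
    "loading_sign_recovery",
    "cv_r2_planted_and_noise",
]


# ---------------------------------------------------------------------------
# Oracle equivalence


def _set_partitions(n: int) -> Iterator[np.ndarray]:
    """All set partitions of n items as restricted-growth label vectors."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, mx: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(mx + 1):
            labels[i] = c
            yield from rec(i + 1, mx + 1 if c == mx else mx)

    yield from rec(0, 0)


def _random_weighted_graph(rng: np.random.Generator) -> tuple[nx.Graph, np.ndarray]:
    n = int(rng.integers(4, 9))
    p = rng.uniform(0.3, 0.9)
    while True:
        A = (rng.random((n, n)) < p) * rng.uniform(0.1, 1.0, (n, n))
        A = np.triu(A, 1)
        A = A + A.T
        if A.sum() > 0:
            break
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if A[i, j] > 0:
                G.add_edge(i, j, weight=float(A[i, j]))
    return G, A


def louvain_vs_exhaustive(
    n_graphs: int = 100, seed: int = 42, restarts: int = 50
) -> dict:
    """Fraction of small random weighted graphs on which Louvain attains the
    exhaustive maximum-modularity partition (graphs of 4-8 nodes)."""
    rng = np.random.default_rng(seed)
    hits = 0
    worst_gap = 0.0
    for g in range(n_graphs):
        G, A = _random_weighted_graph(rng)
        best = max(_modularity_array(A, lab) for lab in _set_partitions(len(A)))
        part = louvain(G, seed=g, restarts=restarts)
        gap = best - part.modularity
        worst_gap = max(worst_gap, gap)
        hits += gap <= 1e-9
    return {"agreement_rate": hits / n_graphs, "worst_gap": worst_gap, "n": n_graphs}


def pagerank_vs_dense_solve(n_graphs: int = 20, seed: int = 1, damping: float = 0.85) -> dict:
    """Max |error| of power-iteration PageRank vs the dense linear solve."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_graphs):
        G, A = _random_weighted_graph(rng)
        # drop isolated nodes: the damped-walk solve below assumes outdegree > 0
        deg = A.sum(axis=1)
        keep = np.where(deg > 0)[0]
        G = G.subgraph(keep).copy()
        if G.number_of_edges() == 0:
            continue
        A = A[np.ix_(keep, keep)]
        n = len(keep)
        M = A / A.sum(axis=0)
        x = np.linalg.solve(np.eye(n) - damping * M, (1 - damping) / n * np.ones(n))
        x /= x.sum()
        pr = pagerank(G, damping=damping)
        worst = max(worst, max(abs(pr[v] - x[i]) for i, v in enumerate(keep)))
    return {"max_abs_error": worst, "n": n_graphs}


def similarity_vs_bruteforce(n_rows: int = 30, n_cols: int = 40, seed: int = 2) -> dict:
    """Max |difference| between the similarity matrix and a naive pair loop."""
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 7, size=(n_rows, n_cols))
    counts = pd.DataFrame(X, index=[f"w{i}" for i in range(n_rows)])
    S = similarity_matrix(CooccurrenceMatrix(counts)).to_numpy()
    worst = 0.0
    for i in range(n_rows):
        for j in range(n_rows):
            expected = 1.0 if i == j else weighted_jaccard(X[i], X[j])
            worst = max(worst, abs(S[i, j] - expected))
    return {"max_abs_error": worst, "n": n_rows}


# ---------------------------------------------------------------------------
# Planted-structure recovery


def _pipeline_ari(study, seed: int) -> float:
    from sklearn.metrics import adjusted_rand_score

    net = build_semantic_network(study.dataset, min_count=3, seed=seed)
    planted = study.lexicon["component"]
    return float(
        adjusted_rand_score(
            [planted[w] for w in net.vocabulary],
            [net.partition.labels[w] for w in net.vocabulary],
        )
    )


def planted_recovery_aris(
    n_seeds: int = 20,
    n_participants: int = 1000,
    leakage: float = 0.1,
    seed: int = 0,
) -> list[float]:
    """Adjusted Rand index of the recovered vs planted partition per seed."""
    aris = []
    for s in range(n_seeds):
        study = generate_study(
            default_config(n_participants=n_participants, leakage=leakage,
                           seed=seed + s)
        )
        aris.append(_pipeline_ari(study, seed=seed + s))
    return aris


def zero_leakage_exactness(
    n_participants: int = 1000, B: int = 50, seed: int = 0
) -> dict:
    """With no cross-component leakage the component vocabularies have
    disjoint level-2 support: recovery must be exact and every bootstrap
    stability summary 100%."""
    study = generate_study(
        default_config(n_participants=n_participants, leakage=0.0, seed=seed)
    )
    net = build_semantic_network(study.dataset, min_count=3, seed=seed)
    ari = _pipeline_ari(study, seed=seed)
    res = stability_analysis(net.cooccurrence, net.partition, B=B, seed=seed)
    return {"ari": ari, "stability_summaries": res.summary, "B": B}


# ---------------------------------------------------------------------------
# Statistical calibration


def group_test_type1_rates(
    n_datasets: int = 30,
    n_participants: int = 1000,
    min_word_count: int = 20,
    alpha: float = 0.05,
    seed: int = 100,
) -> dict:
    """Empirical type-I error of the age and gender tests under the null
    generator (no demographic effects).

    Words entering the chi-square calibration must reach ``min_word_count``
    level-1 tokens so that the large-sample approximation applies; the age
    test additionally requires retrieval in every age bin.
    """
    age_p: list[float] = []
    gender_p: list[float] = []
    for s in range(n_datasets):
        cfg = default_config(
            n_participants=n_participants,
            age_effects=(0.0,) * 5,
            gender_effects=(0.0,) * 5,
            seed=seed + s,
        )
        study = generate_study(cfg)
        filtered, vocab, _ = filter_dataset(study.dataset, min_count=3)
        counts = filtered.level1()["response"].value_counts()
        words = [w for w in vocab if counts[w] >= min_word_count]
        table = group_effect_table(filtered, words, adjust=False)
        age_p += table.loc[table["age_eligible"], "age_p"].tolist()
        gender_p += table["gender_p"].tolist()
    return {
        "age_type1": float(np.mean(np.asarray(age_p) < alpha)),
        "gender_type1": float(np.mean(np.asarray(gender_p) < alpha)),
        "n_age_tests": len(age_p),
        "n_gender_tests": len(gender_p),
    }


def regression_null_rejection_rate(
    n_datasets: int = 30,
    n_participants: int = 500,
    alpha: float = 0.05,
    seed: int = 500,
) -> dict:
    """Rejection rate of component coefficients when the survey outcome
    carries no component signal (all loadings zero)."""
    pvals: list[float] = []
    for s in range(n_datasets):
        study = generate_study(
            default_config(n_participants=n_participants,
                           survey_loadings=(0.0,) * 5, seed=seed + s)
        )
        net = build_semantic_network(study.dataset, min_count=3, seed=s)
        feats = component_features(study.dataset, net.partition, net.similarity)
        coefs = fit_item_regressions(feats, study.dataset.demographics, study.survey)
        comp = coefs[coefs.index.get_level_values("predictor").str.startswith("component")]
        pvals += comp["p"].tolist()
    return {"rejection_rate": float(np.mean(np.asarray(pvals) < alpha)),
            "n_tests": len(pvals)}


# ---------------------------------------------------------------------------
# Parameter recovery


def _community_to_planted(net, planted: pd.Series) -> dict[int, int]:
    return {
        c: Counter(planted[w] for w in members).most_common(1)[0][0]
        for c, members in net.partition.communities().items()
    }


def sentiment_rank_recovery(
    n_seeds: int = 20,
    n_participants: int = 600,
    means: tuple[float, ...] = (0.8, 0.3, 0.0, -0.3, -0.8),
    seed: int = 300,
) -> dict:
    """Fraction of seeds on which the rank order of planted component
    sentiment means is recovered exactly."""
    ok = 0
    for s in range(n_seeds):
        study = generate_study(
            default_config(n_participants=n_participants, sentiment_means=means,
                           seed=seed + s)
        )
        net = build_semantic_network(study.dataset, min_count=3, seed=s)
        inferred = infer_sentiment(study.lexicon["sentiment"], net.cooccurrence)
        table = component_sentiment(inferred, net.partition, B=200, seed=s)
        mapping = _community_to_planted(net, study.lexicon["component"])
        est = {mapping[c]: table.loc[c, "mean_sentiment"] for c in mapping}
        recovered = sorted(est, key=lambda k: -est[k])
        ok += recovered == sorted(range(len(means)), key=lambda k: -means[k])
    return {"recovery_rate": ok / n_seeds, "n_seeds": n_seeds}


def loading_sign_recovery(
    n_seeds: int = 20, n_participants: int = 1200, seed: int = 200
) -> dict:
    """Fraction of seeds on which every nonzero planted survey loading is
    recovered in sign by the standardized item regressions."""
    cfg0 = default_config()
    loadings = dict(enumerate(cfg0._vector("survey_loadings", 0.0)))
    ok = 0
    for s in range(n_seeds):
        study = generate_study(
            default_config(n_participants=n_participants, seed=seed + s)
        )
        net = build_semantic_network(study.dataset, min_count=3, seed=s)
        feats = component_features(study.dataset, net.partition, net.similarity)
        coefs = fit_item_regressions(feats, study.dataset.demographics, study.survey)
        betas = coefs.loc["general"]["beta"]
        mapping = _community_to_planted(net, study.lexicon["component"])
        est = {mapping[c]: betas[f"component_{c}"] for c in mapping}
        ok += all(
            np.sign(est[k]) == np.sign(v) for k, v in loadings.items() if v != 0
        )
    return {"recovery_rate": ok / n_seeds, "n_seeds": n_seeds}


def cv_r2_planted_and_noise(
    n_participants: int = 1200,
    population_r2: float = 0.3,
    folds: int = 10,
    repeats: int = 2,
    seed: int = 11,
) -> dict:
    """Cross-validated R^2 for a planted linear signal of known population
    R^2 over the component features, and for a pure-noise outcome."""
    study = generate_study(default_config(n_participants=n_participants, seed=seed))
    net = build_semantic_network(study.dataset, min_count=3, seed=seed)
    feats = component_features(study.dataset, net.partition, net.similarity)
    rng = np.random.default_rng(seed)
    X = feats.to_numpy()
    Xc = X - X.mean(axis=0)
    beta = rng.normal(0.0, 1.0, X.shape[1])
    lin = Xc @ beta
    noise_sd = float(np.std(lin) * np.sqrt((1 - population_r2) / population_r2))
    survey = pd.DataFrame(
        {
            "participant_id": feats.index,
            "signal": lin + rng.normal(0.0, noise_sd, len(lin)),
            "noise": rng.normal(0.0, 1.0, len(lin)),
        }
    )
    cv = cv_elastic_net(feats, study.dataset.demographics, survey,
                        folds=folds, repeats=repeats, seed=seed)
    m = cv.mean_r2()
    return {
        "planted_cv_r2": float(m.loc[("signal", "components"), "mean_r2"]),
        "noise_cv_r2": float(m.loc[("noise", "components"), "mean_r2"]),
        "n": len(feats),
    }
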