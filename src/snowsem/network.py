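"""The semantic network: co-occurrence counts, weighted Jaccard similarity,
Louvain community detection, and PageRank centrality.

The level-1 x level-2 co-occurrence matrix characterizes every eligible
level-1 word by the frequency distribution of level-2 responses it elicited.
Pairwise weighted Jaccard (Ruzicka) similarity between those count profiles
defines an undirected weighted network whose Louvain communities are the
semantic components.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .data import AssociationDataset

__all__ = [
    "CooccurrenceMatrix",
    "Partition",
    "build_cooccurrence",
    "weighted_jaccard",
    "similarity_matrix",
    "build_network",
    "modularity",
    "louvain",
    "pagerank",
]


@dataclass
class CooccurrenceMatrix:
    """Level-1 words (rows) x level-2 vocabulary (columns) count matrix.

    ``n_dropped`` counts level-2 records whose cue fell outside the eligible
    vocabulary and were therefore ignored.
    """

    counts: pd.DataFrame
    n_dropped: int = 0

    @property
    def words(self) -> list[str]:
        return list(self.counts.index)

    @property
    def level2_vocab(self) -> list[str]:
        return list(self.counts.columns)

    def row(self, word: str) -> np.ndarray:
        return self.counts.loc[word].to_numpy(dtype=float)


@dataclass
class Partition:
    """A community assignment with its modularity.

    ``labels`` maps every node to an integer community index; communities
    are numbered 0..n_communities-1 in order of first appearance over the
    node list sorted alphabetically.
    """

    labels: dict[str, int]
    modularity: float
    seed: int | None = None
    restarts: int = 1

    @property
    def n_communities(self) -> int:
        return len(set(self.labels.values()))

    def members(self, community: int) -> list[str]:
        return sorted(w for w, c in self.labels.items() if c == community)

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for w, c in self.labels.items():
            out.setdefault(c, []).append(w)
        return {c: sorted(ws) for c, ws in sorted(out.items())}

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="component").sort_index()


# ---------------------------------------------------------------------------
# Co-occurrence and similarity


def build_cooccurrence(
    data: AssociationDataset, vocabulary: list[str]
) -> CooccurrenceMatrix:
    """Count level-2 responses elicited by each eligible level-1 word.

    Cell (w, v) pools over participants the number of level-2 records with
    cue w and response v.  Level-2 records whose cue is not in the eligible
    vocabulary are dropped and counted in ``n_dropped``.
    """
    if not vocabulary:
        raise ValueError("eligible vocabulary is empty")
    level2 = data.level2()
    in_vocab = level2["cue"].isin(vocabulary)
    dropped = int((~in_vocab).sum())
    level2 = level2[in_vocab]
    counts = pd.crosstab(level2["cue"], level2["response"])
    counts = counts.reindex(index=vocabulary, fill_value=0)
    counts.index.name = "level1"
    counts.columns.name = "level2"
    return CooccurrenceMatrix(counts=counts.astype(int), n_dropped=dropped)


def weighted_jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted Jaccard (Ruzicka) similarity sum(min) / sum(max).

    Defined as 0 when both vectors are all-zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have the same dimension")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("count vectors must be non-negative")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        return 0.0
    return float(np.minimum(x, y).sum() / denom)


def similarity_matrix(C: CooccurrenceMatrix | pd.DataFrame) -> pd.DataFrame:
    """All pairwise weighted Jaccard similarities between profile rows.

    Returns a square symmetric DataFrame with unit diagonal.
    """
    counts = C.counts if isinstance(C, CooccurrenceMatrix) else C
    X = counts.to_numpy(dtype=float)
    n = X.shape[0]
    rowsum = X.sum(axis=1)
    S = np.empty((n, n))
    for i in range(n):
        mins = np.minimum(X[i], X).sum(axis=1)
        denom = rowsum[i] + rowsum - mins
        with np.errstate(invalid="ignore", divide="ignore"):
            S[i] = np.where(denom > 0, mins / denom, 0.0)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=counts.index.copy(), columns=counts.index.copy())


def build_network(S: pd.DataFrame, min_weight: float = 0.0) -> nx.Graph:
    """Similarity matrix -> undirected weighted graph.

    Node pair (x, y), x != y, is connected iff J(x, y) > ``min_weight``.
    All strictly positive similarities become edges by default.
    """
    words = list(S.index)
    A = S.to_numpy(dtype=float)
    G = nx.Graph()
    G.add_nodes_from(words)
    iu, ju = np.triu_indices(len(words), k=1)
    mask = A[iu, ju] > min_weight
    G.add_weighted_edges_from(
        (words[i], words[j], float(A[i, j]))
        for i, j in zip(iu[mask], ju[mask])
    )
    if G.number_of_edges() == 0:
        raise ValueError("network has no edges at this weight threshold")
    return G


# ---------------------------------------------------------------------------
# Modularity and Louvain


def _adjacency(net: nx.Graph) -> tuple[list[str], np.ndarray]:
    nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight="weight")
    return nodes, A


def modularity(
    net: nx.Graph, labels: dict[str, int], resolution: float = 1.0
) -> float:
    """Newman-Girvan weighted modularity Q = sum_c (e_c - resolution a_c^2)."""
    unlabeled = set(net.nodes) - set(labels)
    if unlabeled:
        raise ValueError(f"unlabeled nodes: {sorted(unlabeled)[:5]}")
    nodes, A = _adjacency(net)
    lab = np.asarray([labels[v] for v in nodes])
    return _modularity_array(A, lab, resolution)


def _modularity_array(A: np.ndarray, lab: np.ndarray, resolution: float = 1.0) -> float:
    m2 = A.sum()
    if m2 == 0:
        return 0.0
    k = A.sum(axis=1)
    e = 0.0
    a2 = 0.0
    for c in np.unique(lab):
        idx = lab == c
        e += A[np.ix_(idx, idx)].sum() / m2
        a2 += (k[idx].sum() / m2) ** 2
    return float(e - resolution * a2)


def _local_move(
    A: np.ndarray,
    rng: np.random.Generator,
    resolution: float,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """One Louvain phase: greedy node moves until no strict modularity gain.

    Convention: diagonal entries hold twice the internal weight of a
    supernode, so strengths and total weight need no special-casing.
    Ties in modularity gain break toward the lowest community index.
    ``init`` optionally seeds the phase with a non-singleton partition.
    """
    n = len(A)
    m2 = A.sum()
    k = A.sum(axis=1)
    labels = np.arange(n) if init is None else init.copy()
    comm_tot = np.bincount(labels, weights=k, minlength=n)
    self_loop = np.diag(A).copy()
    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            ci = labels[i]
            comm_tot[ci] -= k[i]
            w = np.bincount(labels, weights=A[i], minlength=n)
            w[ci] -= self_loop[i]
            gain = w - resolution * k[i] * comm_tot / m2
            best = int(np.argmax(gain))  # argmax takes the lowest index on ties
            if gain[best] > gain[ci] + 1e-12 and best != ci:
                labels[i] = best
                comm_tot[best] += k[i]
                improved = True
            else:
                comm_tot[ci] += k[i]
    return labels


def _louvain_once(
    A: np.ndarray,
    rng: np.random.Generator,
    resolution: float,
    random_init: bool = False,
) -> np.ndarray:
    """Full two-phase Louvain on a dense adjacency; returns original-node labels.

    With ``random_init`` the first local-moving phase starts from a random
    partition rather than singletons, which lets the greedy moves escape
    local optima that every singleton start converges to.
    """
    mapping = np.arange(len(A))
    cur = A.copy()
    first = True
    while True:
        init = None
        if first and random_init:
            init = rng.integers(0, max(2, len(cur) // 2), size=len(cur))
        first = False
        labels = _local_move(cur, rng, resolution, init=init)
        uniq, compact = np.unique(labels, return_inverse=True)
        if len(uniq) == len(cur):
            break
        mapping = compact[mapping]
        M = np.zeros((len(cur), len(uniq)))
        M[np.arange(len(cur)), compact] = 1.0
        cur = M.T @ cur @ M
    # refinement: single-node moves on the original graph from the final
    # partition, undoing unfavorable merges locked in by aggregation
    return _local_move(A, rng, resolution, init=mapping)


def louvain(
    net: nx.Graph,
    seed: int = 0,
    restarts: int = 10,
    resolution: float = 1.0,
) -> Partition:
    """Louvain community detection, best of ``restarts`` seeded runs.

    Each restart shuffles the node visit order with its own stream derived
    from ``seed``; odd-numbered restarts additionally start the first
    local-moving phase from a random partition instead of singletons, which
    helps escape local optima on small dense graphs.  The partition with
    the highest modularity is kept (the earliest restart wins exact ties,
    making the result reproducible).  Connected components of the graph are
    handled implicitly.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    nodes, A = _adjacency(net)
    rng = np.random.default_rng(seed)
    best_lab: np.ndarray | None = None
    best_q = -np.inf
    for r in range(max(1, restarts)):
        sub = np.random.default_rng(rng.integers(2**31))
        lab = _louvain_once(A, sub, resolution, random_init=bool(r % 2))
        q = _modularity_array(A, lab, resolution)
        if q > best_q + 1e-15:
            best_q, best_lab = q, lab
    # canonical community numbering: order of first appearance over sorted nodes
    remap: dict[int, int] = {}
    labels: dict[str, int] = {}
    for v, c in zip(nodes, best_lab):
        labels[v] = remap.setdefault(int(c), len(remap))
    return Partition(
        labels=labels,
        modularity=_modularity_array(A, best_lab, 1.0),
        seed=seed,
        restarts=restarts,
    )


# ---------------------------------------------------------------------------
# PageRank


def pagerank(
    net: nx.Graph, damping: float = 0.85, tol: float = 1e-10, max_iter: int = 1000
) -> dict[str, float]:
    """Weighted PageRank by power iteration; scores sum to one.

    ``tol`` is the L1 convergence threshold on successive iterates.
    """
    if net.number_of_edges() == 0:
        raise ValueError("pagerank requires at least one edge")
    n = net.number_of_nodes()
    try:
        scores = nx.pagerank(
            net, alpha=damping, tol=tol / n, max_iter=max_iter, weight="weight"
        )
    except nx.PowerIterationFailedConvergence as exc:
        raise RuntimeError(
            f"pagerank failed to reach L1 tolerance {tol} within "
            f"{max_iter} iterations on {n} nodes"
        ) from exc
    return {v: float(s) for v, s in scores.items()}
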