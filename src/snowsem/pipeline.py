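"""End-to-end convenience: raw records -> network, partition, centralities."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data import AssociationDataset
from .network import (
    CooccurrenceMatrix,
    Partition,
    build_cooccurrence,
    build_network,
    louvain,
    pagerank,
    similarity_matrix,
)
from .preprocessing import QCReport, filter_dataset, normalize_dataset

__all__ = ["SemanticNetwork", "build_semantic_network"]


@dataclass
class SemanticNetwork:
    """All intermediate products of the network-construction pipeline."""

    dataset: AssociationDataset
    vocabulary: list[str]
    cooccurrence: CooccurrenceMatrix
    similarity: pd.DataFrame
    graph: nx.Graph
    partition: Partition
    pagerank: dict[str, float]
    qc: QCReport

    def summary(self) -> pd.DataFrame:
        """Per-word table: component assignment and PageRank centrality."""
        return pd.DataFrame(
            {
                "component": pd.Series(self.partition.labels),
                "pagerank": pd.Series(self.pagerank),
            }
        ).rename_axis("word")


def build_semantic_network(
    data: AssociationDataset,
    exclusions: set[str] = frozenset(),
    min_count: int = 3,
    min_weight: float = 0.0,
    seed: int = 0,
    restarts: int = 10,
    normalize: bool = True,
    corrections: dict[str, str] | None = None,
) -> SemanticNetwork:
    """Run the full construction: normalize, filter, count, relate, cluster.

    Level-1 words retrieved at least ``min_count`` times are profiled by
    their level-2 response counts; weighted Jaccard similarities between
    profiles define the network, Louvain (best of ``restarts`` seeded runs)
    the components, and weighted PageRank the word centralities.
    """
    if normalize:
        data, _ = normalize_dataset(data, corrections=corrections)
    filtered, vocab, qc = filter_dataset(data, exclusions=exclusions, min_count=min_count)
    C = build_cooccurrence(filtered, vocab)
    S = similarity_matrix(C)
    G = build_network(S, min_weight=min_weight)
    part = louvain(G, seed=seed, restarts=restarts)
    pr = pagerank(G)
    return SemanticNetwork(
        dataset=filtered,
        vocabulary=vocab,
        cooccurrence=C,
        similarity=S,
        graph=G,
        partition=part,
        pagerank=pr,
        qc=qc,
    )
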