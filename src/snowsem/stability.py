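"""Bootstrap cluster-stability analysis.

Level-2 response tokens are resampled with replacement within each level-1
cue row (preserving row totals), the similarity network is rebuilt, and the
clustering re-run.  For every word we then record how often it shares a
cluster with the words of each original component, normalized by component
size so that large components do not dominate modal assignments mechanically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import CooccurrenceMatrix, Partition, build_network, louvain, similarity_matrix

__all__ = ["StabilityResult", "bootstrap_partitions", "costability", "stability_analysis"]


@dataclass
class StabilityResult:
    """Size-normalized co-membership proportions and modal assignments.

    ``table`` has one row per word: original component, the normalized
    co-membership proportion with each component (summing to one), and the
    modal component.  ``summary`` maps each original component to the
    fraction of its member words whose modal component is the original one.
    """

    table: pd.DataFrame
    summary: dict[int, float]
    B: int

    def summary_series(self) -> pd.Series:
        return pd.Series(self.summary, name="stability").sort_index()


def bootstrap_partitions(
    C: CooccurrenceMatrix,
    B: int,
    seed: int = 0,
    restarts: int = 2,
    min_weight: float = 0.0,
) -> list[Partition]:
    """B replicate partitions from row-wise multinomial resampling.

    Each replicate redraws every level-1 word's level-2 response tokens with
    replacement (multinomial with the original row total and the empirical
    row distribution), rebuilds the weighted Jaccard network, and re-runs
    Louvain with a replicate-specific seed.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    X = C.counts.to_numpy(dtype=np.int64)
    totals = X.sum(axis=1)
    probs = X / np.where(totals > 0, totals, 1)[:, None]
    partitions: list[Partition] = []
    for _ in range(B):
        Xb = np.vstack(
            [rng.multinomial(t, p) if t > 0 else np.zeros_like(p, dtype=np.int64)
             for t, p in zip(totals, probs)]
        )
        Cb = pd.DataFrame(Xb, index=C.counts.index, columns=C.counts.columns)
        S = similarity_matrix(CooccurrenceMatrix(Cb))
        net = build_network(S, min_weight=min_weight)
        partitions.append(louvain(net, seed=int(rng.integers(2**31)), restarts=restarts))
    return partitions


def costability(partitions: list[Partition], reference: Partition) -> StabilityResult:
    """Size-normalized co-membership of each word with each original component.

    For word w and original component k the raw score is the mean over
    replicates of the fraction of k's other members found in w's replicate
    cluster; per-word scores are renormalized to sum to one over components.
    The modal component is the argmax, with ties resolved toward the word's
    original component and then the lowest component index.
    """
    words = sorted(reference.labels)
    for p in partitions:
        if set(p.labels) != set(words):
            raise ValueError("replicate partition node set differs from reference")
    ref = np.array([reference.labels[w] for w in words])
    comps = np.unique(ref)
    n = len(words)
    comp_masks = {k: ref == k for k in comps}

    raw = np.zeros((n, len(comps)))
    for p in partitions:
        lab = np.array([p.labels[w] for w in words])
        same = lab[:, None] == lab[None, :]
        np.fill_diagonal(same, False)
        for j, k in enumerate(comps):
            mask = comp_masks[k]
            # shared members of k, excluding w itself, over |k \ {w}|
            shared = same[:, mask].sum(axis=1).astype(float)
            size = mask.sum() - mask.astype(int)  # |k|-1 for members, |k| otherwise
            raw[:, j] += np.where(size > 0, shared / np.maximum(size, 1), 0.0)
    raw /= len(partitions)

    norm = raw.sum(axis=1, keepdims=True)
    props = np.divide(raw, norm, out=np.zeros_like(raw), where=norm > 0)

    modal = np.empty(n, dtype=int)
    for i in range(n):
        row = props[i]
        best = row.max()
        tied = [comps[j] for j in range(len(comps)) if row[j] >= best - 1e-12]
        modal[i] = ref[i] if ref[i] in tied else min(tied)

    table = pd.DataFrame(
        {
            "word": words,
            "original": ref,
            **{f"p_component_{k}": props[:, j] for j, k in enumerate(comps)},
            "modal": modal,
        }
    ).set_index("word")
    summary = {
        int(k): float((modal[comp_masks[k]] == k).mean()) for k in comps
    }
    return StabilityResult(table=table, summary=summary, B=len(partitions))


def stability_analysis(
    C: CooccurrenceMatrix,
    reference: Partition,
    B: int = 1000,
    seed: int = 0,
    restarts: int = 2,
) -> StabilityResult:
    """Convenience wrapper: bootstrap partitions, then co-membership summary."""
    parts = bootstrap_partitions(C, B=B, seed=seed, restarts=restarts)
    return costability(parts, reference)
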