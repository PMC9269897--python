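"""Component characterization: retrieval proportions, sentiment, similarity
to the focal concept, and cross-language comparison of similarity structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AssociationDataset, FOCAL_CUE
from .network import CooccurrenceMatrix, Partition, weighted_jaccard

__all__ = [
    "retrieval_proportions",
    "infer_sentiment",
    "component_sentiment",
    "risk_similarity",
    "focal_profile",
    "swow_profiles",
    "crosslingual_compare",
    "CrosslingualResult",
]


# ---------------------------------------------------------------------------
# Retrieval proportions


def retrieval_proportions(
    data: AssociationDataset,
    partition: Partition,
    by: str = "overall",
) -> pd.DataFrame:
    """Share of level-1 response tokens falling into each component.

    ``by`` is one of ``overall``, ``position``, ``age_bin`` or ``gender``;
    the result has one row per stratum (a single row for ``overall``) and
    one column per component, each row summing to one.  Level-1 responses
    outside the network vocabulary are excluded from denominators; their
    count is stored in ``result.attrs['n_excluded']``.
    """
    level1 = data.merged()
    level1 = level1[level1["level"] == 1].copy()
    in_net = level1["response"].isin(partition.labels)
    n_excluded = int((~in_net).sum())
    level1 = level1[in_net]
    level1["component"] = level1["response"].map(partition.labels)
    comps = sorted(set(partition.labels.values()))

    if by == "overall":
        counts = level1["component"].value_counts()
        table = pd.DataFrame([counts.reindex(comps, fill_value=0)], index=["overall"])
    elif by in ("position", "age_bin", "gender"):
        table = (
            level1.groupby(by)["component"].value_counts().unstack(fill_value=0)
        ).reindex(columns=comps, fill_value=0)
    else:
        raise ValueError(f"unknown stratification: {by!r}")
    denom = table.sum(axis=1)
    props = table.div(denom.where(denom > 0), axis=0)
    props.columns = [f"component_{c}" for c in comps]
    props.attrs["n_excluded"] = n_excluded
    props.attrs["n_included"] = int(len(level1))
    return props


# ---------------------------------------------------------------------------
# Sentiment


def infer_sentiment(
    lexicon: pd.Series, C: CooccurrenceMatrix
) -> pd.Series:
    """Propagate lexicon sentiment onto the network words.

    For word w, ``assoc(w)`` is the count-weighted mean lexicon score over
    w's level-2 responses that have a lexicon entry.  The inferred score is
    the average of the word's own score and ``assoc(w)`` when both exist,
    the available one otherwise, and NaN when neither exists.
    """
    counts = C.counts
    covered = [c for c in counts.columns if c in lexicon.index]
    sub = counts[covered].to_numpy(dtype=float)
    scores = lexicon.reindex(covered).to_numpy(dtype=float)
    weight = sub.sum(axis=1)
    with np.errstate(invalid="ignore"):
        assoc = np.where(weight > 0, sub @ scores / np.where(weight > 0, weight, 1), np.nan)
    own = lexicon.reindex(counts.index).to_numpy(dtype=float)
    both = ~np.isnan(own) & ~np.isnan(assoc)
    inferred = np.where(
        both,
        (own + assoc) / 2.0,
        np.where(~np.isnan(assoc), assoc, own),
    )
    return pd.Series(inferred, index=counts.index, name="sentiment")


def component_sentiment(
    scores: pd.Series,
    partition: Partition,
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> pd.DataFrame:
    """Mean sentiment per component with bootstrap percentile CI over words."""
    return _component_bootstrap(scores, partition, B=B, seed=seed, ci=ci, name="sentiment")


def _component_bootstrap(
    scores: pd.Series, partition: Partition, B: int, seed: int, ci: float, name: str
) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    alpha = (1.0 - ci) / 2.0
    rows = []
    for comp, members in partition.communities().items():
        vals = scores.reindex(members).dropna().to_numpy()
        if len(vals) == 0:
            import warnings

            warnings.warn(f"component {comp} has no scored word", stacklevel=3)
            rows.append((comp, len(members), 0, np.nan, np.nan, np.nan))
            continue
        boots = rng.choice(vals, size=(B, len(vals)), replace=True).mean(axis=1)
        rows.append(
            (
                comp,
                len(members),
                len(vals),
                float(vals.mean()),
                float(np.quantile(boots, alpha)),
                float(np.quantile(boots, 1 - alpha)),
            )
        )
    return pd.DataFrame(
        rows, columns=["component", "size", "n_scored", f"mean_{name}", "ci_lo", "ci_hi"]
    ).set_index("component")


# ---------------------------------------------------------------------------
# Similarity to the focal concept


def focal_profile(data: AssociationDataset, C: CooccurrenceMatrix) -> np.ndarray:
    """Level-1 response frequency vector of the focal cue, projected onto
    the level-2 column vocabulary.

    Level-1 responses outside the level-2 vocabulary are dropped from the
    projection.  This vector lets the focal concept itself enter the
    similarity space that its associates span.
    """
    level1 = data.level1()
    counts = level1["response"].value_counts()
    vec = counts.reindex(C.counts.columns, fill_value=0).to_numpy(dtype=float)
    if vec.sum() == 0:
        raise ValueError("focal profile is empty after projection onto level-2 vocabulary")
    return vec


def risk_similarity(
    C: CooccurrenceMatrix,
    partition: Partition,
    focal: np.ndarray,
    B: int = 1000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[pd.Series, pd.DataFrame]:
    """Weighted Jaccard similarity of every word's profile to the focal cue.

    Returns per-word similarities and a per-component table (mean over
    member words with a bootstrap percentile CI).
    """
    X = C.counts.to_numpy(dtype=float)
    focal = np.asarray(focal, dtype=float)
    mins = np.minimum(X, focal).sum(axis=1)
    maxs = np.maximum(X, focal).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(maxs > 0, mins / maxs, 0.0)
    per_word = pd.Series(sims, index=C.counts.index, name="risk_similarity")
    per_component = _component_bootstrap(
        per_word, partition, B=B, seed=seed, ci=ci, name="risk_similarity"
    )
    return per_word, per_component


# ---------------------------------------------------------------------------
# Cross-language comparison


def swow_profiles(table: pd.DataFrame) -> pd.DataFrame:
    """Convert a (cue, response, count) association-norm table to profile rows."""
    pivot = table.pivot_table(
        index="cue", columns="response", values="count", aggfunc="sum", fill_value=0
    )
    return pivot.astype(float)


@dataclass
class CrosslingualResult:
    """Comparison of two languages' similarity structure over shared terms."""

    block_means_ref: pd.DataFrame
    block_means_other: pd.DataFrame
    pairwise_correlation: float
    n_shared_terms: int
    n_pairs: int
    retrieval_correlation: float | None = None


def crosslingual_compare(
    S_ref: pd.DataFrame,
    S_other: pd.DataFrame,
    partition: Partition,
    term_map: pd.Series | dict | None = None,
    retrieval_ref: pd.Series | None = None,
    retrieval_other: pd.Series | None = None,
) -> CrosslingualResult:
    """Compare similarity structure across languages over shared terms.

    ``term_map`` translates the other language's terms into reference terms;
    omit it when both matrices are already in the same vocabulary.  Only
    terms present in both matrices enter.  The Pearson correlation is taken
    over the upper-triangle term pairs available in both languages; block
    means average within/between-component similarities using the reference
    partition.  If per-component retrieval proportions for both languages
    are supplied, their Pearson correlation is reported as well.
    """
    if term_map is not None:
        mapping = pd.Series(term_map)
        other = S_other.rename(index=mapping, columns=mapping)
        # drop untranslated terms and any duplicate translations
        other = other.loc[~other.index.duplicated(), ~other.columns.duplicated()]
    else:
        other = S_other
    shared = [t for t in S_ref.index if t in other.index and t in partition.labels]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared terms between languages")
    A = S_ref.loc[shared, shared].to_numpy(dtype=float)
    Bm = other.loc[shared, shared].to_numpy(dtype=float)
    iu, ju = np.triu_indices(len(shared), k=1)
    r = float(np.corrcoef(A[iu, ju], Bm[iu, ju])[0, 1])

    lab = np.array([partition.labels[t] for t in shared])
    comps = sorted(set(partition.labels.values()))
    block_ref = _block_means(A, lab, comps)
    block_other = _block_means(Bm, lab, comps)

    retr_r = None
    if retrieval_ref is not None and retrieval_other is not None:
        x = pd.Series(retrieval_ref).reindex(comps).to_numpy(dtype=float)
        y = pd.Series(retrieval_other).reindex(comps).to_numpy(dtype=float)
        retr_r = float(np.corrcoef(x, y)[0, 1])

    return CrosslingualResult(
        block_means_ref=block_ref,
        block_means_other=block_other,
        pairwise_correlation=r,
        n_shared_terms=len(shared),
        n_pairs=len(iu),
        retrieval_correlation=retr_r,
    )


def _block_means(S: np.ndarray, lab: np.ndarray, comps: list[int]) -> pd.DataFrame:
    out = np.full((len(comps), len(comps)), np.nan)
    for a, ca in enumerate(comps):
        for b, cb in enumerate(comps):
            ia = np.where(lab == ca)[0]
            ib = np.where(lab == cb)[0]
            if len(ia) == 0 or len(ib) == 0:
                continue
            block = S[np.ix_(ia, ib)]
            if ca == cb:
                if len(ia) < 2:
                    continue
                mask = ~np.eye(len(ia), dtype=bool)
                out[a, b] = block[mask].mean()
            else:
                out[a, b] = block.mean()
    return pd.DataFrame(out, index=comps, columns=comps)
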