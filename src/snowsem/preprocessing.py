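"""Normalization, QC and frequency filtering of association records."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import AssociationDataset

#: Token used for responses that normalize to the empty string.
EMPTY_TOKEN = "<empty>"


def normalize_response(raw: str) -> str:
    """Trim, casefold and collapse internal whitespace.

    An input that normalizes to nothing (e.g. "  ") is flagged with the
    sentinel token ``<empty>`` so that it can be excluded downstream.
    """
    token = " ".join(str(raw).split()).casefold()
    return token if token else EMPTY_TOKEN


def damerau_levenshtein(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Substitutions, insertions, deletions and adjacent transpositions each
    cost 1; no substring is edited more than once.  Used to QC supplied
    spelling-correction pairs.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2 = None
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and a[i - 1] == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


@dataclass
class QCReport:
    """Bookkeeping from normalization and filtering."""

    n_input_records: int = 0
    n_removed_excluded: int = 0
    n_level1_below_threshold: int = 0
    n_eligible_words: int = 0
    fraction_removed: float = 0.0
    correction_distances: list[int] = field(default_factory=list)

    @property
    def median_correction_distance(self) -> float | None:
        if not self.correction_distances:
            return None
        return float(np.median(self.correction_distances))

    def to_dict(self) -> dict:
        return {
            "n_input_records": self.n_input_records,
            "n_removed_excluded": self.n_removed_excluded,
            "fraction_removed": self.fraction_removed,
            "n_level1_below_threshold": self.n_level1_below_threshold,
            "n_eligible_words": self.n_eligible_words,
            "median_correction_distance": self.median_correction_distance,
        }


def normalize_dataset(
    data: AssociationDataset, corrections: dict[str, str] | None = None
) -> tuple[AssociationDataset, QCReport]:
    """Normalize all cue and response tokens; optionally apply corrections.

    ``corrections`` maps raw tokens to corrected tokens (the stand-in for a
    manual spelling-correction pass); the QC report records the string
    distance of every applied pair.
    """
    report = QCReport(n_input_records=len(data.records))
    records = data.records.copy()
    for col in ("cue", "response"):
        records[col] = records[col].map(normalize_response)
    if corrections:
        corr = {normalize_response(k): normalize_response(v) for k, v in corrections.items()}
        applied = records["response"].isin(corr)
        report.correction_distances = [
            damerau_levenshtein(tok, corr[tok])
            for tok in records.loc[applied, "response"]
        ]
        for col in ("cue", "response"):
            records[col] = records[col].map(lambda t: corr.get(t, t))
    return AssociationDataset(records, data.demographics.copy()), report


def filter_dataset(
    data: AssociationDataset,
    exclusions: set[str] | frozenset[str] = frozenset(),
    min_count: int = 3,
) -> tuple[AssociationDataset, list[str], QCReport]:
    """Drop excluded tokens and determine the eligible level-1 vocabulary.

    Records whose response is in ``exclusions`` (nonwords, failures to
    respond) are removed at both levels.  The eligible vocabulary consists
    of level-1 responses whose total level-1 token count reaches
    ``min_count``; level-2 records are retained regardless of their own
    frequency, since they form the profile dimensions.

    Returns the filtered dataset, the eligible vocabulary (sorted by
    descending level-1 frequency, ties alphabetical), and a QC report.
    """
    report = QCReport(n_input_records=len(data.records))
    records = data.records
    drop = records["response"].isin(exclusions) | (records["response"] == EMPTY_TOKEN)
    report.n_removed_excluded = int(drop.sum())
    report.fraction_removed = report.n_removed_excluded / max(len(records), 1)
    kept = records[~drop]

    level1 = kept[kept["level"] == 1]
    counts = level1["response"].value_counts()
    eligible = counts[counts >= min_count]
    report.n_level1_below_threshold = int((counts < min_count).sum())
    report.n_eligible_words = len(eligible)
    if eligible.empty:
        raise ValueError("no level-1 word passes the frequency threshold")
    vocab = sorted(eligible.index, key=lambda w: (-eligible[w], w))
    filtered = AssociationDataset(kept.reset_index(drop=True), data.demographics.copy())
    return filtered, vocab, report
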