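"""Core containers and plain-text I/O for association data.

All files are UTF-8 text: association records as long-format TSV with
header, sentiment lexica as two-column TSV, surveys as CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: The focal cue of the snowball task.
FOCAL_CUE = "risk"

RECORD_COLUMNS = ["participant_id", "level", "cue", "cue_position", "position", "response"]
TSV_COLUMNS = ["participant_id", "age_bin", "gender", "level", "cue",
               "cue_position", "position", "response"]


@dataclass
class AssociationDataset:
    """Long-format association records plus participant demographics.

    ``records`` columns: participant_id, level (1 or 2), cue, cue_position
    (1..n_level1 for level-2 records, NA for level-1), position (1..n per
    cue page), response.  ``demographics`` columns: participant_id, age_bin
    (1..6), gender ('f'/'m').
    """

    records: pd.DataFrame
    demographics: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_participants(self) -> int:
        return self.demographics["participant_id"].nunique()

    def level1(self) -> pd.DataFrame:
        return self.records[self.records["level"] == 1]

    def level2(self) -> pd.DataFrame:
        return self.records[self.records["level"] == 2]

    def merged(self) -> pd.DataFrame:
        """Records joined with demographics."""
        return self.records.merge(self.demographics, on="participant_id", how="left")

    def copy(self) -> "AssociationDataset":
        return AssociationDataset(self.records.copy(), self.demographics.copy())


def write_associations(dataset: AssociationDataset, path: str | Path) -> None:
    """Write the dataset as a single denormalized long TSV."""
    df = dataset.merged()[TSV_COLUMNS]
    df.to_csv(path, sep="\t", index=False)


def read_associations(path: str | Path) -> AssociationDataset:
    """Read the long TSV dialect written by :func:`write_associations`."""
    df = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "response": str,
                                            "cue": str, "gender": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"association TSV missing columns: {missing}")
    demographics = (
        df[["participant_id", "age_bin", "gender"]]
        .drop_duplicates("participant_id")
        .reset_index(drop=True)
    )
    records = df[RECORD_COLUMNS].copy()
    return AssociationDataset(records=records, demographics=demographics)


def write_sentiment_lexicon(scores: pd.Series | dict, path: str | Path) -> None:
    s = pd.Series(scores, name="score")
    s.rename_axis("word").to_csv(path, sep="\t")


def read_sentiment_lexicon(path: str | Path) -> pd.Series:
    """Two-column TSV (word, score) -> Series of scores in [-1, 1]."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    word_col, score_col = df.columns[:2]
    s = df.set_index(word_col)[score_col].astype(float)
    if (s.abs() > 1).any():
        raise ValueError("sentiment scores must lie in [-1, 1]")
    return s


def read_survey(path: str | Path) -> pd.DataFrame:
    """Survey CSV: participant_id plus the seven 0-10 integer rating items."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise ValueError("survey CSV must have a participant_id column")
    return df


def read_swow_table(path: str | Path) -> pd.DataFrame:
    """Read a cue,response,count association-norm table (SWOW-style CSV).

    Rows with count absent are taken as single tokens (count 1).
    """
    df = pd.read_csv(path, dtype={"cue": str, "response": str})
    if "count" not in df.columns:
        df["count"] = 1
    return df[["cue", "response", "count"]]


def read_translation_table(path: str | Path) -> pd.Series:
    """Two-column TSV mapping other-language terms to reference terms."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    src, dst = df.columns[:2]
    return df.set_index(src)[dst]
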