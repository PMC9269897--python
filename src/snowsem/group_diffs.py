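"""Age and gender differences in retrieval frequencies.

Word-level age trends use a Poisson log-linear model of per-age-group
level-1 counts with the group's total level-1 token count as exposure
offset; word-level gender differences use the difference in log relative
retrieval frequency and a 2x2 chi-square test of stochastic independence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .data import AssociationDataset
from .network import Partition
from .profiles import retrieval_proportions

__all__ = ["age_trend", "gender_diff", "component_by_group", "group_effect_table"]

N_AGE_BINS = 6


@dataclass
class AgeTrend:
    word: str
    beta: float
    p_value: float
    eligible: bool
    counts: np.ndarray | None = None


@dataclass
class GenderDiff:
    word: str
    delta: float
    chi2: float
    p_value: float
    counts: dict | None = None


def _level1_with_demo(data: AssociationDataset) -> pd.DataFrame:
    df = data.merged()
    return df[df["level"] == 1]


def _age_counts(level1: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Word x age-bin level-1 count table and per-bin token totals."""
    table = pd.crosstab(level1["response"], level1["age_bin"]).reindex(
        columns=range(1, N_AGE_BINS + 1), fill_value=0
    )
    return table, table.sum(axis=0).to_numpy(dtype=float)


def _fit_age_trend(
    word: str, y: np.ndarray, n: np.ndarray, model: str
) -> AgeTrend:
    if (y == 0).any() or (n == 0).any():
        return AgeTrend(word, np.nan, np.nan, eligible=False, counts=y)
    bins = np.arange(1, N_AGE_BINS + 1, dtype=float)
    if model == "poisson":
        X = sm.add_constant(bins)
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=np.log(n)).fit()
        beta, p = float(fit.params[1]), float(fit.pvalues[1])
    elif model == "ols":
        X = sm.add_constant(bins)
        fit = sm.OLS(np.log(y / n), X).fit()
        beta, p = float(fit.params[1]), float(fit.pvalues[1])
    else:
        raise ValueError(f"unknown model: {model!r}")
    return AgeTrend(word, beta, p, eligible=True, counts=y)


def age_trend(
    data: AssociationDataset, word: str, model: str = "poisson"
) -> AgeTrend:
    """Linear age trend in a word's log relative retrieval frequency.

    ``model='poisson'`` (default) fits counts ~ Poisson(exp(a + b*bin)) with
    offset log(total level-1 tokens in bin); beta is the slope per age bin
    and p its Wald test.  ``model='ols'`` regresses log relative frequency
    on the bin index by least squares instead.

    A word is eligible only if it was retrieved at least once in every age
    group; ineligible words get ``eligible=False`` and NaN estimates.
    """
    table, totals = _age_counts(_level1_with_demo(data))
    y = (
        table.loc[word].to_numpy(dtype=float)
        if word in table.index
        else np.zeros(N_AGE_BINS)
    )
    return _fit_age_trend(word, y, totals, model)


def _gender_diff_from_counts(
    word: str, c_f: int, c_m: int, n_f: int, n_m: int
) -> GenderDiff:
    if c_f + c_m == 0:
        raise ValueError(f"word {word!r} has zero level-1 tokens")
    if n_f == 0 or n_m == 0:
        raise ValueError("both genders must contribute level-1 tokens")
    delta = float(np.log((c_f + 0.5) / n_f) - np.log((c_m + 0.5) / n_m))
    table = np.array([[c_f, n_f - c_f], [c_m, n_m - c_m]], dtype=float)
    if c_f / n_f == c_m / n_m:
        chi2, p = 0.0, 1.0
    else:
        chi2, _, _, _ = stats.chi2_contingency(table, correction=False)[:4]
        p = float(stats.chi2.sf(chi2, df=1))
        chi2 = float(chi2)
    return GenderDiff(word, delta, chi2, p, counts={"f": (c_f, n_f), "m": (c_m, n_m)})


def gender_diff(data: AssociationDataset, word: str) -> GenderDiff:
    """Gender difference in a word's retrieval frequency.

    Delta is the difference of log relative retrieval frequencies
    (female minus male) with additive smoothing of 0.5 on the word counts
    (display only); the p-value comes from the 2x2 chi-square test of the
    word-vs-other-tokens by gender table on the raw counts, without
    continuity correction.
    """
    level1 = _level1_with_demo(data)
    n_f = int((level1["gender"] == "f").sum())
    n_m = int((level1["gender"] == "m").sum())
    is_word = level1["response"] == word
    c_f = int((is_word & (level1["gender"] == "f")).sum())
    c_m = int((is_word & (level1["gender"] == "m")).sum())
    return _gender_diff_from_counts(word, c_f, c_m, n_f, n_m)


def component_by_group(
    data: AssociationDataset, partition: Partition, by: str = "age_bin"
) -> pd.DataFrame:
    """Retrieval proportions per component stratified by age bin or gender."""
    if by not in ("age_bin", "gender"):
        raise ValueError("by must be 'age_bin' or 'gender'")
    return retrieval_proportions(data, partition, by=by)


def group_effect_table(
    data: AssociationDataset,
    words: list[str],
    age_model: str = "poisson",
    adjust: bool = True,
) -> pd.DataFrame:
    """Word-level age and gender effect table.

    One row per word: age slope and p (NaN when the word is not retrieved
    in every age group), gender log-relative-frequency difference and p.
    When ``adjust`` is set, Benjamini-Hochberg adjusted p-values are added
    as extra transparency columns.
    """
    level1 = _level1_with_demo(data)
    age_table, age_totals = _age_counts(level1)
    gender_table = pd.crosstab(level1["response"], level1["gender"]).reindex(
        columns=["f", "m"], fill_value=0
    )
    n_f = int((level1["gender"] == "f").sum())
    n_m = int((level1["gender"] == "m").sum())
    rows = []
    for w in words:
        y = (
            age_table.loc[w].to_numpy(dtype=float)
            if w in age_table.index
            else np.zeros(N_AGE_BINS)
        )
        a = _fit_age_trend(w, y, age_totals, age_model)
        c_f = int(gender_table.at[w, "f"]) if w in gender_table.index else 0
        c_m = int(gender_table.at[w, "m"]) if w in gender_table.index else 0
        g = _gender_diff_from_counts(w, c_f, c_m, n_f, n_m)
        rows.append(
            {
                "word": w,
                "age_beta": a.beta,
                "age_p": a.p_value,
                "age_eligible": a.eligible,
                "gender_delta": g.delta,
                "gender_p": g.p_value,
            }
        )
    table = pd.DataFrame(rows).set_index("word")
    if adjust:
        from statsmodels.stats.multitest import multipletests

        for col in ("age_p", "gender_p"):
            mask = table[col].notna()
            adj = np.full(len(table), np.nan)
            if mask.any():
                adj[mask.to_numpy()] = multipletests(
                    table.loc[mask, col], method="fdr_bh"
                )[1]
            table[col.replace("_p", "_p_bh")] = adj
    return table
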