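"""Predicting self-reported risk taking from semantic representations.

Each participant is represented by K component features — the mean weighted
Jaccard similarity of their level-1 responses to each component's member
words.  Item-level OLS quantifies standardized effects alongside age and
gender; repeated k-fold cross-validated elastic nets compare the predictive
value of component features, demographics, and their combination, with
corrected resampled t-tests on per-fold differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import ElasticNetCV
from sklearn.model_selection import RepeatedKFold
from sklearn.preprocessing import StandardScaler

from .data import AssociationDataset
from .network import Partition

__all__ = [
    "component_features",
    "fit_item_regressions",
    "cv_elastic_net",
    "corrected_resampled_ttest",
    "word_level_correlations",
    "CVResult",
]

MODEL_VARIANTS = ("components", "demographics", "combined")


def component_features(
    data: AssociationDataset,
    partition: Partition,
    S: pd.DataFrame,
    variant: str = "similarity",
) -> pd.DataFrame:
    """Participant x component feature table.

    ``variant='similarity'`` (default): feature k of a participant is the
    mean, over their in-network level-1 responses r, of the mean similarity
    J(r, w) to the member words w of component k.  ``variant='proportion'``
    instead uses the share of in-network responses assigned to component k.
    Participants with no in-network level-1 response are excluded; their
    count is stored in ``result.attrs['n_excluded']``.
    """
    if set(partition.labels) - set(S.index):
        raise ValueError("partition and similarity matrix cover different vocabularies")
    level1 = data.level1()
    in_net = level1[level1["response"].isin(partition.labels)]
    comps = sorted(set(partition.labels.values()))

    if variant == "similarity":
        lab = pd.Series(partition.labels)
        # word -> mean similarity to each component's members
        word_feats = pd.DataFrame(
            {c: S.loc[:, lab.index[lab == c]].mean(axis=1) for c in comps}
        )
        feats = (
            in_net.join(word_feats, on="response")
            .groupby("participant_id")[comps]
            .mean()
        )
    elif variant == "proportion":
        assigned = in_net["response"].map(partition.labels)
        feats = (
            pd.crosstab(in_net["participant_id"], assigned)
            .reindex(columns=comps, fill_value=0)
            .pipe(lambda t: t.div(t.sum(axis=1), axis=0))
        )
    else:
        raise ValueError(f"unknown variant: {variant!r}")

    if feats.empty:
        raise ValueError("every participant was excluded (no in-network responses)")
    feats.columns = [f"component_{c}" for c in comps]
    feats.attrs["n_excluded"] = data.n_participants - len(feats)
    return feats


def _design(
    features: pd.DataFrame, demographics: pd.DataFrame, survey: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    demo = demographics.set_index("participant_id")
    X = features.join(demo[["age_bin", "gender"]], how="inner")
    X["gender"] = (X["gender"] == "f").astype(float)
    X = X.rename(columns={"age_bin": "age", "gender": "gender_f"})
    y = survey.set_index("participant_id").loc[X.index]
    return X.astype(float), y


def fit_item_regressions(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    survey: pd.DataFrame,
) -> pd.DataFrame:
    """Standardized OLS coefficients per survey item.

    Predictors (age-bin index, female indicator, K component features) and
    outcomes are z-scored, so coefficients are standardized betas; p-values
    are two-sided t-tests.  Returns a long table indexed by (item,
    predictor) with columns ``beta`` and ``p``.
    """
    X, Y = _design(features, demographics, survey)
    if len(X) < 20:
        raise ValueError("need at least 20 complete cases")
    Xz = (X - X.mean()) / X.std(ddof=1)
    if Xz.isna().any().any():
        bad = X.columns[X.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant (collinear) predictor columns: {bad}")
    Xd = sm.add_constant(Xz)
    rows = []
    for item in Y.columns:
        y = Y[item].astype(float)
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(yz, Xd).fit()
        for pred in Xz.columns:
            rows.append((item, pred, float(fit.params[pred]), float(fit.pvalues[pred])))
    return pd.DataFrame(rows, columns=["item", "predictor", "beta", "p"]).set_index(
        ["item", "predictor"]
    )


@dataclass
class CVResult:
    """Repeated k-fold CV R-squared per model variant and item."""

    fold_r2: pd.DataFrame  # columns: item, variant, repeat, fold, r2
    n_train: int
    n_test: int
    folds: int
    repeats: int
    seed: int
    comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)

    def mean_r2(self) -> pd.DataFrame:
        """Mean and corrected resampled SE of CV R^2 per item and variant."""
        ratio = self.n_test / self.n_train
        out = []
        for (item, variant), grp in self.fold_r2.groupby(["item", "variant"]):
            r2 = grp["r2"].to_numpy()
            se = float(np.sqrt(np.var(r2, ddof=1) * (1 / len(r2) + ratio)))
            out.append((item, variant, float(r2.mean()), se, len(r2)))
        return pd.DataFrame(
            out, columns=["item", "variant", "mean_r2", "se", "n_folds"]
        ).set_index(["item", "variant"])


def cv_elastic_net(
    features: pd.DataFrame,
    demographics: pd.DataFrame,
    survey: pd.DataFrame,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    l1_ratio: float = 0.5,
    inner_folds: int = 5,
) -> CVResult:
    """Repeated k-fold cross-validated elastic-net prediction.

    Three model variants per item: component features only, demographics
    (age, gender) only, and all predictors combined.  Within each training
    fold, predictors are z-scored and the penalty strength is selected by
    inner cross-validation at fixed mixing ``l1_ratio``; R^2 is computed on
    the held-out fold as 1 - SSE/SST.  Fold assignments are shared across
    variants so that per-fold differences are paired.
    """
    X, Y = _design(features, demographics, survey)
    comp_cols = [c for c in X.columns if c.startswith("component_")]
    variant_cols = {
        "components": comp_cols,
        "demographics": ["age", "gender_f"],
        "combined": comp_cols + ["age", "gender_f"],
    }
    rkf = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(rkf.split(X))
    rows = []
    for item in Y.columns:
        y = Y[item].to_numpy(dtype=float)
        for s, (tr, te) in enumerate(splits):
            rep, fold = divmod(s, folds)
            if np.var(y[te]) == 0 or np.var(y[tr]) == 0:
                continue  # degenerate fold, skipped
            for variant, cols in variant_cols.items():
                Xv = X[cols].to_numpy(dtype=float)
                scaler = StandardScaler().fit(Xv[tr])
                model = ElasticNetCV(
                    l1_ratio=l1_ratio,
                    cv=inner_folds,
                    random_state=seed,
                    alphas=50,
                    max_iter=5000,
                )
                model.fit(scaler.transform(Xv[tr]), y[tr])
                pred = model.predict(scaler.transform(Xv[te]))
                sse = float(((y[te] - pred) ** 2).sum())
                sst = float(((y[te] - y[te].mean()) ** 2).sum())
                rows.append((item, variant, rep, fold, 1.0 - sse / sst))
    fold_r2 = pd.DataFrame(rows, columns=["item", "variant", "repeat", "fold", "r2"])
    n_test = len(X) // folds
    result = CVResult(
        fold_r2=fold_r2,
        n_train=len(X) - n_test,
        n_test=n_test,
        folds=folds,
        repeats=repeats,
        seed=seed,
    )
    result.comparisons = _compare_variants(result)
    return result


def _compare_variants(result: CVResult) -> pd.DataFrame:
    """Corrected resampled t-tests between model variants per item."""
    pairs = [("combined", "demographics"), ("components", "demographics"),
             ("combined", "components")]
    rows = []
    pivot = result.fold_r2.pivot_table(
        index=["item", "repeat", "fold"], columns="variant", values="r2"
    )
    for item in pivot.index.get_level_values("item").unique():
        sub = pivot.loc[item]
        for a, b in pairs:
            d = (sub[a] - sub[b]).to_numpy()
            t, p = corrected_resampled_ttest(d, result.n_train, result.n_test)
            rows.append((item, a, b, float(np.mean(d)), t, p))
    return pd.DataFrame(
        rows, columns=["item", "model", "baseline", "mean_diff", "t", "p"]
    ).set_index(["item", "model", "baseline"])


def corrected_resampled_ttest(
    differences: np.ndarray, n_train: int, n_test: int
) -> tuple[float, float]:
    """Corrected resampled t-test on paired per-fold performance differences.

    t = mean(d) / sqrt(var(d) * (1/J + n_test/n_train)) on J-1 degrees of
    freedom; the variance inflation accounts for the overlap of training
    sets across cross-validation folds.
    """
    d = np.asarray(differences, dtype=float)
    J = len(d)
    if J < 2:
        raise ValueError("need at least 2 paired fold results")
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0:
        if mean == 0:
            return 0.0, 1.0
        return float(np.sign(mean) * np.inf), 0.0  # zero variance, nonzero mean
    t = mean / np.sqrt(var * (1.0 / J + n_test / n_train))
    p = float(2.0 * stats.t.sf(abs(t), df=J - 1))
    return float(t), p


def word_level_correlations(
    data: AssociationDataset,
    survey: pd.DataFrame,
    min_retrievals: int = 10,
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """Correlation between retrieving a word at level 1 and each survey item.

    For every word retrieved by at least ``min_retrievals`` participants,
    the Pearson correlation between the binary retrieved indicator and each
    item rating; rows are ordered by descending mean correlation.  A
    companion boolean table marks |r| above ``flag_threshold`` in
    ``result.attrs['flagged']``.
    """
    level1 = data.level1()
    pids = survey["participant_id"]
    items = [c for c in survey.columns if c != "participant_id"]
    Y = survey.set_index("participant_id")[items].astype(float)
    retrieved = (
        level1.groupby("response")["participant_id"].agg(set)
    )
    n_by_word = retrieved.map(len)
    words = n_by_word[n_by_word >= min_retrievals].index
    rows = []
    for w in words:
        ind = pids.isin(retrieved[w]).to_numpy(dtype=float)
        if ind.std() == 0:
            rows.append([w] + [np.nan] * len(items))
            continue
        rows.append([w] + [
            float(stats.pearsonr(ind, Y[item].to_numpy()).statistic) for item in items
        ])
    table = pd.DataFrame(rows, columns=["word"] + items).set_index("word")
    table["mean_r"] = table[items].mean(axis=1)
    table = table.sort_values("mean_r", ascending=False)
    table.attrs["flagged"] = table[items].abs() > flag_threshold
    return table
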