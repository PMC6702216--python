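"""Balanced-ensemble random-forest prediction of functional likelihood.

Benchmark functional regions (transcribed regions over exons of genes with
documented loss-of-function phenotypes) and nonfunctional regions
(transcribed pseudogenes) train an ensemble of random forests, one per
balanced dataset.  Each forest contributes a vote fraction — the proportion
of trees calling a region a phenotype exon — and the functional likelihood
is the median vote fraction across balanced datasets.  Two thresholds
calibrated on the benchmark bound an ambiguous zone: T1 (5% false-positive
rate, a stringent functional call) and T2 (5% false-negative rate, a
stringent pseudogene-like call).  A three-class variant adds transcribed
miRNAs to capture non-coding RNA idiosyncrasies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata, ranksums
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression
from sklearn.metrics import precision_recall_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdPair",
    "impute_missing",
    "make_balanced_datasets",
    "train_two_class",
    "functional_likelihood",
    "calibrate_thresholds",
    "classify",
    "train_three_class",
    "evaluate_model",
    "EvalResult",
    "compare_algorithms",
    "CompareResult",
    "QuantileNormalizer",
    "parameter_sweep",
]

POSITIVE_CLASS = "phenotype_exon"
NEGATIVE_CLASS = "transcribed_pseudogene"
MIRNA_CLASS = "transcribed_miRNA"


@dataclass(frozen=True)
class ThresholdPair:
    """Functional-likelihood thresholds: T1 (5% FPR) and T2 (5% FNR)."""

    t1: float
    t2: float

    def __post_init__(self) -> None:
        for v in (self.t1, self.t2):
            if not (0.0 <= v <= 1.0):
                raise ValueError("thresholds must lie in [0, 1]")
        if self.t2 > self.t1:
            warnings.warn(
                "T2 exceeds T1: the ambiguous zone is empty and calls overlap",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# imputation


def _is_binary(col: pd.Series) -> bool:
    vals = set(col.dropna().unique())
    return vals <= {0.0, 1.0}


def impute_missing(
    table: pd.DataFrame, seed: int = 0, n_cycles: int = 10
) -> pd.DataFrame:
    """Chained single-equation regression imputation.

    Missing cells are initialized with the column median (mode for binary
    flags); features are then visited in ascending missingness for
    ``n_cycles`` cycles, re-predicting each feature's missing cells from all
    other features with a linear model (logistic for binary flags).
    Deterministic for a given seed.
    """
    if table.isna().all().any():
        bad = table.columns[table.isna().all()].tolist()
        raise ValueError(f"fully missing feature column(s): {bad}")
    out = table.astype(float).copy()
    missing_mask = out.isna()
    if not missing_mask.any().any():
        return out
    binary = {c: _is_binary(out[c]) for c in out.columns}
    for c in out.columns:
        if not missing_mask[c].any():
            continue
        observed = out[c].dropna()
        fill = observed.mode().iloc[0] if binary[c] else observed.median()
        out.loc[missing_mask[c], c] = fill
    order = (
        missing_mask.sum()[missing_mask.sum() > 0].sort_values().index.tolist()
    )
    for _ in range(n_cycles):
        for c in order:
            rows = missing_mask[c]
            predictors = [x for x in out.columns if x != c]
            X_obs = out.loc[~rows, predictors].values
            y_obs = table.loc[~rows, c].values
            X_mis = out.loc[rows, predictors].values
            if binary[c]:
                if len(np.unique(y_obs)) < 2:
                    pred = np.full(rows.sum(), y_obs[0])
                else:
                    # standardize predictors for a stable logistic fit
                    mu = X_obs.mean(axis=0)
                    sd = X_obs.std(axis=0)
                    sd[sd == 0] = 1.0
                    model = LogisticRegression(max_iter=1000, random_state=seed)
                    model.fit((X_obs - mu) / sd, y_obs.astype(int))
                    pred = model.predict((X_mis - mu) / sd).astype(float)
            else:
                model = LinearRegression()
                model.fit(X_obs, y_obs)
                pred = model.predict(X_mis)
            out.loc[rows, c] = pred
    return out


# ---------------------------------------------------------------------------
# balanced ensembles


def make_balanced_datasets(
    labels: pd.Series, n_sets: int, seed: int = 0
) -> list[pd.Index]:
    """Balanced benchmark subsets: each set holds min-class-size members of
    every class, sampled without replacement within the set.  When classes
    are already equal-sized, every set is the full benchmark."""
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    classes = labels.unique()
    if any((labels == c).sum() == 0 for c in classes) or len(classes) < 2:
        raise ValueError("every class must be non-empty")
    sizes = {c: int((labels == c).sum()) for c in classes}
    m = min(sizes.values())
    rng = np.random.default_rng(seed)
    sets: list[pd.Index] = []
    for _ in range(n_sets):
        idx: list = []
        for c in sorted(sizes):
            members = labels.index[labels == c]
            if sizes[c] == m:
                idx.extend(members)
            else:
                chosen = rng.choice(len(members), size=m, replace=False)
                idx.extend(members[chosen])
        sets.append(pd.Index(idx))
    return sets


def _vote_fractions(
    forest: RandomForestClassifier, X: np.ndarray, n_classes: int
) -> np.ndarray:
    """Per-class fraction of trees predicting each class (n x n_classes)."""
    votes = np.zeros((X.shape[0], n_classes))
    for tree in forest.estimators_:
        pred = tree.predict(X).astype(int)
        votes[np.arange(X.shape[0]), pred] += 1
    return votes / len(forest.estimators_)


def _make_forest(
    n_trees: int, max_depth: int, feat_prop: float | str, seed: int
) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features=feat_prop,
        random_state=seed,
        n_jobs=1,
    )


def train_two_class(
    features: pd.DataFrame,
    labels: pd.Series,
    balanced_sets: Sequence[pd.Index],
    cv_folds: int = 10,
    n_trees: int = 500,
    max_depth: int = 10,
    feat_prop: float | str = 0.25,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> pd.DataFrame:
    """Per-region, per-balanced-set vote-fraction scores.

    Benchmark members of each balanced set are scored out-of-fold under
    stratified cross-validation; every other region is scored by a forest
    refit on the full balanced set.  Scores are fractions of trees voting
    "phenotype exon", so they live on the 1/n_trees grid.
    """
    if features.isna().any().any():
        raise ValueError("features must be complete (impute first)")
    scores = pd.DataFrame(
        np.nan, index=features.index, columns=range(len(balanced_sets))
    )
    rng = np.random.default_rng(seed)
    for si, members in enumerate(balanced_sets):
        y = (labels.loc[members] == positive).astype(int).values
        X = features.loc[members].values
        if min(np.bincount(y)) < cv_folds:
            raise ValueError("fewer members per class than CV folds")
        sub_seed = int(rng.integers(0, 2**31 - 1))
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=sub_seed)
        col = np.full(len(members), np.nan)
        for fold_i, (train_idx, test_idx) in enumerate(skf.split(X, y)):
            forest = _make_forest(n_trees, max_depth, feat_prop, sub_seed + fold_i)
            forest.fit(X[train_idx], y[train_idx])
            votes = _vote_fractions(forest, X[test_idx], 2)
            pos_col = list(forest.classes_).index(1)
            col[test_idx] = votes[:, pos_col]
        scores.loc[members, si] = col
        others = features.index.difference(members)
        if len(others):
            forest = _make_forest(n_trees, max_depth, feat_prop, sub_seed)
            forest.fit(X, y)
            votes = _vote_fractions(forest, features.loc[others].values, 2)
            pos_col = list(forest.classes_).index(1)
            scores.loc[others, si] = votes[:, pos_col]
    return scores


def functional_likelihood(scores: Sequence[float]) -> float:
    """Median vote fraction across balanced datasets (even counts average
    the central pair)."""
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("at least one score is required")
    return float(np.median(arr))


def _nearest_rank(values: Sequence[float], percentile: float) -> float:
    ordered = sorted(values)
    rank = int(np.ceil(percentile / 100.0 * len(ordered)))
    rank = min(max(rank, 1), len(ordered))
    return float(ordered[rank - 1])


def calibrate_thresholds(
    likelihoods: pd.Series,
    labels: pd.Series,
    positive: str = POSITIVE_CLASS,
    negative: str = NEGATIVE_CLASS,
) -> ThresholdPair:
    """Calibrate T1/T2 on benchmark likelihoods.

    T1 is the nearest-rank 95th percentile of nonfunctional-class scores —
    a functional call (score > T1) misclassifies at most 5% of pseudogenes.
    T2 is the nearest-rank 5th percentile of functional-class scores — a
    pseudogene-like call (score < T2) misclassifies at most 5% of phenotype
    exons.
    """
    neg = likelihoods[labels[labels == negative].index.intersection(likelihoods.index)]
    pos = likelihoods[labels[labels == positive].index.intersection(likelihoods.index)]
    if neg.empty or pos.empty:
        raise ValueError("both benchmark classes must be present")
    t1 = _nearest_rank(neg.values, 95.0)
    t2 = _nearest_rank(pos.values, 5.0)
    return ThresholdPair(t1=t1, t2=t2)


def classify(likelihood: float, thresholds: ThresholdPair) -> str:
    """Final call: functional above T1, pseudogene-like below T2, ambiguous
    in between (scores exactly at a threshold stay ambiguous)."""
    if likelihood > thresholds.t1:
        return "functional"
    if likelihood < thresholds.t2:
        return "pseudogene-like"
    return "ambiguous"


def train_three_class(
    features: pd.DataFrame,
    labels: pd.Series,
    cv_folds: int = 20,
    sets_per_fold: int = 250,
    n_trees: int = 500,
    max_depth: int = 10,
    feat_prop: float | str = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Three-class balanced-ensemble prediction (exon / pseudogene / miRNA).

    Benchmark members are scored out-of-fold; per fold, ``sets_per_fold``
    balanced training sets are drawn (equal members of each class, sized to
    the smallest class in the training split) to adjust for the scarcity of
    transcribed miRNAs.  Scores are mean tree-vote fractions per class and
    sum to 1; the predicted class is the argmax, ties broken toward
    pseudogene; exon- or miRNA-predicted regions are called functional.
    """
    if features.isna().any().any():
        raise ValueError("features must be complete (impute first)")
    class_names = sorted(labels.unique())
    if len(class_names) != 3:
        raise ValueError("exactly three benchmark classes are required")
    min_class = min(int((labels == c).sum()) for c in class_names)
    folds = cv_folds
    if min_class < cv_folds:
        folds = max(2, min_class)
        warnings.warn(
            f"smallest class ({min_class}) below fold count; using {folds} folds",
            stacklevel=2,
        )
    encode = {c: i for i, c in enumerate(class_names)}
    idx = labels.index
    X_all = features.loc[idx].values
    y_all = labels.map(encode).values
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
    )
    score_sum = np.zeros((len(idx), 3))
    for train_idx, test_idx in skf.split(X_all, y_all):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sets = make_balanced_datasets(
            pd.Series(y_all[train_idx]), sets_per_fold, seed=sub_seed
        )
        acc = np.zeros((len(test_idx), 3))
        for k, members in enumerate(sets):
            rows = train_idx[np.asarray(members, dtype=int)]
            forest = _make_forest(n_trees, max_depth, feat_prop, sub_seed + k)
            forest.fit(X_all[rows], y_all[rows])
            votes = np.zeros((len(test_idx), 3))
            frac = _vote_fractions(forest, X_all[test_idx], len(forest.classes_))
            for local_col, cls in enumerate(forest.classes_):
                votes[:, int(cls)] = frac[:, local_col]
            acc += votes
        score_sum[test_idx] = acc / len(sets)
    result = pd.DataFrame(
        score_sum, index=idx, columns=[f"score_{c}" for c in class_names]
    )
    pseudo_i = encode.get(NEGATIVE_CLASS, 0)
    predicted = []
    for row in score_sum:
        best = row.max()
        tied = [i for i, v in enumerate(row) if v == best]
        choice = pseudo_i if pseudo_i in tied else min(tied)
        predicted.append(class_names[choice])
    result["predicted_class"] = predicted
    result["functional"] = [p != NEGATIVE_CLASS for p in predicted]
    return result


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalResult:
    auc: float
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray


def evaluate_model(scores: Sequence[float], labels: Sequence[int]) -> EvalResult:
    """AUC-ROC by the rank statistic (midranks for ties) plus the
    precision-recall curve over all score thresholds."""
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    return EvalResult(
        auc=float(auc), precision=precision, recall=recall, thresholds=thresholds
    )


def parameter_sweep(
    features: pd.DataFrame,
    labels: pd.Series,
    depths: Sequence[int] = (3, 5, 10, 50),
    feat_props: Sequence[float | str] = (0.1, 0.25, 0.5, 0.75, "sqrt", "log2"),
    cv_folds: int = 10,
    n_trees: int = 100,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> pd.DataFrame:
    """Cross-validated AUC over the max-depth x feature-proportion grid on
    one balanced dataset."""
    members = make_balanced_datasets(labels, 1, seed=seed)[0]
    rows = []
    for depth in depths:
        for fp in feat_props:
            scores = train_two_class(
                features.loc[members],
                labels.loc[members],
                [members],
                cv_folds=cv_folds,
                n_trees=n_trees,
                max_depth=depth,
                feat_prop=fp,
                seed=seed,
                positive=positive,
            )
            y = (labels.loc[members] == positive).astype(int)
            auc = evaluate_model(scores.loc[members, 0].values, y.values).auc
            rows.append({"max_depth": depth, "feat_prop": str(fp), "auc": auc})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# algorithm comparison


class QuantileNormalizer:
    """Quantile normalization against a rank-average reference distribution
    learned from the training split only."""

    def fit(self, X: pd.DataFrame) -> "QuantileNormalizer":
        values = np.sort(np.asarray(X, dtype=float), axis=0)
        self.reference_ = values.mean(axis=1)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = np.asarray(X, dtype=float)
        n_ref = len(self.reference_)
        ref_q = (np.arange(n_ref) + 0.5) / n_ref
        out = np.empty_like(arr)
        m = arr.shape[0]
        for j in range(arr.shape[1]):
            q = (rankdata(arr[:, j]) - 0.5) / m
            out[:, j] = np.interp(q, ref_q, self.reference_)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


@dataclass
class CompareResult:
    aucs: pd.DataFrame
    ranksum_pvalues: dict[tuple[str, str], float]


def compare_algorithms(
    features: pd.DataFrame,
    labels: pd.Series,
    n_boot: int = 100,
    n_test_per_class: int = 25,
    n_train_per_class: int = 225,
    lasso_lambdas: Sequence[float] = (1e-2, 5e-2),
    n_trees: int = 500,
    max_depth: int = 10,
    feat_prop: float | str = 0.25,
    seed: int = 0,
    positive: str = POSITIVE_CLASS,
) -> CompareResult:
    """Bootstrap comparison of the full random forest against logistic
    regression and LASSO-feature-selected forests.

    Each repeat draws disjoint balanced train/test splits, quantile
    normalizes feature values (reference learned on the training split), and
    records test AUC per arm.  A LASSO penalty selecting zero features
    degrades that arm to an intercept-only model (AUC ~ 0.5) with a warning.
    """
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError("two classes are required")
    need = n_test_per_class + n_train_per_class
    for c in classes:
        if int((labels == c).sum()) < need:
            raise ValueError(
                f"class {c!r} smaller than n_test + n_train = {need}"
            )
    rng = np.random.default_rng(seed)
    arms = ["random_forest", "logistic"] + [
        f"lasso_rf_lambda_{lam:g}" for lam in lasso_lambdas
    ]
    rows = []
    for rep in range(n_boot):
        train_idx: list = []
        test_idx: list = []
        for c in classes:
            members = labels.index[labels == c].to_numpy()
            chosen = rng.choice(len(members), size=need, replace=False)
            test_idx.extend(members[chosen[:n_test_per_class]])
            train_idx.extend(members[chosen[n_test_per_class:]])
        X_train = features.loc[train_idx]
        X_test = features.loc[test_idx]
        y_train = (labels.loc[train_idx] == positive).astype(int).values
        y_test = (labels.loc[test_idx] == positive).astype(int).values
        norm = QuantileNormalizer().fit(X_train)
        Xtr = norm.transform(X_train).values
        Xte = norm.transform(X_test).values
        rep_seed = int(rng.integers(0, 2**31 - 1))
        result = {"repeat": rep}
        forest = _make_forest(n_trees, max_depth, feat_prop, rep_seed)
        forest.fit(Xtr, y_train)
        pos_col = list(forest.classes_).index(1)
        result["random_forest"] = evaluate_model(
            forest.predict_proba(Xte)[:, pos_col], y_test
        ).auc
        logistic = LogisticRegression(max_iter=1000, random_state=rep_seed)
        logistic.fit(Xtr, y_train)
        result["logistic"] = evaluate_model(
            logistic.predict_proba(Xte)[:, 1], y_test
        ).auc
        for lam in lasso_lambdas:
            lasso = Lasso(alpha=lam, max_iter=10_000, random_state=rep_seed)
            lasso.fit(Xtr, y_train)
            selected = np.flatnonzero(lasso.coef_)
            arm = f"lasso_rf_lambda_{lam:g}"
            if selected.size == 0:
                logger.warning(
                    "LASSO lambda=%g selected zero features; intercept-only arm",
                    lam,
                )
                result[arm] = 0.5
                continue
            sub_forest = _make_forest(n_trees, max_depth, feat_prop, rep_seed)
            sub_forest.fit(Xtr[:, selected], y_train)
            pos_col = list(sub_forest.classes_).index(1)
            result[arm] = evaluate_model(
                sub_forest.predict_proba(Xte[:, selected])[:, pos_col], y_test
            ).auc
        rows.append(result)
    aucs = pd.DataFrame(rows).set_index("repeat")
    pvalues: dict[tuple[str, str], float] = {}
    for i, a in enumerate(arms):
        for b in arms[i + 1 :]:
            pvalues[(a, b)] = float(ranksums(aucs[a], aucs[b]).pvalue)
    return CompareResult(aucs=aucs, ranksum_pvalues=pvalues)
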