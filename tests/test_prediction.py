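import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LinearRegression
from sklearn.metrics import roc_auc_score

from itrpred.prediction import (
    ThresholdPair,
    calibrate_thresholds,
    classify,
    compare_algorithms,
    evaluate_model,
    functional_likelihood,
    impute_missing,
    make_balanced_datasets,
    QuantileNormalizer,
    train_three_class,
    train_two_class,
)
from oracle_utils import auc_by_pair_counting


def separable_table(n_per_class=40, n_features=6, seed=0, classes=("phenotype_exon", "transcribed_pseudogene")):
    """Classes with disjoint feature supports: trivially separable."""
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for ci, cls in enumerate(classes):
        block = rng.normal(ci * 10.0, 0.5, size=(n_per_class, n_features))
        idx = [f"{cls}_{i}" for i in range(n_per_class)]
        frames.append(pd.DataFrame(block, index=idx))
        labels.extend([cls] * n_per_class)
    table = pd.concat(frames)
    table.columns = [f"f{i}" for i in range(n_features)]
    return table, pd.Series(labels, index=table.index)


class TestImputation:
    def test_complete_table_unchanged(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        pd.testing.assert_frame_equal(impute_missing(table), table)

    def test_collinear_feature_imputed_by_regression(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        b = 2.0 * a + 1.0
        table = pd.DataFrame({"a": a, "b": b, "c": rng.normal(size=50)})
        table.loc[3, "b"] = np.nan
        direct = LinearRegression().fit(
            table.drop(index=3)[["a", "c"]], table.drop(index=3)["b"]
        ).predict(table.loc[[3], ["a", "c"]])[0]
        got = impute_missing(table)
        assert got.loc[3, "b"] == pytest.approx(direct, rel=1e-6)
        assert got.loc[3, "b"] == pytest.approx(2.0 * a[3] + 1.0, rel=1e-4)

    def test_binary_flags_stay_binary(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60)
        flag = (x > 0).astype(float)
        table = pd.DataFrame({"x": x, "flag": flag})
        table.loc[5, "flag"] = np.nan
        got = impute_missing(table)
        assert got.loc[5, "flag"] in (0.0, 1.0)

    def test_fully_missing_column_errors(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError):
            impute_missing(table)


class TestBalancedDatasets:
    def test_unequal_classes_downsample_majority(self):
        labels = pd.Series(
            ["phenotype_exon"] * 513 + ["transcribed_pseudogene"] * 262
        )
        sets = make_balanced_datasets(labels, 5, seed=0)
        for s in sets:
            counts = labels.loc[s].value_counts()
            assert counts["phenotype_exon"] == 262
            assert counts["transcribed_pseudogene"] == 262
            assert len(s) == len(set(s))  # without replacement

    def test_equal_classes_give_full_benchmark(self):
        labels = pd.Series(["a"] * 50 + ["b"] * 50)
        sets = make_balanced_datasets(labels, 3, seed=0)
        assert all(len(s) == 100 for s in sets)

    def test_reproducible_under_seed(self):
        labels = pd.Series(["a"] * 30 + ["b"] * 10)
        a = make_balanced_datasets(labels, 4, seed=9)
        b = make_balanced_datasets(labels, 4, seed=9)
        assert all(x.equals(y) for x, y in zip(a, b))

    def test_invalid_n_sets_errors(self):
        with pytest.raises(ValueError):
            make_balanced_datasets(pd.Series(["a", "b"]), 0)


class TestFunctionalLikelihood:
    @pytest.mark.parametrize(
        "scores,expected",
        [([0.2, 0.5, 0.9], 0.5), ([0.4, 0.6], 0.5), ([0.7, 0.7, 0.7], 0.7)],
    )
    def test_median(self, scores, expected):
        assert functional_likelihood(scores) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            functional_likelihood([])

    def test_invariant_to_set_order(self):
        rng = np.random.default_rng(3)
        scores = rng.random(25)
        assert functional_likelihood(scores) == functional_likelihood(scores[::-1])


class TestThresholds:
    def test_nearest_rank_percentile(self):
        neg = pd.Series(np.arange(1, 101) / 100.0, index=[f"n{i}" for i in range(100)])
        pos = pd.Series(np.linspace(0.5, 1.0, 100), index=[f"p{i}" for i in range(100)])
        lik = pd.concat([neg, pos])
        labels = pd.Series(
            ["transcribed_pseudogene"] * 100 + ["phenotype_exon"] * 100,
            index=lik.index,
        )
        thr = calibrate_thresholds(lik, labels)
        assert thr.t1 == pytest.approx(0.95)
        assert thr.t2 == pytest.approx(np.sort(pos.values)[4])

    def test_separated_classes_give_zero_error_rates(self):
        neg = pd.Series([0.1] * 20, index=[f"n{i}" for i in range(20)])
        pos = pd.Series([0.9] * 20, index=[f"p{i}" for i in range(20)])
        lik = pd.concat([neg, pos])
        labels = pd.Series(
            ["transcribed_pseudogene"] * 20 + ["phenotype_exon"] * 20, index=lik.index
        )
        thr = calibrate_thresholds(lik, labels)
        assert (neg > thr.t1).mean() == 0.0
        assert (pos < thr.t2).mean() == 0.0

    def test_missing_class_errors(self):
        lik = pd.Series([0.5], index=["a"])
        labels = pd.Series(["phenotype_exon"], index=["a"])
        with pytest.raises(ValueError):
            calibrate_thresholds(lik, labels)

    def test_inverted_pair_warns(self):
        with pytest.warns(UserWarning):
            ThresholdPair(t1=0.2, t2=0.5)

    @pytest.mark.parametrize(
        "lik,expected",
        [(0.99, "functional"), (0.10, "pseudogene-like"), (0.60, "ambiguous"), (0.29, "ambiguous"), (0.45, "ambiguous")],
    )
    def test_classify_with_paper_thresholds(self, lik, expected):
        assert classify(lik, ThresholdPair(0.60, 0.29)) == expected


class TestTwoClassEnsemble:
    def test_separable_features_give_perfect_auc(self):
        table, labels = separable_table(n_per_class=30)
        sets = make_balanced_datasets(labels, 2, seed=0)
        scores = train_two_class(
            table, labels, sets, cv_folds=5, n_trees=50, seed=0
        )
        lik = scores.median(axis=1)
        y = (labels == "phenotype_exon").astype(int)
        assert evaluate_model(lik.values, y.values).auc == pytest.approx(1.0)
        assert scores.values.min() >= 0.0 and scores.values.max() <= 1.0

    def test_non_benchmark_regions_scored(self):
        table, labels = separable_table(n_per_class=25)
        extra = pd.DataFrame(
            np.random.default_rng(2).normal(0, 0.5, size=(5, table.shape[1])),
            index=[f"itr{i}" for i in range(5)],
            columns=table.columns,
        )
        all_features = pd.concat([table, extra])
        sets = make_balanced_datasets(labels, 1, seed=0)
        scores = train_two_class(
            all_features, labels, sets, cv_folds=5, n_trees=50, seed=0
        )
        # ITR-like rows resemble the phenotype-exon cluster at mean 0
        assert scores.loc[extra.index, 0].mean() > 0.5
        assert not scores.isna().any().any()

    def test_incomplete_features_error(self):
        table, labels = separable_table(n_per_class=15)
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            train_two_class(table, labels, [table.index], cv_folds=3, n_trees=10)

    def test_fewer_members_than_folds_errors(self):
        table, labels = separable_table(n_per_class=4)
        with pytest.raises(ValueError):
            train_two_class(table, labels, [table.index], cv_folds=10, n_trees=10)


class TestThreeClass:
    def test_separable_three_classes_recovered(self):
        table, labels = separable_table(
            n_per_class=30,
            classes=(
                "phenotype_exon",
                "transcribed_pseudogene",
                "transcribed_miRNA",
            ),
        )
        result = train_three_class(
            table, labels, cv_folds=3, sets_per_fold=5, n_trees=50, seed=0
        )
        for cls in labels.unique():
            recall = (result.loc[labels == cls, "predicted_class"] == cls).mean()
            assert recall > 0.9
        sums = result[[c for c in result.columns if c.startswith("score_")]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_exon_and_mirna_predictions_are_functional(self):
        table, labels = separable_table(
            n_per_class=30,
            classes=(
                "phenotype_exon",
                "transcribed_pseudogene",
                "transcribed_miRNA",
            ),
        )
        result = train_three_class(
            table, labels, cv_folds=3, sets_per_fold=5, n_trees=50, seed=0
        )
        func = result[result.predicted_class != "transcribed_pseudogene"]
        assert func.functional.all()
        nonfunc = result[result.predicted_class == "transcribed_pseudogene"]
        assert (~nonfunc.functional).all()

    def test_small_class_reduces_folds_with_warning(self):
        table, labels = separable_table(
            n_per_class=30,
            classes=("phenotype_exon", "transcribed_pseudogene", "transcribed_miRNA"),
        )
        # shrink the miRNA class below the fold count
        keep = labels.index[:-25]
        with pytest.warns(UserWarning, match="below fold count"):
            train_three_class(
                table.loc[keep], labels.loc[keep], cv_folds=20,
                sets_per_fold=2, n_trees=10, seed=0,
            )


class TestEvaluateModel:
    def test_perfect_and_inverted_ranking(self):
        labels = [0, 0, 1, 1]
        assert evaluate_model([0.1, 0.2, 0.8, 0.9], labels).auc == 1.0
        assert evaluate_model([0.9, 0.8, 0.2, 0.1], labels).auc == 0.0

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            evaluate_model([0.5, 0.6], [1, 1])

    def test_matches_pair_counting_and_sklearn(self):
        """Rank-statistic AUC equals both the explicit pair-counting oracle
        and the library implementation, including under ties."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores = np.round(rng.random(30), 1)  # coarse grid forces ties
            labels = rng.integers(0, 2, size=30)
            if labels.sum() in (0, 30):
                continue
            auc = evaluate_model(scores, labels).auc
            assert auc == pytest.approx(auc_by_pair_counting(scores, labels))
            assert auc == pytest.approx(roc_auc_score(labels, scores))


class TestQuantileNormalizer:
    def test_train_columns_share_distribution(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(
            {"a": rng.normal(0, 1, 100), "b": rng.exponential(5, 100)}
        )
        norm = QuantileNormalizer().fit(X)
        out = norm.transform(X)
        np.testing.assert_allclose(
            np.sort(out["a"].values), np.sort(out["b"].values), rtol=1e-8
        )


class TestCompareAlgorithms:
    def test_separable_data_all_arms_near_one(self):
        table, labels = separable_table(n_per_class=40, seed=4)
        result = compare_algorithms(
            table,
            labels,
            n_boot=3,
            n_test_per_class=8,
            n_train_per_class=30,
            n_trees=30,
            lasso_lambdas=(1e-2,),
            seed=0,
        )
        assert (result.aucs >= 0.95).all().all()
        assert ("random_forest", "logistic") in result.ranksum_pvalues

    def test_degenerate_lasso_falls_back_to_chance(self, caplog):
        table, labels = separable_table(n_per_class=40, seed=4)
        with caplog.at_level("WARNING"):
            result = compare_algorithms(
                table,
                labels,
                n_boot=2,
                n_test_per_class=8,
                n_train_per_class=30,
                n_trees=20,
                lasso_lambdas=(1e6,),
                seed=0,
            )
        assert (result.aucs["lasso_rf_lambda_1e+06"] == 0.5).all()
        assert "selected zero features" in caplog.text

    def test_insufficient_class_size_errors(self):
        table, labels = separable_table(n_per_class=10)
        with pytest.raises(ValueError):
            compare_algorithms(table, labels, n_boot=1, n_test_per_class=8, n_train_per_class=30)
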