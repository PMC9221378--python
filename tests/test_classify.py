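"""LDA + LOOCV, confusion metrics, merged-malignant pooling, Mann-Whitney."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from octraman.classify import (
    FeatureMatrix,
    accuracy,
    confusion_metrics,
    fit_lda,
    loocv,
    mann_whitney,
    mann_whitney_matrix,
    merge_malignant,
    significance_stars,
)


def make_fm(X, labels, tag="test"):
    ids = [f"s{i:03d}" for i in range(len(X))]
    return FeatureMatrix(
        X=pd.DataFrame(np.asarray(X, dtype=float), index=ids),
        labels=pd.Series(list(labels), index=ids),
        dataset_tag=tag,
    )


def gaussian_classes(rng, means, n, sd=0.5, labels=None):
    X, y = [], []
    labels = labels or [f"c{k}" for k in range(len(means))]
    for mean, lab in zip(means, labels):
        X.append(rng.normal(mean, sd, size=(n, np.shape(mean)[0] if np.ndim(mean) else 1)))
        y += [lab] * n
    return make_fm(np.vstack(X), y)


class TestFitLDA:
    def test_separated_classes_reach_perfect_training_accuracy(self):
        rng = np.random.default_rng(0)
        fm = gaussian_classes(rng, [-5.0, 5.0], n=20, sd=0.5)
        model = fit_lda(fm)
        assert (model.predict(fm.X) == fm.labels.to_numpy()).mean() == 1.0

    def test_permuted_labels_generalize_at_chance(self):
        """With labels shuffled there is nothing to learn: held-out accuracy
        sits at chance for two balanced classes (training accuracy is allowed
        a modest overfitting excess)."""
        rng = np.random.default_rng(1)
        held, train = [], []
        for _ in range(100):
            X = rng.normal(0, 1, size=(40, 1))
            y = np.array(["a"] * 20 + ["b"] * 20)
            rng.shuffle(y)
            fm = make_fm(X[:20], y[:20])
            model = fit_lda(fm)
            train.append((model.predict(fm.X) == y[:20]).mean())
            held.append((model.predict(pd.DataFrame(X[20:])) == y[20:]).mean())
        se = np.sqrt(0.25 / 20 / 100)
        assert abs(np.mean(held) - 0.5) < 4 * se
        assert np.mean(train) < 0.75

    def test_four_classes_project_to_three_dimensions(self):
        rng = np.random.default_rng(2)
        fm = gaussian_classes(
            rng,
            [np.zeros(6), np.ones(6), 2 * np.ones(6), 3 * np.ones(6)],
            n=8,
            labels=["skin", "lipoma", "MCT", "STS"],
        )
        model = fit_lda(fm)
        assert model.transform(fm.X).shape == (32, 3)

    def test_degenerate_feature_triggers_named_shrinkage_fallback(self):
        rng = np.random.default_rng(3)
        X = np.column_stack([rng.normal(size=20), np.full(20, 7.0)])
        fm = make_fm(X, ["a"] * 10 + ["b"] * 10)
        fm.X.columns = ["ok", "constant"]
        with pytest.warns(RuntimeWarning, match="constant"):
            model = fit_lda(fm)
        assert set(model.predict(fm.X)) <= {"a", "b"}

    def test_missing_values_rejected(self):
        X = pd.DataFrame({"f": [1.0, np.nan, 2.0, 3.0]}, index=list("abcd"))
        with pytest.raises(ValueError, match="missing"):
            FeatureMatrix(X=X, labels=pd.Series(list("xxyy"), index=list("abcd")))


class TestLOOCV:
    def test_prediction_table_has_one_row_per_sample(self):
        rng = np.random.default_rng(4)
        fm = gaussian_classes(rng, [-4.0, 4.0], n=6)
        table = loocv(fm)
        assert len(table) == 12
        assert set(table["sample_id"]) == set(fm.X.index)
        assert list(table.columns[:3]) == ["sample_id", "true_label", "predicted_label"]
        assert "LD1" in table.columns

    def test_perfectly_separated_classes_classified_without_error(self):
        rng = np.random.default_rng(5)
        fm = gaussian_classes(rng, [-8.0, 0.0, 8.0], n=6, sd=0.4)
        table = loocv(fm)
        assert (table["true_label"] == table["predicted_label"]).all()

    def test_duplicated_dataset_does_not_lose_accuracy(self):
        rng = np.random.default_rng(6)
        fm = gaussian_classes(rng, [-3.0, 3.0], n=8, sd=1.0)
        single = accuracy(loocv(fm))
        X2 = pd.concat([fm.X, fm.X.set_index(fm.X.index + "_dup")])
        y2 = pd.concat([fm.labels, fm.labels.set_axis(fm.X.index + "_dup")])
        doubled = accuracy(loocv(FeatureMatrix(X=X2, labels=y2)))
        assert doubled >= single

    def test_singleton_class_rejected_by_name(self):
        X = np.arange(5.0).reshape(-1, 1)
        with pytest.raises(ValueError, match="lonely"):
            make_fm(X, ["a", "a", "b", "b", "lonely"])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(7)
        fm = gaussian_classes(rng, [-2.0, 2.0], n=7, sd=1.5)
        table = loocv(fm).set_index("sample_id")
        perm = rng.permutation(fm.X.index)
        fm2 = FeatureMatrix(X=fm.X.loc[perm], labels=fm.labels.loc[perm])
        table2 = loocv(fm2).set_index("sample_id")
        pd.testing.assert_series_equal(
            table["predicted_label"].sort_index(), table2["predicted_label"].sort_index()
        )


class TestMergedMalignant:
    def test_cross_malignant_confusion_counts_as_correct(self):
        table = pd.DataFrame(
            {"sample_id": ["a"], "true_label": ["MCT"], "predicted_label": ["STS"]}
        )
        merged = merge_malignant(table)
        assert merged.loc[0, "true_label"] == merged.loc[0, "predicted_label"] == "malignant"

    def test_benign_rows_untouched(self):
        table = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "true_label": ["skin", "lipoma"],
                "predicted_label": ["skin", "MCT"],
            }
        )
        merged = merge_malignant(table)
        assert merged["true_label"].tolist() == ["skin", "lipoma"]
        assert merged["predicted_label"].tolist() == ["skin", "malignant"]

    def test_all_mct_table_collapses_to_malignant(self):
        table = pd.DataFrame(
            {"sample_id": list("abc"), "true_label": ["MCT"] * 3,
             "predicted_label": ["MCT"] * 3}
        )
        merged = merge_malignant(table)
        assert (merged[["true_label", "predicted_label"]] == "malignant").all().all()

    @pytest.mark.parametrize("seed", range(5))
    def test_coarsening_never_creates_new_errors(self, seed):
        rng = np.random.default_rng(seed)
        classes = ["skin", "lipoma", "MCT", "STS"]
        table = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(40)],
                "true_label": rng.choice(classes, 40),
                "predicted_label": rng.choice(classes, 40),
            }
        )
        merged = merge_malignant(table)
        assert accuracy(merged) >= accuracy(table)
        if {"MCT", "STS"} <= set(table["true_label"]):
            sens = confusion_metrics(merged, "malignant").sensitivity
            per_class = [
                confusion_metrics(table, c).sensitivity
                for c in ("MCT", "STS")
            ]
            assert sens >= min(per_class)


class TestConfusionMetrics:
    def test_perfect_predictions(self):
        table = pd.DataFrame(
            {"sample_id": range(10), "true_label": ["A"] * 10, "predicted_label": ["A"] * 10}
        )
        table = pd.concat(
            [table, pd.DataFrame({"sample_id": [10], "true_label": ["B"],
                                  "predicted_label": ["B"]})],
            ignore_index=True,
        )
        m = confusion_metrics(table, "A")
        assert (m.sensitivity, m.specificity) == (1.0, 1.0)
        assert (m.tp, m.fn, m.tn, m.fp) == (10, 0, 1, 0)

    def test_hand_counted_confusion_table(self):
        table = pd.DataFrame(
            {
                "sample_id": range(10),
                "true_label": ["A"] * 4 + ["B"] * 6,
                "predicted_label": ["A"] * 3 + ["B"] + ["B"] * 6,
            }
        )
        m = confusion_metrics(table, "A")
        assert m.sensitivity == 0.75
        assert m.specificity == 1.0
        assert m.tp + m.fn + m.tn + m.fp == 10

    def test_all_classes_perfect_when_predicted_equals_true(self):
        rng = np.random.default_rng(8)
        y = rng.choice(["A", "B", "C"], 30)
        table = pd.DataFrame(
            {"sample_id": range(30), "true_label": y, "predicted_label": y}
        )
        for c in "ABC":
            m = confusion_metrics(table, c)
            assert m.sensitivity == m.specificity == 1.0

    def test_absent_class_rejected(self):
        table = pd.DataFrame(
            {"sample_id": [0], "true_label": ["A"], "predicted_label": ["A"]}
        )
        with pytest.raises(ValueError, match="absent"):
            confusion_metrics(table, "Z")


def enumeration_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(group1):
        g1 = pooled[list(group1)]
        g2 = pooled[[i for i in idx if i not in set(group1)]]
        return sum((a > b) + 0.5 * (a == b) for a in g1 for b in g2)

    u_obs = u_of(range(n1))
    center = n1 * (len(pooled) - n1) / 2
    dev = abs(u_obs - center)
    us = [u_of(c) for c in combinations(idx, n1)]
    return float(np.mean([abs(u - center) >= dev - 1e-12 for u in us]))


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        u, p = mann_whitney([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_not_significant(self):
        u, p = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert p == pytest.approx(1.0)
        assert significance_stars(p) == "NS"

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match="untestable"):
            mann_whitney([1, 2], [3, 4, 5])

    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 4), (7, 7)])
    def test_exact_p_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(3):
            x = rng.normal(size=n1)
            y = rng.normal(loc=rng.uniform(0, 2), size=n2)
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(enumeration_p(x, y), abs=1e-12)

    def test_star_thresholds(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.06) == "NS"

    def test_matrix_covers_all_pairs_and_features(self):
        rng = np.random.default_rng(9)
        fm = gaussian_classes(
            rng, [0.0, 1.0, 5.0], n=5, sd=0.5, labels=["skin", "lipoma", "MCT"]
        )
        fm.X.columns = ["f0"]
        table = mann_whitney_matrix(fm)
        assert len(table) == 3  # 3 class pairs x 1 feature
        assert set(table["stars"]) <= {"***", "**", "*", "NS"}
        row = table[(table.class_a == "skin") & (table.class_b == "MCT")].iloc[0]
        assert row["p_value"] < 0.05
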