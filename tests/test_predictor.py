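"""Categorical naive Bayes, cross-validation, feature selection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gcsubtype.predictor import (
    FIXED_FEATURES,
    cross_validate,
    fit_nb,
    predict,
    select_features,
)


def brute_force_posteriors(features, labels, query, alpha=1.0):
    """Bayes arithmetic by direct counting with Laplace smoothing."""
    classes = sorted(labels.unique())
    posts = []
    for c in classes:
        mask = labels == c
        p = mask.mean()
        for col in features.columns:
            vocab = sorted(features[col].astype(str).unique())
            count = (features.loc[mask, col].astype(str) == str(query[col])).sum()
            p *= (count + alpha) / (mask.sum() + alpha * (len(vocab) + 1))
        posts.append(p)
    posts = np.array(posts)
    return posts / posts.sum(), classes


@pytest.fixture
def toy():
    features = pd.DataFrame({
        "f1": ["a", "a", "b", "b", "a", "b"],
        "f2": ["x", "y", "x", "y", "x", "y"],
        "f3": ["1", "1", "2", "2", "2", "1"],
    }, index=[f"S{i}" for i in range(6)])
    labels = pd.Series([1, 1, 2, 2, 1, 2], index=features.index)
    return features, labels


class TestNaiveBayes:
    def test_posteriors_match_brute_force_bayes(self, toy):
        features, labels = toy
        model = fit_nb(features, labels, alpha=1.0)
        for _, query in features.iterrows():
            ours = predict(model, query.to_frame().T)
            expected, classes = brute_force_posteriors(features, labels, query)
            for c, e in zip(classes, expected):
                assert ours[f"p_{c}"].iloc[0] == pytest.approx(e, abs=1e-12)

    def test_posterior_rows_sum_to_one(self, toy):
        features, labels = toy
        model = fit_nb(features, labels)
        posts = predict(model, features)[[f"p_{c}" for c in model.classes]]
        np.testing.assert_allclose(posts.sum(axis=1), 1.0, atol=1e-12)

    def test_perfect_separator_gives_training_accuracy_one(self):
        features = pd.DataFrame({"f": ["a"] * 10 + ["b"] * 10})
        labels = pd.Series([1] * 10 + [2] * 10)
        model = fit_nb(features, labels)
        assert (predict(model, features)["subtype"] == labels).all()

    def test_large_alpha_limit_predicts_prior_argmax(self):
        features = pd.DataFrame({"f": ["a", "b", "a", "b", "a", "a", "a"]})
        labels = pd.Series([1, 2, 1, 2, 1, 1, 1])  # prior favors class 1
        model = fit_nb(features, labels, alpha=1e9)
        out = predict(model, pd.DataFrame({"f": ["b"]}))
        assert out["subtype"].iloc[0] == 1
        for col, table in model.conditionals.items():
            np.testing.assert_allclose(table, table[0, 0], rtol=1e-6)

    def test_unseen_category_predicts_without_crash(self, toy):
        features, labels = toy
        model = fit_nb(features, labels)
        out = predict(model, pd.DataFrame({"f1": ["z"], "f2": ["x"], "f3": ["1"]}))
        assert np.isfinite(out[[f"p_{c}" for c in model.classes]].to_numpy()).all()

    def test_column_order_invariance(self, toy):
        features, labels = toy
        model = fit_nb(features, labels)
        a = predict(model, features)
        b = predict(model, features[["f3", "f1", "f2"]])
        pd.testing.assert_frame_equal(a, b)

    def test_missing_feature_rejected(self, toy):
        features, labels = toy
        model = fit_nb(features, labels)
        with pytest.raises(ValueError):
            predict(model, features.drop(columns=["f2"]))

    def test_model_json_round_trip(self, toy):
        from gcsubtype.predictor import NaiveBayesModel

        features, labels = toy
        model = fit_nb(features, labels)
        back = NaiveBayesModel.from_json(model.to_json())
        pd.testing.assert_frame_equal(predict(model, features),
                                      predict(back, features))

    def test_absent_class_rejected(self, toy):
        features, labels = toy
        with pytest.raises(ValueError):
            fit_nb(features, labels.drop("S0"))


class TestCrossValidation:
    def test_folds_partition_all_samples(self):
        rng = np.random.default_rng(0)
        features = pd.DataFrame({"f": rng.choice(list("ab"), 40)})
        labels = pd.Series(rng.choice([1, 2], 40))
        out = cross_validate(features, labels, n_folds=5, seed=1)
        assert sum(f["n_test"] for f in out["folds"]) == 40

    def test_perfectly_separable_data_scores_one(self):
        features = pd.DataFrame({"f": ["a"] * 20 + ["b"] * 20})
        labels = pd.Series([1] * 20 + [2] * 20)
        out = cross_validate(features, labels, n_folds=5, seed=0)
        assert out["accuracy"] == 1.0

    def test_shuffled_labels_score_near_majority_rate(self):
        """With uninformative features, CV accuracy tracks the majority-class
        proportion (within 5 points averaged over seeds)."""
        rng = np.random.default_rng(2)
        features = pd.DataFrame({"f": rng.choice(list("abcd"), 60)})
        accs = []
        for seed in range(30):
            labels = pd.Series(np.random.default_rng(seed).permutation(
                [1] * 36 + [2] * 24))
            accs.append(cross_validate(features, labels, n_folds=5,
                                       seed=seed)["accuracy"])
        assert abs(np.mean(accs) - 0.6) < 0.05

    def test_too_many_folds_rejected(self, toy):
        features, labels = toy
        with pytest.raises(ValueError):
            cross_validate(features, labels, n_folds=10)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        features = pd.DataFrame({"f": rng.choice(list("ab"), 30)})
        labels = pd.Series(rng.choice([1, 2], 30))
        a = cross_validate(features, labels, n_folds=5, seed=4)
        b = cross_validate(features, labels, n_folds=5, seed=4)
        assert a == b


class TestFeatureSelection:
    def test_fixed_mode_returns_the_five_panel_features(self):
        features = pd.DataFrame({f: ["a", "b"] * 5 for f in FIXED_FEATURES})
        labels = pd.Series([1, 2] * 5)
        selected, trace = select_features(features, labels, method="fixed")
        assert selected == ["sig_cluster", "cnv_cluster", "FAT4_mut",
                            "LRP1B_mut", "CCNE1_cnv"]
        assert len(trace) == 5

    def test_fixed_mode_missing_feature_rejected(self):
        features = pd.DataFrame({"sig_cluster": ["1", "2"]})
        with pytest.raises(ValueError, match="CCNE1_cnv|absent"):
            select_features(features, pd.Series([1, 2]), method="fixed")

    def test_greedy_picks_label_copy_first(self):
        rng = np.random.default_rng(5)
        labels = pd.Series(rng.choice([1, 2, 3], 60))
        features = pd.DataFrame({
            "noise1": rng.choice(list("ab"), 60),
            "oracle": labels.astype(str),
            "noise2": rng.choice(list("xy"), 60),
        })
        selected, trace = select_features(features, labels, method="greedy",
                                          n_folds=5, seed=0)
        assert selected[0] == "oracle"
        assert trace.loc[0, "cv_accuracy"] == 1.0

    def test_greedy_on_pure_noise_stops_early(self):
        rng = np.random.default_rng(6)
        labels = pd.Series([1] * 36 + [2] * 24)
        features = pd.DataFrame({f"n{i}": rng.choice(list("ab"), 60)
                                 for i in range(4)})
        selected, trace = select_features(features, labels, method="greedy",
                                          n_folds=5, seed=1)
        assert len(selected) <= 2
        assert abs(trace["cv_accuracy"].iloc[-1] - 0.6) < 0.15
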