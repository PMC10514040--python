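"""Feature assembly, Welch-t filter, RUSBoost and the LOO-CV harness."""

import numpy as np
import pandas as pd
import pytest

from plvnet.classify import (
    RUSBoostClassifier,
    assemble_features,
    evaluate_classifiers,
    loo_cv,
    make_classifier,
    metrics_from_confusion,
    rank_features_welch,
)


def make_long_table(n_ls=6, n_hs=4, channels=("A", "B"), bands=("beta",), freqs=(16,), rng=None):
    rng = rng or np.random.default_rng(0)
    rows = []
    for s in range(n_ls + n_hs):
        grp = "LS-like" if s < n_ls else "HS-like"
        sid = f"s{s:02d}"
        for b in bands:
            for f in freqs:
                for c in channels:
                    for metric in ("cc", "strength"):
                        rows.append((sid, grp, b, f, c, metric, rng.uniform()))
                rows.append((sid, grp, b, f, "GLOBAL", "ge", rng.uniform()))
    return pd.DataFrame(
        rows, columns=["subject", "group", "band", "target_frequency", "channel", "metric", "value"]
    )


def separable_features(n_ls=12, n_hs=6, n_feat=5, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_ls + n_hs, n_feat))
    X[n_ls:, 0] += 10.0  # one hugely separating feature
    idx = [f"s{i:02d}" for i in range(n_ls + n_hs)]
    df = pd.DataFrame(X, index=idx, columns=[f"f{j}" for j in range(n_feat)])
    df.attrs["groups"] = pd.Series(
        ["LS-like"] * n_ls + ["HS-like"] * n_hs, index=idx
    )
    return df


class TestAssembleFeatures:
    def test_column_count_matches_design(self):
        long = make_long_table()
        feats = assemble_features(long, ("A", "B"), ("beta",), (16,))
        # 2 metrics x 2 channels x 1 band x 1 freq + 1 ge = 5
        assert feats.shape == (10, 5)

    def test_full_design_column_arithmetic(self):
        channels = tuple(f"ch{i}" for i in range(64))
        # column count formula: 64 channels x 2 metrics x (6 bands x 8 freqs) + 48 ge
        n_cols = 64 * 2 * 6 * 8 + 6 * 8
        assert n_cols == 6192
        bands = tuple(f"b{i}" for i in range(2))
        freqs = (8, 10)
        long = make_long_table(channels=channels, bands=bands, freqs=freqs)
        feats = assemble_features(long, channels, bands, freqs)
        assert feats.shape[1] == 64 * 2 * 2 * 2 + 2 * 2

    def test_missing_cell_raises_with_names(self):
        long = make_long_table()
        long = long[~((long.channel == "B") & (long.metric == "cc"))]
        with pytest.raises(ValueError, match="cc.B"):
            assemble_features(long, ("A", "B"), ("beta",), (16,))


class TestRankFeatures:
    def test_separating_feature_ranks_first(self):
        df = separable_features()
        order = rank_features_welch(df.to_numpy(), df.attrs["groups"].to_numpy())
        assert order[0] == 0

    def test_duplicated_columns_rank_adjacently_in_index_order(self):
        df = separable_features(n_feat=3)
        X = df.to_numpy()
        X = np.column_stack([X, X[:, 0]])  # duplicate the strong feature (index 3)
        order = rank_features_welch(X, df.attrs["groups"].to_numpy())
        assert list(order[:2]) == [0, 3]

    def test_matches_columnwise_welch_oracle(self, rng):
        from plvnet.stats import welch_t

        X = rng.standard_normal((30, 8))
        y = np.array(["a"] * 14 + ["b"] * 16)
        order = rank_features_welch(X, y)
        tvals = [abs(welch_t(X[y == "a", j], X[y == "b", j])[0]) for j in range(8)]
        assert list(order) == list(np.argsort(-np.array(tvals), kind="stable"))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_features_welch(np.zeros((4, 2)), np.array(["x"] * 4))


class TestRUSBoost:
    def test_round_resamples_are_class_balanced(self, monkeypatch, rng):
        X = rng.standard_normal((30, 3))
        y = np.array(["LS-like"] * 22 + ["HS-like"] * 8)
        X[22:] += 3.0
        sizes = []
        from sklearn.tree import DecisionTreeClassifier

        orig = DecisionTreeClassifier.fit

        def spy(self, Xs, ys, **kw):
            vals, counts = np.unique(ys, return_counts=True)
            sizes.append(tuple(counts))
            return orig(self, Xs, ys, **kw)

        monkeypatch.setattr(DecisionTreeClassifier, "fit", spy)
        RUSBoostClassifier(n_rounds=10, random_state=0).fit(X, y)
        assert sizes, "no rounds were fit"
        assert all(c == (8, 8) for c in sizes)

    def test_separable_training_error_zero(self, rng):
        X = rng.standard_normal((30, 2))
        y = np.array(["a"] * 20 + ["b"] * 10)
        X[20:] += 8.0
        clf = RUSBoostClassifier(n_rounds=30, random_state=1).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_matches_plain_adaboost_when_undersampling_disabled(self):
        # balanced noisy data, stumps, learning rate 1: same boosting path
        from sklearn.ensemble import AdaBoostClassifier

        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 4))
        y = np.where(X[:, 0] + 0.8 * rng.standard_normal(40) > 0, 1, 0)
        ours = RUSBoostClassifier(
            n_rounds=12, max_depth=1, learning_rate=1.0, undersample=False, random_state=0
        ).fit(X, y)
        ref = AdaBoostClassifier(n_estimators=12, random_state=0).fit(X, y)
        assert np.array_equal(ours.predict(X), ref.predict(X))

    def test_minority_too_small_rejected(self):
        X = np.zeros((5, 2))
        y = np.array(["a", "a", "a", "a", "b"])
        with pytest.raises(ValueError):
            RUSBoostClassifier().fit(X, y)


class TestLOOCV:
    def test_fold_count_equals_subjects(self):
        df = separable_features(n_ls=29, n_hs=14)
        res = loo_cv(df, classifier="dt", k=3, seed=0)
        assert len(res.predictions) == 43
        assert res.tp + res.fn == 14
        assert res.tn + res.fp == 29

    @pytest.mark.parametrize("name", ["dt", "knn", "lda", "svm", "rusboost"])
    def test_separable_clusters_are_perfect_for_every_classifier(self, name):
        df = separable_features(n_ls=12, n_hs=6)
        res = loo_cv(df, classifier=name, k=3, seed=0)
        assert res.metrics["accuracy"] == 100.0

    def test_no_leakage_held_out_values_cannot_change_fold_ranking(self):
        # corrupting subject 0's features must not change the feature list
        # selected inside fold 0 (whose training set excludes subject 0)
        df = separable_features(n_ls=8, n_hs=5, n_feat=4, seed=2)
        res1 = loo_cv(df, classifier="svm", k=2, seed=0)
        df2 = df.copy()
        df2.attrs["groups"] = df.attrs["groups"]
        df2.iloc[0, :] = 1e6
        res2 = loo_cv(df2, classifier="svm", k=2, seed=0)
        assert res1.selected_features[0] == res2.selected_features[0]
        # whereas the leaky global ranking does see the corrupted row
        leaky = loo_cv(df2, classifier="svm", k=2, seed=0, leaky_global_ranking=True)
        assert leaky.selected_features[0] != res2.selected_features[0]

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            make_classifier("mlp")

    def test_chance_level_with_permuted_labels(self, rng):
        # pure-noise features, majority-heavy labels: accuracy ~ majority rate
        accs = []
        for rep in range(5):
            df = separable_features(n_ls=15, n_hs=7, seed=rep)
            X = df.to_numpy()
            X[:, 0] = rng.standard_normal(len(X))  # remove the separation
            noise = pd.DataFrame(X, index=df.index, columns=df.columns)
            noise.attrs["groups"] = df.attrs["groups"].sample(
                frac=1, random_state=rep
            ).set_axis(df.index)
            res = loo_cv(noise, classifier="dt", k=2, seed=rep)
            accs.append((res.predictions.true == res.predictions.predicted).mean())
        assert 0.2 < np.mean(accs) < 0.85


class TestConfusionMetrics:
    def test_anxiety_like_scenario(self):
        m = metrics_from_confusion(13, 1, 28, 1)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (95.34, 92.85, 96.55)
        assert m["f1"] == pytest.approx(0.92)

    def test_serenity_like_scenario(self):
        m = metrics_from_confusion(12, 2, 25, 4)
        assert (m["accuracy"], m["sensitivity"], m["specificity"]) == (86.04, 85.71, 86.20)

    def test_all_correct(self):
        m = metrics_from_confusion(10, 0, 20, 0)
        assert m["accuracy"] == 100.0 and m["f1"] == 1.0

    def test_f1_proportion_truncation(self):
        # 13/14 = 0.9285... -> 0.92 under truncation
        assert metrics_from_confusion(13, 1, 28, 1)["f1"] == 0.92

    def test_zero_denominator_flagged(self):
        m = metrics_from_confusion(0, 0, 5, 5)
        assert m["undefined"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(-1, 0, 1, 0)


def test_evaluate_classifiers_table_shape():
    df = separable_features(n_ls=10, n_hs=5)
    tab = evaluate_classifiers(df, classifiers=("dt", "svm"), k=2, seed=0)
    assert list(tab.classifier) == ["dt", "svm"]
    assert {"accuracy", "sensitivity", "specificity", "f1"} <= set(tab.columns)
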