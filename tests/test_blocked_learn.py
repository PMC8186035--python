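"""Clade folds, kappa, AUPRC, imputation, and blocked forest training."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from sklearn.metrics import cohen_kappa_score

from microtraits import blocked_learn as bl
from microtraits.blocked_learn import (
    FoldSpec,
    LearnConfig,
    blocked_classify,
    blocked_regress,
    cohens_kappa,
    make_clade_folds,
    mean_impute,
    precision_recall_auc,
)


def _lineage(n, classes, families=None):
    idx = [f"t{i}" for i in range(n)]
    df = pd.DataFrame({"class": [classes[i % len(classes)] for i in range(n)]},
                      index=idx)
    if families is not None:
        df["family"] = [families[i % len(families)] for i in range(n)]
    return df


class TestMakeCladeFolds:
    def test_one_fold_per_label(self):
        lab = _lineage(12, ["a", "b", "c", "d"])
        folds = make_clade_folds(list(lab.index), lab, "class")
        assert folds.n_folds == 4 and folds.level == "class"
        assert sorted(folds.units()) == sorted(lab.index)

    def test_single_class_falls_back_to_families(self):
        lab = _lineage(8, ["only"], families=["f1", "f2"])
        folds = make_clade_folds(list(lab.index), lab, "class")
        assert folds.level == "family" and folds.n_folds == 2

    def test_all_distinct_labels_is_leave_one_out(self):
        lab = _lineage(5, [f"c{i}" for i in range(5)])
        folds = make_clade_folds(list(lab.index), lab, "class")
        assert folds.n_folds == 5

    def test_no_splittable_level_errors(self):
        lab = _lineage(6, ["only"], families=["f"])
        with pytest.raises(ValueError):
            make_clade_folds(list(lab.index), lab, "class")

    def test_overlapping_folds_rejected(self):
        with pytest.raises(ValueError):
            FoldSpec({"a": ("t1", "t2"), "b": ("t2",)}, "class")


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([0, 1, 0, 1], [0, 1, 0, 1]) == 1.0

    def test_prevalence_only_null_scores_zero(self):
        obs = [1] * 90 + [0] * 10
        assert cohens_kappa(obs, [1] * 100) == pytest.approx(0.0)

    def test_confusion_fixture_kappa_point_six(self):
        # TP=45 FN=5 FP=15 TN=35: p_o=0.8, p_e=0.5
        obs = [1] * 50 + [0] * 50
        pred = [1] * 45 + [0] * 5 + [1] * 15 + [0] * 35
        assert cohens_kappa(obs, pred) == pytest.approx(0.6)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cohens_kappa([1, 0], [1])

    def test_degenerate_single_class(self):
        assert cohens_kappa([1, 1, 1], [1, 1, 1]) == 0.0

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)),
                    min_size=2, max_size=60))
    def test_matches_sklearn_and_bounds(self, pairs):
        obs = [a for a, _ in pairs]
        pred = [b for _, b in pairs]
        k = cohens_kappa(obs, pred)
        assert -1.0 - 1e-9 <= k <= 1.0 + 1e-9
        ref = cohen_kappa_score(obs, pred)
        if not np.isnan(ref):
            assert k == pytest.approx(ref, abs=1e-12)


class TestPrecisionRecallAUC:
    def test_perfect_separation(self):
        assert precision_recall_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = [1, 0, 0, 0, 1]
        assert precision_recall_auc(y, [0.5] * 5) == pytest.approx(0.4)

    def test_hand_example_matches_threshold_enumeration(self):
        y = np.array([1, 0, 1, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.1])
        # brute-force: sweep unique thresholds descending, step-sum the curve
        order = np.argsort(-s)
        y_sorted = y[order]
        auc = 0.0
        prev_recall = 0.0
        n_pos = y.sum()
        for k in range(1, len(y) + 1):
            precision = y_sorted[:k].mean()
            recall = y_sorted[:k].sum() / n_pos
            auc += (recall - prev_recall) * precision
            prev_recall = recall
        assert precision_recall_auc(y, s) == pytest.approx(auc)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            precision_recall_auc([1, 1, 1], [0.2, 0.5, 0.9])


class TestMeanImpute:
    def test_column_mean_fill(self):
        df = pd.DataFrame({"a": [1.0, np.nan, 3.0], "b": [1.0, 1.0, 1.0]})
        out = mean_impute(df)
        assert out.loc[1, "a"] == pytest.approx(2.0)

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        pd.testing.assert_frame_equal(mean_impute(df), df)

    def test_all_missing_column_dropped(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "bad": [np.nan, np.nan]})
        assert "bad" not in mean_impute(df).columns

    def test_random_mask_matches_recomputed_means(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        mask = rng.random(df.shape) < 0.25
        masked = df.mask(mask)
        out = mean_impute(masked)
        for col in df.columns:
            expected = masked[col].mean()
            got = out[col][masked[col].isna()]
            assert np.allclose(got, expected)


def _clade_world(seed, n=96, n_clades=4, signal="feature"):
    """Units with clade-structured features; label source configurable."""
    rng = np.random.default_rng(seed)
    idx = [f"t{i}" for i in range(n)]
    clades = np.array([f"c{i % n_clades}" for i in range(n)])
    clade_means = rng.normal(scale=2.0, size=(n_clades, 6))
    X = pd.DataFrame(
        clade_means[[int(c[1]) for c in clades]] + rng.normal(size=(n, 6)),
        index=idx, columns=[f"f{j}" for j in range(6)],
    )
    if signal == "feature":
        y = pd.Series((X["f0"] > X["f0"].median()).astype(int), index=idx)
    elif signal == "clade":
        clade_p = rng.uniform(0.1, 0.9, size=n_clades)
        y = pd.Series(
            (rng.random(n) < clade_p[[int(c[1]) for c in clades]]).astype(int),
            index=idx,
        )
    else:  # pure noise
        y = pd.Series(rng.integers(0, 2, size=n), index=idx)
    lineage = pd.DataFrame({"class": clades}, index=idx)
    return X, y, lineage


class TestBlockedClassify:
    def test_planted_separable_signal_perfect_kappa(self):
        rng = np.random.default_rng(1)
        idx = [f"t{i}" for i in range(80)]
        X = pd.DataFrame(rng.normal(size=(80, 4)), index=idx,
                         columns=list("abcd"))
        y = pd.Series(rng.integers(0, 2, size=80), index=idx)
        X["a"] = y.astype(float)  # one feature deterministically equals the label
        lineage = pd.DataFrame({"class": [f"c{i % 4}" for i in range(80)]},
                               index=idx)
        folds = make_clade_folds(idx, lineage, "class")
        _, m, imp = blocked_classify(
            X, y, folds, LearnConfig(n_trees=200, seed=0, importance_repeats=1)
        )
        assert (m.per_fold["kappa"] == 1.0).all()
        assert imp["mean"].idxmax() == "a"

    def test_randomized_labels_mean_kappa_near_zero(self):
        kappas = []
        for seed in range(20):
            X, y, lineage = _clade_world(seed, signal="noise")
            folds = make_clade_folds(list(X.index), lineage, "class")
            _, m, _ = blocked_classify(
                X, y, folds,
                LearnConfig(n_trees=60, seed=seed, compute_importance=False),
            )
            kappas.append(m.mean_kappa)
        assert abs(np.mean(kappas)) < 0.05

    def test_each_unit_predicted_exactly_once(self):
        X, y, lineage = _clade_world(3)
        folds = make_clade_folds(list(X.index), lineage, "class")
        preds, _, _ = blocked_classify(
            X, y, folds, LearnConfig(n_trees=50, seed=0,
                                     compute_importance=False)
        )
        assert sorted(preds["unit"]) == sorted(X.index)
        assert folds.n_folds == 4 and preds["fold"].nunique() == 4

    def test_no_unit_in_both_partitions(self):
        X, y, lineage = _clade_world(4)
        folds = make_clade_folds(list(X.index), lineage, "class")
        for fold_id, members in folds.folds.items():
            train = {u for f, mem in folds.folds.items() if f != fold_id
                     for u in mem}
            assert not train & set(members)

    def test_single_class_training_fold_skipped(self):
        X, _, lineage = _clade_world(5, n=30, n_clades=3)
        y = pd.Series(
            [1 if lineage.loc[t, "class"] == "c0" else 0 for t in X.index],
            index=X.index,
        )
        # held-out c0 leaves a training partition with only class 0
        _, m, _ = blocked_classify(
            X, y, folds=make_clade_folds(list(X.index), lineage, "class"),
            config=LearnConfig(n_trees=30, seed=0, compute_importance=False),
        )
        assert "c0" in m.skipped_folds

    def test_blocked_kappa_below_random_split_kappa(self):
        """On clade-confounded data, random folds leak clade identity and
        inflate apparent performance; clade blocking removes the optimism."""
        blocked, naive = [], []
        rng = np.random.default_rng(99)
        for seed in range(20):
            X, y, lineage = _clade_world(seed, signal="clade")
            folds = make_clade_folds(list(X.index), lineage, "class")
            _, mb, _ = blocked_classify(
                X, y, folds,
                LearnConfig(n_trees=60, seed=seed, compute_importance=False),
            )
            shuffled = rng.permutation(len(X))
            random_folds = FoldSpec(
                {f"r{k}": tuple(X.index[shuffled[k::4]]) for k in range(4)},
                "random",
            )
            _, mn, _ = blocked_classify(
                X, y, random_folds,
                LearnConfig(n_trees=60, seed=seed, compute_importance=False),
            )
            blocked.append(mb.mean_kappa)
            naive.append(mn.mean_kappa)
        assert np.mean(naive) > np.mean(blocked)


class TestBlockedRegress:
    def test_separable_regression(self):
        rng = np.random.default_rng(0)
        idx = [f"t{i}" for i in range(80)]
        X = pd.DataFrame(rng.normal(size=(80, 3)), index=idx,
                         columns=list("abc"))
        y = X["a"] * 3
        lineage = pd.DataFrame({"class": [f"c{i % 4}" for i in range(80)]},
                               index=idx)
        folds = make_clade_folds(idx, lineage, "class")
        _, m, _ = blocked_regress(
            X, y, folds, LearnConfig(n_trees=200, seed=0,
                                     compute_importance=False)
        )
        assert m.mean_rho > 0.95
        assert m.mean_rmse < y.std()

    def test_noise_response_rho_near_zero(self):
        rhos = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            idx = [f"t{i}" for i in range(60)]
            X = pd.DataFrame(rng.normal(size=(60, 3)), index=idx,
                             columns=list("abc"))
            y = pd.Series(rng.normal(size=60), index=idx)
            lineage = pd.DataFrame(
                {"class": [f"c{i % 3}" for i in range(60)]}, index=idx
            )
            folds = make_clade_folds(idx, lineage, "class")
            _, m, _ = blocked_regress(
                X, y, folds, LearnConfig(n_trees=60, seed=seed,
                                         compute_importance=False)
            )
            rhos.append(m.mean_rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_rmse_closed_form(self):
        # RMSE((1,2,3) vs (1,2,5)) = sqrt(4/3)
        pred = np.array([1.0, 2.0, 5.0])
        obs = np.array([1.0, 2.0, 3.0])
        assert np.sqrt(np.mean((pred - obs) ** 2)) == pytest.approx(
            np.sqrt(4 / 3)
        )
        # and the per-fold metric agrees on a constructed fold
        idx = ["a", "b", "c", "d", "e", "f"]
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]}, index=idx)
        y = pd.Series([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], index=idx)
        folds = FoldSpec({"f1": ("a", "b", "c"), "f2": ("d", "e", "f")}, "class")
        _, m, _ = blocked_regress(
            X, y, folds, LearnConfig(n_trees=100, seed=0,
                                     compute_importance=False)
        )
        assert (m.per_fold["rmse"] >= 0).all()
        assert (m.per_fold["adj_r2"] <= m.per_fold["rho"] ** 2 + 1e-9).all()
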