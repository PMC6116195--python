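"""Balanced splits, the bagged forest, OOB permutation importance."""

import numpy as np
import pandas as pd
import pytest

from jimrad import (
    BaggedForest,
    CohortTable,
    SplitSpec,
    balanced_split,
    oob_permutation_importance,
    run_all_tasks,
    train_eval_rf,
)
from jimrad.classify import default_feature_subsets

from conftest import make_feature_cohort


SMALL_SPEC = SplitSpec(n_train_pos=10, n_train_neg=10, n_test_pos=5, n_test_neg=5)


class TestBalancedSplit:
    def test_default_sizes_and_disjointness(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(30, 39, 30), n_features=5)
        train, test = balanced_split(cohort, "G1", SplitSpec(), seed=3)
        assert train.n_cases == 40 and test.n_cases == 20
        assert (train.groups == "G1").sum() == 20
        assert (test.groups == "G1").sum() == 10
        assert len(set(train.features.index) & set(test.features.index)) == 0

    def test_same_seed_reproduces_split(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(30, 39, 30), n_features=3)
        a = balanced_split(cohort, "G2", seed=7)
        b = balanced_split(cohort, "G2", seed=7)
        assert list(a[0].features.index) == list(b[0].features.index)
        assert list(a[1].features.index) == list(b[1].features.index)

    def test_insufficient_cases_names_the_class(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(25, 39, 30), n_features=3)
        with pytest.raises(ValueError, match="G1"):
            balanced_split(cohort, "G1", SplitSpec(), seed=0)


class TestForest:
    def test_separable_feature_gives_high_auc(self, rng):
        aucs = []
        for seed in range(5):
            trng = np.random.default_rng(100 + seed)
            cohort = make_feature_cohort(
                trng, n_per_group=(20, 20, 20), n_features=10, planted={0: 2.5}
            )
            train, test = balanced_split(cohort, "G1", SMALL_SPEC, seed=seed)
            res = train_eval_rf(
                train, test, "G1", n_trees=100, seed=seed, with_importance=False
            )
            aucs.append(res.auc)
        assert np.mean(aucs) >= 0.85

    def test_duplicated_test_set_leaves_auc_unchanged(self, rng):
        cohort = make_feature_cohort(
            rng, n_per_group=(20, 20, 20), n_features=8, planted={0: 2.0}
        )
        train, test = balanced_split(cohort, "G1", SMALL_SPEC, seed=1)
        res = train_eval_rf(
            train, test, "G1", n_trees=60, seed=5, with_importance=False
        )
        doubled = CohortTable(
            features=pd.concat(
                [test.features, test.features.set_index(test.features.index + "_b")]
            ),
            groups=pd.concat(
                [test.groups, test.groups.set_axis(test.groups.index + "_b")]
            ),
        )
        res2 = train_eval_rf(
            train, doubled, "G1", n_trees=60, seed=5, with_importance=False
        )
        assert res.auc == pytest.approx(res2.auc)

    def test_anti_ranked_scores_flip_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        cohort = make_feature_cohort(
            rng, n_per_group=(20, 20, 20), n_features=6, planted={0: 2.0}
        )
        train, test = balanced_split(cohort, "G1", SMALL_SPEC, seed=2)
        forest = BaggedForest(n_trees=50, seed=0).fit(
            train.features.to_numpy(), (train.groups == "G1").astype(int)
        )
        y = (test.groups == "G1").astype(int)
        scores = forest.decision_scores(test.features.to_numpy())
        assert roc_auc_score(y, -scores) == pytest.approx(
            1 - roc_auc_score(y, scores)
        )

    def test_single_class_training_set_rejected(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(6, 6, 6), n_features=3)
        sub = CohortTable(
            features=cohort.features[cohort.groups == "G1"],
            groups=cohort.groups[cohort.groups == "G1"],
        )
        other = CohortTable(
            features=cohort.features[cohort.groups != "G1"],
            groups=cohort.groups[cohort.groups != "G1"],
        )
        with pytest.raises(ValueError, match="single class"):
            train_eval_rf(sub, other, "G1", n_trees=10, seed=0)

    def test_determinism_given_seed(self, rng):
        cohort = make_feature_cohort(
            rng, n_per_group=(20, 20, 20), n_features=6, planted={1: 1.5}
        )
        train, test = balanced_split(cohort, "G1", SMALL_SPEC, seed=4)
        a = train_eval_rf(train, test, "G1", n_trees=40, seed=9)
        b = train_eval_rf(train, test, "G1", n_trees=40, seed=9)
        assert a.auc == b.auc
        pd.testing.assert_series_equal(a.importance, b.importance)

    def test_agrees_with_stock_random_forest_on_separable_data(self, rng):
        # independent cross-check of the bagging layer: scikit-learn's own
        # forest should score the same easy task comparably
        from sklearn.ensemble import RandomForestClassifier
        from sklearn.metrics import roc_auc_score

        cohort = make_feature_cohort(
            rng, n_per_group=(25, 25, 25), n_features=10, planted={0: 2.5}
        )
        train, test = balanced_split(cohort, "G1", SMALL_SPEC, seed=0)
        y_train = (train.groups == "G1").astype(int)
        y_test = (test.groups == "G1").astype(int)
        ours = train_eval_rf(
            train, test, "G1", n_trees=200, seed=0, with_importance=False
        ).auc
        ref = RandomForestClassifier(n_estimators=200, random_state=0).fit(
            train.features, y_train
        )
        ref_auc = roc_auc_score(y_test, ref.predict_proba(test.features)[:, 1])
        assert abs(ours - ref_auc) < 0.15


class TestImportance:
    def test_planted_feature_ranks_first_and_positive(self, rng):
        hits = 0
        for seed in range(8):
            trng = np.random.default_rng(200 + seed)
            cohort = make_feature_cohort(
                trng, n_per_group=(20, 20, 20), n_features=10, planted={2: 2.5}
            )
            train, _ = balanced_split(cohort, "G1", SMALL_SPEC, seed=seed)
            forest = BaggedForest(n_trees=150, seed=seed).fit(
                train.features.to_numpy(), (train.groups == "G1").astype(int)
            )
            imp = oob_permutation_importance(forest, train, "G1")
            if imp.idxmax() == "f02" and imp["f02"] > 0:
                hits += 1
        assert hits >= 7

    def test_constant_feature_has_zero_importance(self, rng):
        cohort = make_feature_cohort(
            rng, n_per_group=(15, 15, 15), n_features=5, planted={0: 2.0}
        )
        feats = cohort.features.copy()
        feats["f04"] = 1.0  # constant column: permutation changes nothing
        cohort = CohortTable(features=feats, groups=cohort.groups)
        train, _ = balanced_split(cohort, "G1", SMALL_SPEC, seed=0)
        forest = BaggedForest(n_trees=80, seed=0).fit(
            train.features.to_numpy(), (train.groups == "G1").astype(int)
        )
        imp = oob_permutation_importance(forest, train, "G1")
        assert imp["f04"] == 0.0

    def test_unfitted_forest_rejected(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(5, 5, 5), n_features=3)
        with pytest.raises(ValueError, match="OOB"):
            oob_permutation_importance(BaggedForest(n_trees=5), cohort, "G1")


class TestRunAllTasks:
    def test_bookkeeping_three_tasks_by_subsets(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(16, 16, 16), n_features=6)
        subsets = {"a": ["f00", "f01"], "b": ["f02", "f03", "f04"]}
        out = run_all_tasks(
            cohort, subsets, spec=SMALL_SPEC, n_trees=20, n_reps=2, seed=0
        )
        assert len(out) == 6  # 3 tasks x 2 subsets
        assert set(out["target"]) == {"G1", "G2", "G3"}

    def test_signal_subset_beats_noise_subset(self):
        aucs = {"signal": [], "noise": []}
        for seed in range(4):
            trng = np.random.default_rng(400 + seed)
            cohort = make_feature_cohort(
                trng, n_per_group=(20, 20, 20), n_features=8,
                planted={0: 2.5, 1: 2.0},
            )
            out = run_all_tasks(
                cohort,
                {"signal": ["f00", "f01"], "noise": ["f05", "f06", "f07"]},
                spec=SMALL_SPEC,
                n_trees=60,
                n_reps=2,
                seed=seed,
            )
            g1 = out[out["target"] == "G1"].set_index("subset")["auc_mean"]
            aucs["signal"].append(g1["signal"])
            aucs["noise"].append(g1["noise"])
        assert np.mean(aucs["signal"]) > np.mean(aucs["noise"])

    def test_single_rep_fixed_seed_reproducible(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(16, 16, 16), n_features=5)
        kwargs = dict(spec=SMALL_SPEC, n_trees=25, n_reps=1, seed=11)
        a = run_all_tasks(cohort, {"all": list(cohort.features.columns)}, **kwargs)
        b = run_all_tasks(cohort, {"all": list(cohort.features.columns)}, **kwargs)
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_subset_feature_rejected(self, rng):
        cohort = make_feature_cohort(rng, n_per_group=(16, 16, 16), n_features=4)
        with pytest.raises(ValueError, match="unknown"):
            run_all_tasks(cohort, {"bad": ["nope"]}, spec=SMALL_SPEC, n_reps=1)

    def test_default_subsets_from_signature_columns(self):
        cols = (
            [f"GLCM_T2_f{i}" for i in range(3)]
            + [f"GLCM_ADC_f{i}" for i in range(3)]
            + [f"JIM_f{i}" for i in range(3)]
            + ["HIST_T2_mean", "HIST_ADC_mean"]
        )
        subsets = default_feature_subsets(cols)
        assert set(subsets) == {"GLCM_T2", "GLCM_ADC", "JIM", "combined", "standard"}
        assert len(subsets["combined"]) == 9
        assert len(subsets["standard"]) == 2
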