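"""Balanced one-vs-all random-forest prediction of Gleason groupings.

Each grouping (G1, G2, G3) is treated as a binary task against the pooled
remainder. Splits are class-balanced: by default 20 positives + 20 negatives
for training and 10 + 10 held out for testing, drawn without replacement
from the cohort. A 500-tree forest of CART trees (sqrt(p) features per
split, unlimited depth, bootstrap samples of the training size) is fit on
the training set and scored by the ROC AUC of its test-set class
probabilities.

Feature importance follows the out-of-bag permutation scheme: for every
tree, the increase in misclassification error on that tree's out-of-bag
cases after permuting one feature's values, averaged over the ensemble and
normalized by the ensemble standard deviation of the per-tree increases.
Positive scores mark predictive features; scores near or below zero mark
uninformative ones.

The bagging loop is explicit (rather than delegated to a stock forest
class) so that per-tree bootstrap and out-of-bag index sets are first-class
objects: the same ensemble produces both the AUC and the importance scores,
and every number is a deterministic function of (cohort, spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from .stats import CohortTable, GROUP_ORDER

__all__ = [
    "SplitSpec",
    "ClassifierResult",
    "BaggedForest",
    "balanced_split",
    "train_eval_rf",
    "oob_permutation_importance",
    "run_all_tasks",
    "default_feature_subsets",
]


@dataclass(frozen=True)
class SplitSpec:
    """Balanced train/test sizes for one one-vs-all task."""

    n_train_pos: int = 20
    n_train_neg: int = 20
    n_test_pos: int = 10
    n_test_neg: int = 10

    def __post_init__(self) -> None:
        if min(
            self.n_train_pos, self.n_train_neg, self.n_test_pos, self.n_test_neg
        ) < 1:
            raise ValueError("all split counts must be >= 1")


@dataclass(frozen=True)
class ClassifierResult:
    """Outcome of one trained task: test AUC and per-feature importance."""

    target: str
    auc: float
    importance: pd.Series  # index = feature names; NaN if not computed
    n_trees: int
    seed: int


class BaggedForest:
    """Bootstrap-aggregated CART trees with recorded out-of-bag sets.

    Trees come from scikit-learn (``max_features='sqrt'``, unlimited depth);
    bootstrap indices are drawn here with a seeded generator so out-of-bag
    masks are available for permutation importance. Class-probability
    predictions average the per-tree leaf class frequencies.
    """

    def __init__(self, n_trees: int = 500, seed: int = 0, max_features="sqrt"):
        if n_trees < 1:
            raise ValueError(f"n_trees must be >= 1, got {n_trees}")
        self.n_trees = n_trees
        self.seed = seed
        self.max_features = max_features
        self.trees_: list[DecisionTreeClassifier] = []
        self.bootstrap_idx_: list[np.ndarray] = []
        self.oob_masks_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaggedForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training set must contain both classes")
        self.classes_ = classes
        n = len(y)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.bootstrap_idx_, self.oob_masks_ = [], [], []
        for t in range(self.n_trees):
            idx = rng.integers(0, n, size=n)
            oob = np.ones(n, dtype=bool)
            oob[idx] = False
            tree = DecisionTreeClassifier(
                max_features=self.max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.bootstrap_idx_.append(idx)
            self.oob_masks_.append(oob)
        return self

    def _tree_proba(self, tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
        """Per-tree P(positive class), aligned to self.classes_."""
        proba = tree.predict_proba(X)
        out = np.zeros((len(X), len(self.classes_)))
        for k, c in enumerate(tree.classes_):
            out[:, np.searchsorted(self.classes_, c)] = proba[:, k]
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not self.trees_:
            raise ValueError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        acc = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees_:
            acc += self._tree_proba(tree, X)
        return acc / self.n_trees

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """P(class == classes_[-1]), the ROC score for the positive class."""
        return self.predict_proba(X)[:, -1]


def balanced_split(
    cohort: CohortTable, target: str, spec: SplitSpec = SplitSpec(), seed: int = 0
) -> tuple[CohortTable, CohortTable]:
    """Draw disjoint balanced train/test case sets for a one-vs-all task.

    Positives are the target group; negatives pool the other two groups.
    Sampling is uniform without replacement, deterministic given ``seed``.
    """
    if target not in GROUP_ORDER:
        raise ValueError(f"unknown target group {target!r}")
    rng = np.random.default_rng(seed)
    is_pos = (cohort.groups == target).to_numpy()
    pos_ids = cohort.features.index[is_pos].to_numpy()
    neg_ids = cohort.features.index[~is_pos].to_numpy()
    need_pos = spec.n_train_pos + spec.n_test_pos
    need_neg = spec.n_train_neg + spec.n_test_neg
    if len(pos_ids) < need_pos:
        raise ValueError(
            f"group {target} has {len(pos_ids)} cases, needs {need_pos}"
        )
    if len(neg_ids) < need_neg:
        raise ValueError(
            f"pooled non-{target} classes have {len(neg_ids)} cases, need {need_neg}"
        )
    pos = rng.permutation(pos_ids)
    neg = rng.permutation(neg_ids)
    train_ids = np.concatenate([pos[: spec.n_train_pos], neg[: spec.n_train_neg]])
    test_ids = np.concatenate(
        [
            pos[spec.n_train_pos : need_pos],
            neg[spec.n_train_neg : need_neg],
        ]
    )

    def subset(ids):
        return CohortTable(
            features=cohort.features.loc[ids], groups=cohort.groups.loc[ids]
        )

    return subset(train_ids), subset(test_ids)


def _binary_labels(groups: pd.Series, target: str) -> np.ndarray:
    return (groups == target).astype(int).to_numpy()


def train_eval_rf(
    train: CohortTable,
    test: CohortTable,
    target: str,
    n_trees: int = 500,
    seed: int = 0,
    with_importance: bool = True,
) -> ClassifierResult:
    """Fit a forest on the training set and report held-out ROC AUC.

    Class labels are 1 for the target group and 0 for the rest; the AUC uses
    the forest's positive-class probability as the score.
    """
    overlap = train.features.index.intersection(test.features.index)
    if len(overlap) > 0:
        raise ValueError(f"train and test sets overlap: {list(overlap[:5])}")
    y_train = _binary_labels(train.groups, target)
    y_test = _binary_labels(test.groups, target)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set has a single class")
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set has a single class")
    forest = BaggedForest(n_trees=n_trees, seed=seed).fit(
        train.features.to_numpy(), y_train
    )
    auc = float(roc_auc_score(y_test, forest.decision_scores(test.features.to_numpy())))
    if with_importance:
        imp = oob_permutation_importance(forest, train, target)
    else:
        imp = pd.Series(np.nan, index=train.features.columns)
    return ClassifierResult(
        target=target, auc=auc, importance=imp, n_trees=n_trees, seed=seed
    )


def oob_permutation_importance(
    forest: BaggedForest, train: CohortTable, target: str
) -> pd.Series:
    """Normalized out-of-bag permutation importance per feature.

    For tree t and feature f: error increase
    ``e_tf = err(OOB_t with f permuted) - err(OOB_t)`` under 0/1
    misclassification at the 0.5 probability threshold. The score is
    ``mean_t(e_tf) / sd_t(e_tf)`` (zero-variance features score 0). All
    permutations for one tree are evaluated in a single batched predict.
    """
    if not forest.trees_:
        raise ValueError("forest has no fitted trees (no OOB records)")
    X = train.features.to_numpy(dtype=float)
    y = _binary_labels(train.groups, target)
    n_feat = X.shape[1]
    rng = np.random.default_rng(forest.seed + 1)
    increases = np.zeros((forest.n_trees, n_feat))
    for t, (tree, oob) in enumerate(zip(forest.trees_, forest.oob_masks_)):
        if not oob.any():
            continue
        X_oob, y_oob = X[oob], np.asarray(y)[oob]
        n_oob = len(y_oob)
        base_err = np.mean(tree.predict(X_oob) != y_oob)
        # one batched predict: n_feat stacked copies, each with one column shuffled
        stacked = np.tile(X_oob, (n_feat, 1))
        for f in range(n_feat):
            block = slice(f * n_oob, (f + 1) * n_oob)
            stacked[block, f] = X_oob[rng.permutation(n_oob), f]
        pred = tree.predict(stacked)
        perm_err = (pred != np.tile(y_oob, n_feat)).reshape(n_feat, n_oob).mean(axis=1)
        increases[t] = perm_err - base_err
    mean = increases.mean(axis=0)
    sd = increases.std(axis=0, ddof=0)
    score = np.divide(mean, sd, out=np.zeros_like(mean), where=sd > 0)
    return pd.Series(score, index=train.features.columns)


def default_feature_subsets(feature_names) -> dict[str, list[str]]:
    """The five signature subsets: per-matrix blocks, the combined 57, and
    the 12 first-order histogram features (when present)."""
    names = list(feature_names)
    subsets = {
        "GLCM_T2": [n for n in names if n.startswith("GLCM_T2_")],
        "GLCM_ADC": [n for n in names if n.startswith("GLCM_ADC_")],
        "JIM": [n for n in names if n.startswith("JIM_")],
    }
    subsets["combined"] = subsets["GLCM_T2"] + subsets["GLCM_ADC"] + subsets["JIM"]
    hist = [n for n in names if n.startswith("HIST_")]
    if hist:
        subsets["standard"] = hist
    return {k: v for k, v in subsets.items() if v}


def run_all_tasks(
    cohort: CohortTable,
    feature_subsets: dict[str, list[str]] | None = None,
    spec: SplitSpec = SplitSpec(),
    n_trees: int = 500,
    n_reps: int = 25,
    seed: int = 0,
    with_importance: bool = False,
) -> pd.DataFrame:
    """Mean +/- SD test AUC over repeated balanced splits, for every
    one-vs-all task and feature subset.

    Returns a tidy frame with one row per (target, subset): columns
    ``auc_mean``, ``auc_sd``, ``n_reps``. ``n_reps=1`` reproduces the
    single-split protocol exactly.
    """
    if feature_subsets is None:
        feature_subsets = default_feature_subsets(cohort.features.columns)
    unknown = {
        f for cols in feature_subsets.values() for f in cols
    } - set(cohort.features.columns)
    if unknown:
        raise ValueError(f"unknown features in subsets: {sorted(unknown)[:5]}")
    rows = []
    for task_idx, target in enumerate(GROUP_ORDER):
        for rep in range(n_reps):
            split_seed = seed + 1000 * rep + 101 * task_idx
            train, test = balanced_split(cohort, target, spec, seed=split_seed)
            for sub_name, cols in feature_subsets.items():
                sub_train = CohortTable(train.features[cols], train.groups)
                sub_test = CohortTable(test.features[cols], test.groups)
                res = train_eval_rf(
                    sub_train,
                    sub_test,
                    target,
                    n_trees=n_trees,
                    seed=split_seed + 1,
                    with_importance=with_importance and rep == 0,
                )
                rows.append((target, sub_name, rep, res.auc))
    frame = pd.DataFrame(rows, columns=["target", "subset", "rep", "auc"])
    out = (
        frame.groupby(["target", "subset"], sort=False)["auc"]
        .agg(auc_mean="mean", auc_sd="std")
        .reset_index()
    )
    out["auc_sd"] = out["auc_sd"].fillna(0.0)
    out["n_reps"] = n_reps
    return out
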