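"""Univariate screening of texture features against Gleason groupings.

Per feature: a Kruskal-Wallis test across the G1/G2/G3 groups, a Spearman
rank correlation against the ordinal group coding (G1=1 < G2=2 < G3=3), and
family-wise Holm-Bonferroni correction of the Kruskal-Wallis p-values over
all features in the submitted table (m = 57 for the texture signature).
A two-sided Wilcoxon rank-sum test is provided for pairwise comparisons of
first-order histogram features.

Ties are handled with mid-ranks throughout; p-values use the conventional
chi-square / t / normal approximations appropriate at cohort sizes near 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GROUP_ORDER",
    "CohortTable",
    "UnivariateResult",
    "kruskal_wallis",
    "holm_bonferroni",
    "spearman",
    "wilcoxon_ranksum",
    "univariate_screen",
]

GROUP_ORDER = ("G1", "G2", "G3")
_GROUP_RANK = {g: r for r, g in enumerate(GROUP_ORDER, start=1)}


@dataclass(frozen=True)
class CohortTable:
    """Feature matrix (cases x features) with one group label per case."""

    features: pd.DataFrame  # index = case_id, columns = feature names
    groups: pd.Series  # index = case_id, values in GROUP_ORDER

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.groups.index):
            raise ValueError("features and groups must share the same case index")
        if self.features.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        bad = set(self.groups.unique()) - set(GROUP_ORDER)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_cases(self) -> int:
        return len(self.features)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, group_col: str = "gleason_group"):
        """Split a flat table (as written by the extraction step) into
        features and labels."""
        if group_col not in frame.columns:
            raise ValueError(f"table has no '{group_col}' column")
        return cls(
            features=frame.drop(columns=[group_col]).astype(float),
            groups=frame[group_col],
        )

    def to_frame(self, group_col: str = "gleason_group") -> pd.DataFrame:
        out = self.features.copy()
        out[group_col] = self.groups
        return out


@dataclass(frozen=True)
class UnivariateResult:
    """Per-feature screening results plus the correction family size m."""

    table: pd.DataFrame  # index = feature; kw_H, kw_p, holm_significant, ...
    m: int
    alpha: float

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["holm_significant"]])


def kruskal_wallis(values, groups) -> tuple[float, float]:
    """Kruskal-Wallis H (mid-ranks, tie-corrected) and its chi-square p-value.

    Identical group value-sets give H = 0, p = 1 rather than scipy's
    all-ties error.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups, got {len(labels)}")
    samples = [values[groups == g] for g in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group needs at least one observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*samples)
    return float(h), float(p)


def holm_bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """Holm's step-down significance flags, in input order.

    Sort ascending; reject hypothesis (k) while p_(k) <= alpha / (m - k + 1)
    and stop at the first failure.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.ndim != 1 or pvals.size == 0:
        raise ValueError("pvals must be a non-empty 1D sequence")
    if np.any((pvals < 0) | (pvals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    flags = np.zeros(m, dtype=bool)
    for k, idx in enumerate(order):  # k = 0 .. m-1
        if pvals[idx] <= alpha / (m - k):
            flags[idx] = True
        else:
            break
    return flags


def spearman(values, groups) -> tuple[float, float]:
    """Spearman rho between a feature and the ordinal group coding.

    Group labels map to ranks G1=1, G2=2, G3=3; rho is the mid-rank Pearson
    correlation with the t-approximation p-value. A constant feature is
    degenerate: (0.0, 1.0) is returned instead of NaN.
    """
    values = np.asarray(values, dtype=float)
    ordinals = np.array([_GROUP_RANK.get(g, g) for g in np.asarray(groups)], dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 cases")
    if np.all(values == values[0]) or np.all(ordinals == ordinals[0]):
        return 0.0, 1.0
    rho, p = sps.spearmanr(values, ordinals)
    return float(rho), float(p)


def wilcoxon_ranksum(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum with normal approximation and tie
    correction. Returns (rank-sum of the first sample, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    w = float(res.statistic + a.size * (a.size + 1) / 2)  # U -> rank sum of a
    return w, float(res.pvalue)


def univariate_screen(cohort: CohortTable, alpha: float = 0.05) -> UnivariateResult:
    """Kruskal-Wallis + Holm + Spearman for every feature of a cohort table.

    The Holm family is the full set of features in the table (m = 57 for the
    default texture signature); m is reported alongside the flags.
    """
    groups = cohort.groups.to_numpy()
    rows = []
    for name in cohort.features.columns:
        v = cohort.features[name].to_numpy()
        h, p = kruskal_wallis(v, groups)
        rho, rho_p = spearman(v, groups)
        rows.append((name, h, p, rho, rho_p))
    table = pd.DataFrame(
        rows, columns=["feature", "kw_H", "kw_p", "spearman_rho", "spearman_p"]
    ).set_index("feature")
    table.insert(2, "holm_significant", holm_bonferroni(table["kw_p"], alpha))
    return UnivariateResult(table=table, m=len(table), alpha=alpha)
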