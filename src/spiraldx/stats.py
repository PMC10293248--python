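"""Univariate feature statistics: Spearman correlations, Mann-Whitney-U group
comparisons, Bonferroni correction and significance annotation.

The three diagnostic tasks are binary contrasts over the cohort groups:
Task1 = PD vs CG, Task2 = (PD ∪ DD) vs CG, Task3 = PD vs DD.  For Spearman
correlations the task label is encoded 0/1 with the disease (positive) group
as 1, so a positive rho means the feature rises with disease.  All tests are
two-sided; with 14 features the Bonferroni-corrected level is
0.05/14 ≈ 0.0036.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DomainError, ValidationError
from .features import FEATURE_NAMES

DEFAULT_ALPHA = 0.05
N_CORRECTED_TESTS = 14  # QYes + F1c..F13


@dataclass(frozen=True)
class TaskSpec:
    """A binary diagnostic contrast between two disjoint sets of groups."""

    name: str
    positive_groups: frozenset = field(default_factory=frozenset)
    negative_groups: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.positive_groups & self.negative_groups:
            raise DomainError("positive and negative groups must be disjoint")

    def labels(self, groups: pd.Series) -> pd.Series:
        """0/1 task labels (positive group = 1) for the participants involved;
        participants outside both groups are dropped."""
        mask_pos = groups.isin(self.positive_groups)
        mask_neg = groups.isin(self.negative_groups)
        labels = pd.Series(np.nan, index=groups.index)
        labels[mask_pos] = 1.0
        labels[mask_neg] = 0.0
        return labels.dropna().astype(int)


TASK1 = TaskSpec("Task1", frozenset({"PD"}), frozenset({"CG"}))
TASK2 = TaskSpec("Task2", frozenset({"PD", "DD"}), frozenset({"CG"}))
TASK3 = TaskSpec("Task3", frozenset({"PD"}), frozenset({"DD"}))
TASKS = {"Task1": TASK1, "Task2": TASK2, "Task3": TASK3}


def bonferroni_threshold(alpha: float = DEFAULT_ALPHA, c: int = N_CORRECTED_TESTS) -> float:
    """Corrected significance level alpha/c (0.05/14 ≈ 0.0036)."""
    if c < 1:
        raise DomainError(f"number of tests must be >= 1, got {c}")
    return alpha / c


def significance_annotation(p: float, c: int = N_CORRECTED_TESTS) -> str:
    """Annotation ladder: ns > 0.05/c >= * > 0.01/c >= ** > 0.001/c >= *** > 1e-4/c >= ****."""
    if not 0 < p <= 1:
        raise DomainError(f"p-value must be in (0, 1], got {p}")
    if p <= 0.0001 / c:
        return "****"
    if p <= 0.001 / c:
        return "***"
    if p <= 0.01 / c:
        return "**"
    if p <= 0.05 / c:
        return "*"
    return "ns"


def _stat_row(feature: str, target: str, rho: float, p: float, c: int) -> dict:
    threshold = bonferroni_threshold(c=c)
    significant = bool(p < threshold)
    # exact-zero p-values (perfect separation) still get the strongest label
    p_ann = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return {
        "feature": feature,
        "target": target,
        "rho": rho,
        "p_value": p,
        "significant": significant,
        "annotation": significance_annotation(p_ann, c) if np.isfinite(p) else "ns",
    }


def spearman_table(features: pd.DataFrame, tasks=None, include_age: bool = True,
                   c: int = N_CORRECTED_TESTS,
                   feature_names=FEATURE_NAMES) -> pd.DataFrame:
    """Spearman rank correlation of every feature against each task label (and age).

    Constant features have undefined rank correlation and are reported with
    NaN rho and p = NaN (flagged ``ns``) after a warning.
    """
    tasks = TASKS if tasks is None else tasks
    targets: dict[str, pd.Series] = {}
    for name, task in tasks.items():
        labels = task.labels(features["group"])
        if labels.nunique() < 2:
            raise ValidationError(f"{name}: both groups must be represented")
        targets[name] = labels
    if include_age:
        targets["age"] = features["age"]

    rows = []
    for target_name, target in targets.items():
        sub = features.loc[target.index]
        for feat in feature_names:
            x = sub[feat].to_numpy(dtype=float)
            if np.all(x == x[0]):
                warnings.warn(f"feature {feat} is constant; rho undefined")
                rows.append(_stat_row(feat, target_name, np.nan, np.nan, c))
                continue
            rho, p = sps.spearmanr(x, target.to_numpy(dtype=float))
            rows.append(_stat_row(feat, target_name, float(rho), float(p), c))
    return pd.DataFrame(rows)


def mann_whitney_tests(features: pd.DataFrame, task: TaskSpec,
                       c: int = N_CORRECTED_TESTS,
                       feature_names=FEATURE_NAMES,
                       exact_max_n: int = 12) -> pd.DataFrame:
    """Two-sided Mann-Whitney-U test of each feature between the task's groups.

    Exact enumeration when both groups have <= ``exact_max_n`` members and the
    pooled values are tie-free; tie-corrected normal approximation otherwise.
    """
    labels = task.labels(features["group"])
    if (labels == 1).sum() == 0 or (labels == 0).sum() == 0:
        raise ValidationError(f"{task.name}: both groups must be non-empty")
    sub = features.loc[labels.index]
    rows = []
    for feat in feature_names:
        a = sub.loc[labels == 1, feat].to_numpy(dtype=float)
        b = sub.loc[labels == 0, feat].to_numpy(dtype=float)
        pooled = np.concatenate([a, b])
        if np.all(pooled == pooled[0]):
            # no separation at all: U is at its mean for every labelling
            u, p = len(a) * len(b) / 2.0, 1.0
        else:
            has_ties = len(np.unique(pooled)) < len(pooled)
            method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n
                                 and not has_ties) else "asymptotic"
            res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
            u, p = float(res.statistic), float(min(res.pvalue, 1.0))
        row = _stat_row(feat, task.name, np.nan, p, c)
        row["U"] = u
        row["n_pos"], row["n_neg"] = len(a), len(b)
        rows.append(row)
    return pd.DataFrame(rows)[
        ["feature", "target", "U", "n_pos", "n_neg", "p_value", "significant", "annotation"]
    ]


def feature_boxplots(features: pd.DataFrame, feature_names, task: TaskSpec,
                     c: int = N_CORRECTED_TESTS, log: bool = True, path=None):
    """Group-wise boxplots per feature with significance annotations.

    Drawing-task features are shown on the log(value + 1e-9) scale, which
    keeps occasional extreme values from dominating the axis.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .features import log_transform_features

    labels = task.labels(features["group"])
    sub = features.loc[labels.index]
    tests = mann_whitney_tests(features, task, c, feature_names)
    fig, axes = plt.subplots(1, len(feature_names),
                             figsize=(3.0 * len(feature_names), 4.0), squeeze=False)
    for ax, feat in zip(axes[0], feature_names):
        pos = sub.loc[labels == 1, feat].to_numpy(dtype=float)
        neg = sub.loc[labels == 0, feat].to_numpy(dtype=float)
        if log and feat != "QYes":
            pos, neg = log_transform_features(pos), log_transform_features(neg)
        ax.boxplot([neg, pos], tick_labels=["neg", "pos"])
        ann = tests.loc[tests["feature"] == feat, "annotation"].iloc[0]
        ax.set_title(f"{feat}\n{ann}")
    fig.suptitle(task.name)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
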