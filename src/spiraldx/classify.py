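"""Cross-validated classification of the three diagnostic tasks.

The estimator is a scaler → PCA → gradient-boosted-trees pipeline evaluated
under stratified fivefold cross-validation; scaler and PCA are fitted on the
training folds only.  Three feature sets mirror the ablation design:
``questionnaire_only`` (QYes alone), ``tablet_only`` (F1c..F13) and
``integrated`` (all 14), plus a majority-class dummy baseline.

Feature importances are exact Shapley values of a companion booster trained
per fold on the standardized but *unreduced* features: Shapley values of PCA
components are not attributable to named features, so PCA is bypassed for
explanation only.

The statsmodels-style front end is :class:`TaskClassifier` /
:class:`TaskClassifierResults`; the functions below are the underlying
operations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.dummy import DummyClassifier
from sklearn.metrics import accuracy_score, f1_score, precision_score, recall_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .errors import DomainError, ValidationError
from .features import FEATURE_NAMES, TABLET_FEATURES
from .shapley import exact_shapley
from .stats import TASKS, TaskSpec

FEATURE_SETS = {
    "questionnaire_only": ("QYes",),
    "tablet_only": TABLET_FEATURES,
    "integrated": FEATURE_NAMES,
}


@dataclass(frozen=True)
class ModelConfig:
    """Cross-validation and pipeline settings (library-default learner)."""

    n_folds: int = 5
    use_scaler: bool = True
    pca_variance_retained: float = 0.95
    seed: int = 0
    shap_background_size: int = 8

    def __post_init__(self):
        if self.n_folds < 2:
            raise DomainError("need >= 2 folds")
        if not 0 < self.pca_variance_retained <= 1:
            raise DomainError("pca_variance_retained must be in (0, 1]")


def _make_learner(seed: int) -> XGBClassifier:
    # library defaults; single-threaded for bitwise reproducibility
    return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0)


def _make_pipeline(config: ModelConfig, columns) -> Pipeline:
    """Scaler → PCA → boosted trees, with PCA restricted to the tablet features.

    Dimensionality reduction applies to the drawing features only; the
    questionnaire count (and any other non-tablet column) is standardized and
    passed through beside the principal components, so its signal is never
    smeared across components.
    """
    from sklearn.compose import ColumnTransformer

    tablet_idx = [i for i, c in enumerate(columns) if c in TABLET_FEATURES]
    other_idx = [i for i, c in enumerate(columns) if c not in TABLET_FEATURES]
    tablet_steps = []
    if config.use_scaler:
        tablet_steps.append(("scaler", StandardScaler()))
    tablet_steps.append(("pca", PCA(n_components=config.pca_variance_retained,
                                    svd_solver="full", random_state=config.seed)))
    branches = []
    if tablet_idx:
        branches.append(("tablet", Pipeline(tablet_steps), tablet_idx))
    if other_idx:
        other = StandardScaler() if config.use_scaler else "passthrough"
        branches.append(("other", other, other_idx))
    return Pipeline([
        ("features", ColumnTransformer(branches)),
        ("learner", _make_learner(config.seed)),
    ])


def make_task_dataset(features: pd.DataFrame, task: TaskSpec,
                      feature_set: str = "integrated"):
    """Rows restricted to the task's groups, columns per feature set.

    Returns (X, y, meta): X a DataFrame of predictors, y 0/1 labels with the
    disease group positive, meta the demographic columns for error analysis.
    """
    if feature_set not in FEATURE_SETS:
        raise DomainError(f"unknown feature set {feature_set!r}")
    labels = task.labels(features["group"])
    if labels.nunique() < 2:
        raise ValidationError(f"{task.name}: both groups must be non-empty")
    sub = features.loc[labels.index]
    X = sub[list(FEATURE_SETS[feature_set])]
    meta_cols = [c for c in ("group", "age", "gender", "hoehn_yahr", "QYes")
                 if c in sub.columns]
    return X, labels, sub[meta_cols]


def majority_baseline(y, n_folds: int = 5) -> float:
    """Mean stratified-CV test accuracy of the always-majority predictor."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class input: majority baseline is trivially 1.0")
        return 1.0
    skf = StratifiedKFold(n_splits=n_folds, shuffle=False)
    accs = []
    for train, test in skf.split(np.zeros((len(y), 1)), y):
        clf = DummyClassifier(strategy="most_frequent").fit(
            np.zeros((len(train), 1)), y[train]
        )
        accs.append(accuracy_score(y[test], clf.predict(np.zeros((len(test), 1)))))
    return float(np.mean(accs))


@dataclass
class CVResult:
    """Per-fold metrics, pooled out-of-fold predictions and the fold models."""

    fold_metrics: pd.DataFrame
    oof_prediction: pd.Series
    oof_probability: pd.Series
    fold_assignment: pd.Series
    models: list
    X: pd.DataFrame
    y: pd.Series
    config: ModelConfig
    train_indices: list

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics[["accuracy", "precision", "recall", "f1"]].mean()


def run_cv(X: pd.DataFrame, y: pd.Series, config: ModelConfig = ModelConfig(),
           _leak_preprocessing: bool = False) -> CVResult:
    """Stratified k-fold CV of the scaler→PCA→boosted-trees pipeline.

    ``_leak_preprocessing`` exists only for the no-leakage regression test: it
    (incorrectly) fits scaler and PCA on the full dataset before the split.
    """
    y = pd.Series(np.asarray(y), index=X.index, name="label")
    counts = y.value_counts()
    if (counts < config.n_folds).any():
        raise ValidationError(
            f"every class needs >= {config.n_folds} members for {config.n_folds}-fold "
            f"CV (counts: {counts.to_dict()}); use fewer folds"
        )
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    Xv = X.to_numpy(dtype=float)
    yv = y.to_numpy()

    leaky_transform = None
    if _leak_preprocessing:
        pre = Pipeline([("scaler", StandardScaler()),
                        ("pca", PCA(n_components=config.pca_variance_retained,
                                    svd_solver="full", random_state=config.seed))])
        leaky_transform = pre.fit(Xv).transform

    rows, models, train_indices = [], [], []
    oof_pred = pd.Series(index=X.index, dtype=float)
    oof_proba = pd.Series(index=X.index, dtype=float)
    fold_of = pd.Series(index=X.index, dtype=int)
    for fold, (train, test) in enumerate(skf.split(Xv, yv)):
        if leaky_transform is not None:
            learner = _make_learner(config.seed)
            learner.fit(leaky_transform(Xv[train]), yv[train])
            proba = learner.predict_proba(leaky_transform(Xv[test]))[:, 1]
            model = learner
        else:
            model = _make_pipeline(config, X.columns)
            model.fit(Xv[train], yv[train])
            proba = model.predict_proba(Xv[test])[:, 1]
        pred = (proba >= 0.5).astype(int)
        rows.append({
            "fold": fold,
            "accuracy": accuracy_score(yv[test], pred),
            "precision": precision_score(yv[test], pred, zero_division=0),
            "recall": recall_score(yv[test], pred, zero_division=0),
            "f1": f1_score(yv[test], pred, zero_division=0),
            "n_test": len(test),
        })
        oof_pred.iloc[test] = pred
        oof_proba.iloc[test] = proba
        fold_of.iloc[test] = fold
        models.append(model)
        train_indices.append(train)
    return CVResult(
        fold_metrics=pd.DataFrame(rows).set_index("fold"),
        oof_prediction=oof_pred.astype(int),
        oof_probability=oof_proba,
        fold_assignment=fold_of.astype(int),
        models=models,
        X=X,
        y=y,
        config=config,
        train_indices=train_indices,
    )


@dataclass
class ImportanceReport:
    """Per-fold Shapley summaries per feature (log-odds scale).

    ``per_fold_mean`` holds the signed mean attribution over each test fold
    (the quantity whose five-fold distribution the importance boxplots show);
    ``per_fold_mean_abs`` the mean |attribution|, which is what features are
    ranked by — signed means of a symmetric effect cancel.
    """

    per_fold_mean: pd.DataFrame      # folds x features, signed
    per_fold_mean_abs: pd.DataFrame  # folds x features, mean |phi|
    per_sample: list  # per fold: (phi array, base value, margins, test index)

    @property
    def mean_abs_ranking(self) -> pd.Series:
        return self.per_fold_mean_abs.mean(axis=0).sort_values(ascending=False)


def shap_importance(cv: CVResult) -> ImportanceReport:
    """Exact Shapley importances of each fold's companion model on its test fold.

    The companion is the same boosted-tree learner fitted on the fold's
    standardized training features without PCA; attributions are exact
    coalition-enumeration Shapley values against a seeded subsample of the
    training rows, on the log-odds scale.
    """
    rng = np.random.default_rng(cv.config.seed)
    Xv = cv.X.to_numpy(dtype=float)
    yv = cv.y.to_numpy()
    fold_rows, fold_rows_abs, per_sample = [], [], []
    for fold in sorted(cv.fold_assignment.unique()):
        train = cv.train_indices[fold]
        test = np.flatnonzero(cv.fold_assignment.to_numpy() == fold)
        scaler = StandardScaler().fit(Xv[train])
        companion = _make_learner(cv.config.seed)
        companion.fit(scaler.transform(Xv[train]), yv[train])
        predict = lambda A: companion.predict(A, output_margin=True)
        b = min(cv.config.shap_background_size, len(train))
        background = scaler.transform(
            Xv[rng.choice(train, size=b, replace=False)]
        )
        X_test = scaler.transform(Xv[test])
        phi, base = exact_shapley(predict, X_test, background)
        margins = np.asarray(predict(X_test), dtype=float)
        fold_rows.append(pd.Series(phi.mean(axis=0), index=cv.X.columns, name=fold))
        fold_rows_abs.append(pd.Series(np.abs(phi).mean(axis=0), index=cv.X.columns,
                                       name=fold))
        per_sample.append((phi, base, margins, cv.X.index[test]))
    return ImportanceReport(per_fold_mean=pd.DataFrame(fold_rows),
                            per_fold_mean_abs=pd.DataFrame(fold_rows_abs),
                            per_sample=per_sample)


def error_analysis(cv: CVResult, meta: pd.DataFrame, task: TaskSpec) -> pd.DataFrame:
    """Descriptive statistics of the misclassified subgroups.

    Error classes are FP (negatives predicted positive) and FN (positives
    predicted negative); for Task2 FN is split by the true subgroup (PD/DD).
    Reported per class: count, mean age, female count, mean QYes, mean
    Hoehn-Yahr over members with a defined stage.  Empty subgroups report
    count 0 and blank statistics.
    """
    pred, truth = cv.oof_prediction, cv.y
    errors = {
        "FP": meta.index[(truth == 0) & (pred == 1)],
        "FN": meta.index[(truth == 1) & (pred == 0)],
    }
    if task.name == "Task2":
        fn = errors.pop("FN")
        errors["FN_PD"] = [i for i in fn if meta.loc[i, "group"] == "PD"]
        errors["FN_DD"] = [i for i in fn if meta.loc[i, "group"] == "DD"]
    rows = []
    for label, ids in errors.items():
        sub = meta.loc[list(ids)]
        row = {"task": task.name, "error_class": label, "count": len(sub)}
        if len(sub):
            row["mean_age"] = float(sub["age"].mean())
            row["female_count"] = int((sub["gender"] == "female").sum())
            row["mean_qyes"] = float(sub["QYes"].mean()) if "QYes" in sub else np.nan
            hy = sub["hoehn_yahr"].dropna()
            row["mean_hoehn_yahr"] = float(hy.mean()) if len(hy) else np.nan
        else:
            row.update({"mean_age": np.nan, "female_count": np.nan,
                        "mean_qyes": np.nan, "mean_hoehn_yahr": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def ablation_suite(features: pd.DataFrame, config: ModelConfig = ModelConfig(),
                   tasks=None) -> dict:
    """The full ablation: dummy / questionnaire-only / tablet-only / integrated
    accuracy per task, plus precision/recall/F1 of the integrated model."""
    tasks = TASKS if tasks is None else tasks
    report: dict = {}
    for name, task in tasks.items():
        X, y, meta = make_task_dataset(features, task, "integrated")
        entry = {"n": int(len(y)),
                 "dummy_accuracy": majority_baseline(y, config.n_folds)}
        for fs_name, key in (("questionnaire_only", "qyes_only_accuracy"),
                             ("tablet_only", "tablet_only_accuracy"),
                             ("integrated", "integrated_accuracy")):
            Xf, yf, _ = make_task_dataset(features, task, fs_name)
            cv = run_cv(Xf, yf, config)
            entry[key] = float(cv.mean_metrics["accuracy"])
            if fs_name == "integrated":
                entry["integrated_precision"] = float(cv.mean_metrics["precision"])
                entry["integrated_recall"] = float(cv.mean_metrics["recall"])
                entry["integrated_f1"] = float(cv.mean_metrics["f1"])
        report[name] = entry
    return report


# ---------------------------------------------------------------------------
# model-object front end
# ---------------------------------------------------------------------------

class TaskClassifier:
    """Cross-validated classifier for one diagnostic task.

    Built from a participant feature table (``extract_feature_table`` output
    or an equivalent DataFrame); ``fit`` runs the stratified CV and returns a
    :class:`TaskClassifierResults`.
    """

    def __init__(self, features: pd.DataFrame, task: TaskSpec | str,
                 feature_set: str = "integrated",
                 config: ModelConfig = ModelConfig()):
        self.task = TASKS[task] if isinstance(task, str) else task
        self.feature_set = feature_set
        self.config = config
        self.features = features
        self.X, self.y, self.meta = make_task_dataset(features, self.task, feature_set)

    @classmethod
    def from_cohort(cls, cohort, task, feature_set: str = "integrated",
                    config: ModelConfig = ModelConfig(), **extract_kwargs):
        from .features import extract_feature_table

        return cls(extract_feature_table(cohort, **extract_kwargs), task,
                   feature_set, config)

    def fit(self) -> "TaskClassifierResults":
        cv = run_cv(self.X, self.y, self.config)
        return TaskClassifierResults(self, cv)


class TaskClassifierResults:
    """Fit results: per-fold metrics, pooled predictions, importances, errors."""

    def __init__(self, model: TaskClassifier, cv: CVResult):
        self.model = model
        self.cv = cv
        self.fold_metrics = cv.fold_metrics
        self.mean_metrics = cv.mean_metrics
        self._importance: ImportanceReport | None = None

    @property
    def accuracy(self) -> float:
        return float(self.mean_metrics["accuracy"])

    def shap_importance(self) -> ImportanceReport:
        if self._importance is None:
            self._importance = shap_importance(self.cv)
        return self._importance

    def error_analysis(self) -> pd.DataFrame:
        return error_analysis(self.cv, self.model.meta, self.model.task)

    def baseline_accuracy(self) -> float:
        return majority_baseline(self.cv.y, self.model.config.n_folds)

    def summary(self) -> str:
        lines = [
            f"{self.model.task.name}: "
            f"{sorted(self.model.task.positive_groups)} vs {sorted(self.model.task.negative_groups)}",
            f"feature set: {self.model.feature_set} "
            f"({self.model.X.shape[1]} predictors, n={len(self.cv.y)})",
            f"stratified {self.model.config.n_folds}-fold CV, seed {self.model.config.seed}",
            "",
            self.fold_metrics.to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            "mean over folds:",
            self.mean_metrics.to_string(float_format=lambda v: f"{v:.3f}"),
            f"majority baseline accuracy: {self.baseline_accuracy():.3f}",
        ]
        return "\n".join(lines)

    def plot_importance(self, path=None):
        """Fig.-4-style boxplots of the per-fold mean Shapley values."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        report = self.shap_importance()
        order = report.mean_abs_ranking.index
        fig, ax = plt.subplots(figsize=(7, 0.4 * len(order) + 1.5))
        ax.boxplot([report.per_fold_mean[f] for f in order][::-1],
                   orientation="horizontal", tick_labels=list(order)[::-1])
        ax.axvline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("mean Shapley value per fold (log-odds)")
        ax.set_title(f"{self.model.task.name} feature importance")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
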