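"""Multi-classifier evaluation of ordinal feature sets.

Three model families — random forest, RBF support-vector machine, and
gradient-boosted trees (XGBoost) — are tuned by randomized hyperparameter
search (5-fold cross-validated accuracy, 75 candidate configurations by
default) on a stratified 85/15 train/test split, then evaluated with
row-normalized five-class confusion matrices and, for the tree ensembles,
total-gain feature importances.

The hyperparameter search spaces live in :data:`SEARCH_SPACES` and are plain
data, so callers can override them per family.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import loguniform, randint, uniform
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RandomizedSearchCV, StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import UnsupportedModelError
from .feature_pipeline import FeatureTable
from .sleep_io import STAGES

MODEL_FAMILIES = ("random_forest", "svm", "gradient_boosted_trees")

#: Randomized-search spaces per family (user-overridable defaults; the study
#: protocol fixes only the search budget, not the spaces).
SEARCH_SPACES: dict[str, dict] = {
    "random_forest": {
        "n_estimators": randint(100, 500),
        "max_depth": [None, 5, 10, 20, 30],
        "max_features": ["sqrt", "log2", 0.5],
        "min_samples_split": randint(2, 11),
        "min_samples_leaf": randint(1, 5),
    },
    "svm": {
        "svc__C": loguniform(1e-2, 1e3),
        "svc__gamma": loguniform(1e-4, 1e1),
    },
    "gradient_boosted_trees": {
        "n_estimators": randint(100, 600),
        "max_depth": randint(3, 11),
        "learning_rate": loguniform(0.01, 0.3),
        "subsample": uniform(0.6, 0.4),
        "colsample_bytree": uniform(0.6, 0.4),
        "min_child_weight": randint(1, 6),
    },
}


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one feature-set x model-family experiment."""

    feature_set: str = "GWPDF"
    model_family: str = "gradient_boosted_trees"
    test_fraction: float = 0.15
    cv_folds: int = 5
    n_search_iters: int = 75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"model_family must be one of {MODEL_FAMILIES}")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2 or self.n_search_iters < 1:
            raise ValueError("cv_folds >= 2 and n_search_iters >= 1 required")


@dataclass
class EvaluationReport:
    """Cross-validation and held-out performance of one fitted model."""

    feature_set: str
    model_family: str
    cv_mean_accuracy: float
    cv_sd_accuracy: float
    test_accuracy: float
    confusion_counts: np.ndarray  # 5x5, true stages (W,N1,N2,N3,R) as rows
    confusion_percent: np.ndarray  # row-normalized to 100
    feature_importances: list[tuple[str, float | None, float]] | None = None
    best_params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "feature_set": self.feature_set,
            "model_family": self.model_family,
            "cv_mean_accuracy": self.cv_mean_accuracy,
            "cv_sd_accuracy": self.cv_sd_accuracy,
            "test_accuracy": self.test_accuracy,
            "stage_order": list(STAGES),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_percent": self.confusion_percent.tolist(),
            "feature_importances": self.feature_importances,
            "best_params": {k: repr(v) for k, v in self.best_params.items()},
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _encode_labels(y: np.ndarray) -> np.ndarray:
    index = {s: i for i, s in enumerate(STAGES)}
    return np.array([index[label] for label in y])


def split_data(
    table: FeatureTable, spec: ExperimentSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Stratified, seeded train/test split of a feature table.

    Returns ``(X_train, X_test, y_train, y_test)`` with integer-encoded
    stage labels (W=0 .. R=4).
    """
    X = table.X
    y = _encode_labels(table.y)
    return train_test_split(
        X,
        y,
        test_size=spec.test_fraction,
        random_state=spec.seed,
        stratify=y,
    )


def make_estimator(model_family: str, seed: int):
    """Unfitted estimator for one family (SVM wrapped with standardization)."""
    if model_family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if model_family == "svm":
        return Pipeline(
            [("scaler", StandardScaler()), ("svc", SVC(kernel="rbf", random_state=seed))]
        )
    if model_family == "gradient_boosted_trees":
        # exact split finding: places thresholds at margin midpoints, which
        # matters at the few-hundred-epoch scale this package targets
        return XGBClassifier(
            random_state=seed,
            n_jobs=1,
            tree_method="exact",
            importance_type="total_gain",
            verbosity=0,
        )
    raise ValueError(f"unknown model family {model_family!r}")


def tune_and_train(X_train: np.ndarray, y_train: np.ndarray, spec: ExperimentSpec):
    """Randomized hyperparameter search, refit on the full training split.

    Samples ``n_search_iters`` configurations from the family's search space,
    scores each by ``cv_folds``-fold cross-validated accuracy, and refits the
    best.  Returns ``(model, cv_mean_accuracy, cv_sd_accuracy, best_params)``.
    """
    if np.unique(y_train).size < 2:
        raise ValueError("training data must contain at least two classes")
    estimator = make_estimator(spec.model_family, spec.seed)
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)
    search = RandomizedSearchCV(
        estimator,
        SEARCH_SPACES[spec.model_family],
        n_iter=spec.n_search_iters,
        scoring="accuracy",
        cv=cv,
        random_state=spec.seed,
        n_jobs=1,
        refit=True,
    )
    search.fit(X_train, y_train)
    best = search.best_index_
    cv_mean = float(search.cv_results_["mean_test_score"][best])
    cv_sd = float(search.cv_results_["std_test_score"][best])
    return search.best_estimator_, cv_mean, cv_sd, dict(search.best_params_)


def evaluate(
    model,
    X_test: np.ndarray,
    y_test: np.ndarray,
    spec: ExperimentSpec,
    cv_mean: float = float("nan"),
    cv_sd: float = float("nan"),
    feature_names: list[str] | None = None,
    best_params: dict | None = None,
) -> EvaluationReport:
    """Held-out confusion matrix (row-normalized %) and test accuracy."""
    y_pred = model.predict(X_test)
    counts = confusion_matrix(y_test, y_pred, labels=np.arange(len(STAGES)))
    row_sums = counts.sum(axis=1, keepdims=True)
    empty = row_sums[:, 0] == 0
    if empty.any():
        warnings.warn(
            f"stages absent from test set: {[STAGES[i] for i in np.flatnonzero(empty)]}"
        )
    percent = 100.0 * counts / np.where(row_sums == 0, 1, row_sums)
    accuracy = float(np.trace(counts) / counts.sum())

    importances = None
    if feature_names is not None and spec.model_family != "svm":
        try:
            importances = feature_importance(model, feature_names)
        except UnsupportedModelError:
            importances = None

    return EvaluationReport(
        feature_set=spec.feature_set,
        model_family=spec.model_family,
        cv_mean_accuracy=cv_mean,
        cv_sd_accuracy=cv_sd,
        test_accuracy=accuracy,
        confusion_counts=counts,
        confusion_percent=percent,
        feature_importances=importances,
        best_params=best_params or {},
    )


def _parse_q(feature_name: str) -> float | None:
    if "_q" in feature_name:
        try:
            return float(feature_name.rsplit("_q", 1)[1])
        except ValueError:
            return None
    return None


def feature_importance(model, feature_names: list[str]) -> list[tuple[str, float | None, float]]:
    """Per-feature split-gain importance, normalized to sum 1, descending.

    Defined for the tree ensembles only; gain has no analogue for the SVM.
    Each entry is ``(feature_name, q_index_or_None, relative_importance)``.
    """
    if isinstance(model, Pipeline) or isinstance(model, SVC):
        raise UnsupportedModelError("gain importance is undefined for SVM models")
    if isinstance(model, XGBClassifier):
        booster = model.get_booster()
        score = booster.get_score(importance_type="total_gain")
        raw = np.array([score.get(f"f{i}", 0.0) for i in range(len(feature_names))])
    elif hasattr(model, "feature_importances_"):
        raw = np.asarray(model.feature_importances_, dtype=float)
    else:
        raise UnsupportedModelError(f"no importance defined for {type(model).__name__}")
    total = raw.sum()
    if total <= 0:
        raise UnsupportedModelError("model has no positive split gains")
    rel = raw / total
    order = np.argsort(rel)[::-1]
    return [(feature_names[i], _parse_q(feature_names[i]), float(rel[i])) for i in order]


def run_experiment(table: FeatureTable, spec: ExperimentSpec) -> EvaluationReport:
    """Split, tune, train and evaluate one feature-set / family cell."""
    X_train, X_test, y_train, y_test = split_data(table, spec)
    model, cv_mean, cv_sd, best_params = tune_and_train(X_train, y_train, spec)
    return evaluate(
        model,
        X_test,
        y_test,
        spec,
        cv_mean=cv_mean,
        cv_sd=cv_sd,
        feature_names=table.feature_names,
        best_params=best_params,
    )


def run_experiment_grid(
    tables: dict[str, FeatureTable],
    families: tuple[str, ...] = MODEL_FAMILIES,
    base_spec: ExperimentSpec | None = None,
) -> tuple[dict[tuple[str, str], EvaluationReport], pd.DataFrame]:
    """Evaluate every feature set with every model family.

    Failures in one cell are recorded and the grid continues.  Returns the
    report mapping and a summary frame of CV accuracy +/- sd per cell.
    """
    base = base_spec or ExperimentSpec()
    reports: dict[tuple[str, str], EvaluationReport] = {}
    rows = []
    for feature_set, table in tables.items():
        for family in families:
            spec = replace(base, feature_set=feature_set, model_family=family)
            try:
                report = run_experiment(table, spec)
            except Exception as exc:  # noqa: BLE001 - keep the grid running
                warnings.warn(f"experiment {feature_set}/{family} failed: {exc}")
                continue
            reports[(feature_set, family)] = report
            rows.append(
                {
                    "feature_set": feature_set,
                    "model_family": family,
                    "cv_mean_accuracy": report.cv_mean_accuracy,
                    "cv_sd_accuracy": report.cv_sd_accuracy,
                    "test_accuracy": report.test_accuracy,
                }
            )
    return reports, pd.DataFrame(rows)


def plot_confusion(report: EvaluationReport, ax=None):
    """Heatmap of the row-normalized confusion matrix (percent)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    im = ax.imshow(report.confusion_percent, cmap="Blues", vmin=0, vmax=100)
    ax.set_xticks(range(len(STAGES)), STAGES)
    ax.set_yticks(range(len(STAGES)), STAGES)
    ax.set_xlabel("Predicted stage")
    ax.set_ylabel("True stage")
    ax.set_title(f"{report.model_family} / {report.feature_set}")
    for i in range(len(STAGES)):
        for j in range(len(STAGES)):
            ax.text(j, i, f"{report.confusion_percent[i, j]:.0f}", ha="center", va="center")
    plt.colorbar(im, ax=ax, label="%")
    return ax
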