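"""Feature selection, subject-level splitting, and nested cross-validation.

The evaluation design tests *between-subject* generalization: the outer loop
is leave-one-subject-out (all of a subject's segments held out together) and
an inner 5-fold grid search on the remaining subjects picks hyperparameters
that minimise the mean inner test error.  Feature selection by mutual
information happens once on the full training partition before nested CV —
this mirrors a common applied design and is a known (mild) source of
optimism, documented rather than silently fixed.

Four classifier families are supported: gradient boosting, XGBoost, random
forest, and L2 logistic regression (with standardisation).
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, GroupKFold, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .resp_features import META_COLUMNS
from .rocstats import auc as roc_auc
from .rocstats import ci_over_loops

__all__ = [
    "ALGORITHM_ALIASES",
    "DEFAULT_GRIDS",
    "REDUCED_GRIDS",
    "NestedCVResult",
    "ModelBundle",
    "split_by_subject",
    "select_top_k_mutual_info",
    "nested_cv",
    "final_model",
    "evaluate",
    "permute_labels_within_subject",
    "feature_columns",
]

ALGORITHM_ALIASES = {
    "gb": "gradient_boosting",
    "xgb": "xgboost",
    "rf": "random_forest",
    "lr": "logistic_regression",
}

#: small published-default grids per algorithm
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "gradient_boosting": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3, 5],
        "learning_rate": [0.05, 0.1],
    },
    "xgboost": {
        "n_estimators": [100, 300],
        "max_depth": [2, 3, 5],
        "learning_rate": [0.05, 0.1],
    },
    "random_forest": {
        "n_estimators": [100, 300],
        "max_depth": [3, 5, None],
    },
    "logistic_regression": {"clf__C": [0.01, 0.1, 1.0, 10.0]},
}

#: reduced grids for runtime-constrained end-to-end runs
REDUCED_GRIDS: dict[str, dict[str, list]] = {
    "gradient_boosting": {"n_estimators": [100], "max_depth": [2, 3], "learning_rate": [0.1]},
    "xgboost": {"n_estimators": [100], "max_depth": [2, 3], "learning_rate": [0.1]},
    "random_forest": {"n_estimators": [100], "max_depth": [3, None]},
    "logistic_regression": {"clf__C": [0.1, 1.0]},
}


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def make_estimator(algorithm: str, seed: int = 0):
    """Instantiate an unfitted classifier for one of the four families."""
    algorithm = ALGORITHM_ALIASES.get(algorithm, algorithm)
    if algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed)
    if algorithm == "xgboost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", verbosity=0
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1)
    if algorithm == "logistic_regression":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        )
    raise ValueError(f"unknown algorithm '{algorithm}'")


def split_by_subject(
    subjects: list[str], test_fraction: float = 0.2, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random disjoint train/test split at the subject level.

    The test pool should be restricted to subjects with complete data across
    all methods so the same test set can be reused for every method.
    """
    subjects = sorted(set(subjects))
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects to split")
    n_test = max(1, int(round(test_fraction * len(subjects))))
    if n_test >= len(subjects):
        raise ValueError("test fraction leaves no training subjects")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    test = sorted(subjects[i] for i in order[:n_test])
    train = sorted(subjects[i] for i in order[n_test:])
    return train, test


def select_top_k_mutual_info(
    table: pd.DataFrame, k: int = 10, seed: int = 0
) -> list[str]:
    """Rank features by estimated mutual information with the speech label.

    Returns the ``k`` highest-MI feature names (training subjects only should
    be passed in).  A feature independent of the label has MI ~ 0 and is
    excluded; ties are broken by column order for determinism.
    """
    cols = feature_columns(table)
    if k > len(cols):
        raise ValueError(f"k={k} exceeds feature count {len(cols)}")
    mi = mutual_info_classif(
        table[cols].to_numpy(), table["label"].to_numpy(), random_state=seed
    )
    order = np.argsort(-mi, kind="stable")
    return [cols[i] for i in order[:k]]


def evaluate(scores, labels) -> dict[str, float]:
    """AUC, accuracy, sensitivity and specificity (percent) at threshold 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = (scores >= 0.5).astype(int)
    pos = labels == 1
    neg = labels == 0
    return {
        "auc": 100.0 * roc_auc(scores, labels),
        "accuracy": 100.0 * float(np.mean(pred == labels)),
        "sensitivity": 100.0 * float(np.mean(pred[pos] == 1)),
        "specificity": 100.0 * float(np.mean(pred[neg] == 0)),
    }


@dataclass
class NestedCVResult:
    """Per-outer-loop metrics of a leave-one-subject-out nested CV."""

    algorithm: str
    loops: pd.DataFrame  # subject_id, auc, accuracy, sensitivity, specificity, params
    train_subject_sets: list[frozenset] = field(default_factory=list)

    @property
    def n_loops(self) -> int:
        return len(self.loops)

    def summary(self) -> dict[str, tuple[float, float, float, float]]:
        """Per metric: mean, SD, and 95 % CI bounds over the outer loops."""
        return {
            m: ci_over_loops(self.loops[m].to_numpy())
            for m in ("auc", "accuracy", "sensitivity", "specificity")
        }

    def mean_auc(self) -> float:
        return float(self.loops["auc"].mean(skipna=True))

    def mode_params(self) -> dict:
        """Per-hyperparameter mode over outer loops; ties break toward the
        smaller (more regularized) value, ``None`` counting as largest."""

        def regkey(v):
            return float("inf") if v is None else v

        keys = self.loops["params"].iloc[0].keys()
        out = {}
        for key in keys:
            counts = Counter(p[key] for p in self.loops["params"])
            out[key] = min(counts, key=lambda v: (-counts[v], regkey(v)))
        return out


def nested_cv(
    table: pd.DataFrame,
    algorithm: str,
    grid: dict[str, list] | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    grouped_inner: bool = False,
) -> NestedCVResult:
    """Leave-one-subject-out nested cross-validation.

    Each outer loop holds out all segments of one subject; an inner
    ``inner_folds``-fold grid search over the remaining subjects' segments
    (stratified over segments by default; grouped by subject with
    ``grouped_inner=True``) selects hyperparameters by mean accuracy; the
    selected model is refit on the full outer-train data and scored on the
    held-out subject.  A held-out subject with a single class has no defined
    AUC; the loop is recorded with NaN metrics and excluded from summaries
    with a warning.
    """
    algorithm = ALGORITHM_ALIASES.get(algorithm, algorithm)
    if grid is None:
        grid = DEFAULT_GRIDS[algorithm]
    if not grid:
        raise ValueError("hyperparameter grid must be non-empty")
    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 3:
        raise ValueError("nested CV needs at least 3 training subjects")
    cols = feature_columns(table)

    rows = []
    train_sets: list[frozenset] = []
    for held_out in subjects:
        outer_train = table[table["subject_id"] != held_out]
        outer_test = table[table["subject_id"] == held_out]
        assert held_out not in set(outer_train["subject_id"])  # no-leakage guard
        train_sets.append(frozenset(outer_train["subject_id"].unique()))

        X = outer_train[cols].to_numpy()
        y = outer_train["label"].to_numpy()
        if grouped_inner:
            cv = GroupKFold(n_splits=inner_folds)
            groups = outer_train["subject_id"].to_numpy()
        else:
            cv = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
            groups = None
        search = GridSearchCV(
            make_estimator(algorithm, seed),
            grid,
            scoring="accuracy",
            cv=cv,
            n_jobs=1,
            refit=True,
        )
        search.fit(X, y, groups=groups)

        y_test = outer_test["label"].to_numpy()
        proba = search.predict_proba(outer_test[cols].to_numpy())[:, 1]
        if len(np.unique(y_test)) < 2:
            warnings.warn(
                f"held-out subject {held_out} has a single class; AUC undefined",
                UserWarning,
                stacklevel=2,
            )
            metrics = {m: np.nan for m in ("auc", "accuracy", "sensitivity", "specificity")}
        else:
            metrics = evaluate(proba, y_test)
        rows.append({"subject_id": held_out, **metrics, "params": search.best_params_})
    return NestedCVResult(algorithm, pd.DataFrame(rows), train_sets)


@dataclass
class ModelBundle:
    """A final fitted model with its provenance manifest."""

    algorithm: str
    params: dict
    feature_names: list[str]
    model: object
    train_subjects: list[str]
    seed: int = 0

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(table[self.feature_names].to_numpy())[:, 1]

    @property
    def feature_importances(self) -> pd.Series:
        """Impurity importances for tree models, |coefficients| for the
        linear model, indexed by feature name."""
        if hasattr(self.model, "feature_importances_"):
            vals = self.model.feature_importances_
        else:
            vals = np.abs(self.model.named_steps["clf"].coef_.ravel())
        return pd.Series(vals, index=self.feature_names)

    def save(self, path) -> None:
        path = Path(path)
        joblib.dump(self.model, path)
        import sklearn

        manifest = {
            "algorithm": self.algorithm,
            "hyperparameters": {k: v for k, v in self.params.items()},
            "feature_names": self.feature_names,
            "train_subjects": self.train_subjects,
            "seed": self.seed,
            "versions": {"sklearn": sklearn.__version__, "numpy": np.__version__},
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)

    @classmethod
    def load(cls, path) -> "ModelBundle":
        path = Path(path)
        model = joblib.load(path)
        with open(path.with_suffix(path.suffix + ".json")) as fh:
            manifest = json.load(fh)
        return cls(
            algorithm=manifest["algorithm"],
            params=manifest["hyperparameters"],
            feature_names=manifest["feature_names"],
            model=model,
            train_subjects=manifest["train_subjects"],
            seed=manifest["seed"],
        )


def final_model(
    table: pd.DataFrame, algorithm: str, cv_result: NestedCVResult, seed: int = 0
) -> ModelBundle:
    """Train the single final model on all training subjects.

    Hyperparameters are set to the per-parameter mode across the nested-CV
    outer loops (ties toward the more regularized value); features are the
    table's feature columns (already reduced to the selected set).
    """
    algorithm = ALGORITHM_ALIASES.get(algorithm, algorithm)
    if cv_result.algorithm != algorithm:
        raise ValueError(
            f"cv_result is for '{cv_result.algorithm}', not '{algorithm}'"
        )
    params = cv_result.mode_params()
    est = make_estimator(algorithm, seed)
    est.set_params(**params)
    cols = feature_columns(table)
    est.fit(table[cols].to_numpy(), table["label"].to_numpy())
    return ModelBundle(
        algorithm=algorithm,
        params=params,
        feature_names=cols,
        model=est,
        train_subjects=sorted(table["subject_id"].unique()),
        seed=seed,
    )


def permute_labels_within_subject(table: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Shuffle labels within each subject (null-distribution experiments)."""
    rng = np.random.default_rng(seed)
    out = table.copy()
    for _, idx in out.groupby("subject_id", sort=False).groups.items():
        out.loc[idx, "label"] = rng.permutation(out.loc[idx, "label"].to_numpy())
    return out
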