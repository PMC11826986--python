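"""End-to-end synthetic study: cohort -> features -> nested CV -> comparison.

Reproduces the full evaluation design on a synthetic cohort: generate
subjects, extract each method's feature bank, hold out a subject-level test
set (the same subjects for every method), select the top-10 features by
mutual information on the training partition, run leave-one-subject-out
nested cross-validation, train final models with mode hyperparameters, score
them on the held-out subjects, and compare methods' test ROC curves with the
paired DeLong test.  A label-permutation null run calibrates the pipeline
against leakage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import simulate_cohort
from .ml import (
    REDUCED_GRIDS,
    ModelBundle,
    NestedCVResult,
    evaluate,
    final_model,
    nested_cv,
    permute_labels_within_subject,
    select_top_k_mutual_info,
)
from .pipeline import METHODS, features_for_recording
from .resp_features import impute_within_subject
from .rocstats import ROCComparison, delong_paired_test
from .ml import split_by_subject

__all__ = ["StudyResult", "run_study", "extract_method_tables"]


@dataclass
class StudyResult:
    """Everything the synthetic study computes, keyed by method."""

    n_subjects: int
    seed: int
    train_subjects: list[str]
    test_subjects: list[str]
    selected_features: dict[str, list[str]]
    cv_results: dict[str, NestedCVResult]
    final_models: dict[str, ModelBundle]
    test_metrics: dict[str, dict[str, float]]
    delong_vs_accgyro: dict[str, ROCComparison]
    permuted_null_auc: float
    tables: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def nested_auc(self) -> dict[str, float]:
        return {m: r.mean_auc() for m, r in self.cv_results.items()}


def extract_method_tables(
    n_subjects: int, seed: int, window_s: float = 30.0, methods=METHODS
) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and extract every method's feature table.

    Subjects are streamed: each recording is generated, featurised for all
    methods, and released before the next is drawn.
    """
    parts: dict[str, list[pd.DataFrame]] = {m: [] for m in methods}
    for rec in simulate_cohort(n_subjects, seed):
        for m in methods:
            parts[m].append(features_for_recording(rec, m, window_s))
    return {
        m: impute_within_subject(pd.concat(frames, ignore_index=True))
        for m, frames in parts.items()
    }


def run_study(
    n_subjects: int = 20,
    seed: int = 0,
    *,
    algorithm: str = "gradient_boosting",
    grids: dict[str, dict] | None = None,
    top_k: int = 10,
    test_fraction: float = 0.2,
    window_s: float = 30.0,
    null_algorithm: str = "logistic_regression",
    n_null_permutations: int = 3,
    keep_tables: bool = False,
) -> StudyResult:
    """Run the complete synthetic evaluation.

    ``grids`` defaults to the reduced grids to keep a full study tractable on
    one CPU.  The permutation null shuffles labels within subject and reruns
    feature selection and nested CV (with the fast linear model), averaging
    the mean AUC over ``n_null_permutations`` permutations.
    """
    if grids is None:
        grids = REDUCED_GRIDS
    rng_state = np.random.SeedSequence(seed).generate_state(4)
    split_seed, mi_seed, fit_seed, null_seed = (int(s % 2**31) for s in rng_state)

    tables = extract_method_tables(n_subjects, seed, window_s)
    subjects = sorted(tables[METHODS[0]]["subject_id"].unique())
    train_ids, test_ids = split_by_subject(subjects, test_fraction, split_seed)

    selected: dict[str, list[str]] = {}
    cv_results: dict[str, NestedCVResult] = {}
    models: dict[str, ModelBundle] = {}
    test_metrics: dict[str, dict[str, float]] = {}
    test_scores: dict[str, np.ndarray] = {}
    meta = ["subject_id", "segment_idx", "label"]
    test_labels: np.ndarray | None = None

    for m in METHODS:
        table = tables[m]
        train = table[table["subject_id"].isin(train_ids)].reset_index(drop=True)
        test = table[table["subject_id"].isin(test_ids)].reset_index(drop=True)
        feats = select_top_k_mutual_info(train, top_k, seed=mi_seed)
        selected[m] = feats
        train = train[meta + feats]
        cv = nested_cv(train, algorithm, grids[algorithm], seed=fit_seed)
        cv_results[m] = cv
        bundle = final_model(train, algorithm, cv, seed=fit_seed)
        models[m] = bundle
        scores = bundle.predict_proba(test)
        test_scores[m] = scores
        labels = test["label"].to_numpy()
        if test_labels is None:
            test_labels = labels
        test_metrics[m] = evaluate(scores, labels)

    delong = {
        m: delong_paired_test(test_scores["accgyro"], test_scores[m], test_labels)
        for m in METHODS
        if m != "accgyro"
    }

    # permutation null: destroy the label-feature link within subject and
    # verify the pipeline scores at chance
    null_table = tables[METHODS[0]]
    null_train = null_table[null_table["subject_id"].isin(train_ids)].reset_index(drop=True)
    null_aucs = []
    for i in range(n_null_permutations):
        permuted = permute_labels_within_subject(null_train, seed=null_seed + i)
        feats = select_top_k_mutual_info(permuted, top_k, seed=mi_seed)
        cv = nested_cv(
            permuted[meta + feats], null_algorithm, grids[null_algorithm], seed=fit_seed
        )
        null_aucs.append(cv.mean_auc())
    permuted_null = float(np.mean(null_aucs))

    return StudyResult(
        n_subjects=n_subjects,
        seed=seed,
        train_subjects=train_ids,
        test_subjects=test_ids,
        selected_features=selected,
        cv_results=cv_results,
        final_models=models,
        test_metrics=test_metrics,
        delong_vs_accgyro=delong,
        permuted_null_auc=permuted_null,
        tables=tables if keep_tables else {},
    )
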