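import numpy as np
import pandas as pd
import pytest

from biovad.ml import (
    REDUCED_GRIDS,
    evaluate,
    final_model,
    nested_cv,
    permute_labels_within_subject,
    select_top_k_mutual_info,
    split_by_subject,
)


def toy_table(n_subjects=6, n_segments=40, seed=0, informative=True):
    """Small feature table with one informative and several noise features."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        labels = rng.permutation([1] * (n_segments // 2) + [0] * (n_segments // 2))
        for i, y in enumerate(labels):
            signal = (3.0 * y if informative else 0.0) + rng.normal()
            rows.append(
                {
                    "subject_id": f"S{s}",
                    "segment_idx": i,
                    "label": int(y),
                    "good": signal,
                    **{f"noise{j}": rng.normal() for j in range(5)},
                }
            )
    return pd.DataFrame(rows)


class TestSplitBySubject:
    def test_paper_sized_split(self):
        subjects = [f"P{i}" for i in range(44)]
        train, test = split_by_subject(subjects, test_fraction=10 / 44, seed=1)
        assert len(test) == 10
        assert len(train) == 34
        assert not set(train) & set(test)

    def test_deterministic(self):
        subjects = [f"P{i}" for i in range(20)]
        assert split_by_subject(subjects, seed=3) == split_by_subject(subjects, seed=3)

    def test_single_subject_raises(self):
        with pytest.raises(ValueError):
            split_by_subject(["only"], 0.2, 0)


class TestMutualInfoSelection:
    def test_label_copy_ranked_first(self):
        t = toy_table()
        t["oracle"] = t["label"].astype(float)
        assert select_top_k_mutual_info(t, k=1, seed=0) == ["oracle"]

    def test_informative_feature_selected(self):
        t = toy_table()
        assert "good" in select_top_k_mutual_info(t, k=2, seed=0)

    def test_k_of_21_thorax_features(self, small_tables):
        selected = select_top_k_mutual_info(small_tables["rip1"], k=10, seed=0)
        assert len(selected) == 10
        # the generator's informative respiratory contrasts should surface
        assert {"mean_ie", "sd_te"} & set(selected)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError):
            select_top_k_mutual_info(toy_table(), k=100)


class TestEvaluate:
    def test_perfect_scores(self):
        m = evaluate([1.0, 1.0, 0.0], [1, 1, 0])
        assert all(v == 100.0 for v in m.values())

    def test_uninformative_ties(self):
        m = evaluate([0.5] * 4, [1, 1, 0, 0])
        assert m["auc"] == 50.0
        assert m["sensitivity"] == 100.0  # >= 0.5 predicts speech
        assert m["specificity"] == 0.0

    def test_hand_ranked_case(self):
        m = evaluate([0.9, 0.6, 0.4, 0.1], [1, 1, 0, 0])
        assert m["auc"] == 100.0
        assert m["accuracy"] == 100.0


class TestNestedCV:
    def test_one_loop_per_subject_and_no_leakage(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", REDUCED_GRIDS["logistic_regression"], seed=0)
        assert res.n_loops == 6
        for held_out, train_set in zip(res.loops["subject_id"], res.train_subject_sets):
            assert held_out not in train_set
            assert len(train_set) == 5

    def test_separable_data_high_auc(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", REDUCED_GRIDS["logistic_regression"], seed=0)
        assert res.mean_auc() > 90.0

    def test_permuted_labels_chance_level(self):
        t = permute_labels_within_subject(toy_table(n_subjects=8, n_segments=60), seed=1)
        t["good"] = np.random.default_rng(2).normal(size=len(t))  # no signal left
        res = nested_cv(t, "logistic_regression", REDUCED_GRIDS["logistic_regression"], seed=0)
        assert abs(res.mean_auc() - 50.0) < 10.0

    def test_needs_three_subjects(self):
        t = toy_table(n_subjects=2)
        with pytest.raises(ValueError):
            nested_cv(t, "logistic_regression", REDUCED_GRIDS["logistic_regression"])

    def test_empty_grid_raises(self):
        with pytest.raises(ValueError):
            nested_cv(toy_table(), "logistic_regression", {})


class TestFinalModel:
    def test_mode_hyperparameters(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", {"clf__C": [0.1, 1.0]}, seed=0)
        # inject a known params column to pin the mode rule
        res.loops["params"] = [{"clf__C": 0.1}] * 4 + [{"clf__C": 1.0}] * 2
        bundle = final_model(t, "logistic_regression", res, seed=0)
        assert bundle.params == {"clf__C": 0.1}

    def test_mode_tie_breaks_to_regularized(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", {"clf__C": [0.1, 1.0]}, seed=0)
        res.loops["params"] = [{"clf__C": 0.1}] * 3 + [{"clf__C": 1.0}] * 3
        bundle = final_model(t, "logistic_regression", res, seed=0)
        assert bundle.params == {"clf__C": 0.1}

    def test_algorithm_mismatch_raises(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", {"clf__C": [1.0]}, seed=0)
        with pytest.raises(ValueError):
            final_model(t, "gradient_boosting", res)

    def test_separable_test_predictions(self):
        t = toy_table(n_subjects=8)
        train_ids, test_ids = split_by_subject(sorted(t["subject_id"].unique()), 0.25, 0)
        train = t[t["subject_id"].isin(train_ids)]
        test = t[t["subject_id"].isin(test_ids)]
        res = nested_cv(train, "logistic_regression", {"clf__C": [1.0]}, seed=0)
        bundle = final_model(train, "logistic_regression", res, seed=0)
        m = evaluate(bundle.predict_proba(test), test["label"].to_numpy())
        assert set(m) == {"auc", "accuracy", "sensitivity", "specificity"}
        assert m["auc"] > 90.0

    def test_save_load_roundtrip(self, tmp_path):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", {"clf__C": [1.0]}, seed=0)
        bundle = final_model(t, "logistic_regression", res, seed=0)
        p = tmp_path / "model.joblib"
        bundle.save(p)
        from biovad.ml import ModelBundle

        back = ModelBundle.load(p)
        assert back.algorithm == bundle.algorithm
        assert back.feature_names == bundle.feature_names
        assert np.allclose(back.predict_proba(t), bundle.predict_proba(t))

    def test_feature_importances_named(self):
        t = toy_table()
        res = nested_cv(t, "logistic_regression", {"clf__C": [1.0]}, seed=0)
        bundle = final_model(t, "logistic_regression", res, seed=0)
        imp = bundle.feature_importances
        assert imp.idxmax() == "good"
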