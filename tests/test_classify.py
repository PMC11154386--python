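"""Classifier specs, LOSOCV mechanics, and the evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from painlab.classify import (
    ClassifierSpec,
    compute_metrics,
    default_spec,
    fit_fold,
    fit_predict,
    losocv,
)
from painlab.core import CLASS_LABELS, InputError


def blob_table(
    n_subjects=6,
    rows_per_class=6,
    n_features=4,
    separation=6.0,
    seed=0,
    shuffle_labels=False,
):
    """Subject-structured Gaussian blobs, one centroid per class."""
    rng = np.random.default_rng(seed)
    centroids = {
        lab: separation * rng.normal(size=n_features) for lab in CLASS_LABELS
    }
    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:02d}"
        for lab in CLASS_LABELS:
            for _ in range(rows_per_class):
                x = centroids[lab] + rng.normal(size=n_features)
                rows.append(
                    {"subject": sid, "class": lab,
                     **{f"f{i}": x[i] for i in range(n_features)}}
                )
    df = pd.DataFrame(rows)
    if shuffle_labels:
        df["class"] = rng.permutation(df["class"].to_numpy())
    return df


class TestMetrics:
    def test_perfect_diagonal(self):
        m = compute_metrics(np.diag([12, 12, 12]))
        for v in m.values():
            assert v == pytest.approx(100.0)

    def test_hand_computed_example(self):
        conf = np.array([[10, 2, 0], [0, 12, 0], [0, 0, 12]])
        m = compute_metrics(conf)
        assert m["accuracy"] == pytest.approx(100 * 34 / 36)
        assert m["sensitivity"] == pytest.approx(100 * (10 / 12 + 1 + 1) / 3)
        assert m["specificity"] == pytest.approx(100 * (1 + 22 / 24 + 1) / 3)
        # F1: B 20/22, LP 24/26, HP 1
        assert m["f1"] == pytest.approx(100 * (20 / 22 + 24 / 26 + 1) / 3)

    def test_uniform_confusion_is_chance(self):
        m = compute_metrics(np.full((3, 3), 5))
        assert m["accuracy"] == pytest.approx(100 / 3)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            compute_metrics(np.zeros((3, 3)))

    def test_absent_class_excluded_from_macro_not_zero(self):
        conf = np.array([[10, 0, 0], [0, 10, 0], [0, 0, 0]])
        m = compute_metrics(conf)
        assert m["sensitivity"] == pytest.approx(100.0)  # mean over 2 classes


class TestFitPredict:
    def test_knn_one_neighbor_recovers_training_row(self):
        table = blob_table(n_subjects=2)
        spec = ClassifierSpec("knn", {"n_neighbors": 1, "distance": "euclidean",
                                      "weights": "equal"})
        preds = fit_predict(table, table.iloc[[0]], spec)
        assert preds[0] == table.iloc[0]["class"]

    def test_svm_separable_blobs_zero_training_error(self):
        table = blob_table(separation=10.0, seed=3)
        spec = default_spec("svm", "fused")
        preds = fit_predict(table, table, spec)
        assert (preds == table["class"].to_numpy()).all()

    def test_discriminant_families_fit_separable_data(self):
        table = blob_table(separation=10.0, seed=4)
        for mode in ("hbo2", "hhb", "fused"):
            spec = default_spec("discriminant", mode)
            preds = fit_predict(table, table, spec)
            assert (preds == table["class"].to_numpy()).mean() > 0.95

    def test_empty_test_set_gives_empty_predictions(self):
        table = blob_table(n_subjects=2)
        spec = default_spec("svm", "fused")
        assert len(fit_predict(table, table.iloc[0:0], spec)) == 0

    def test_feature_column_mismatch_rejected(self):
        table = blob_table(n_subjects=2)
        other = table.rename(columns={"f0": "g0"})
        with pytest.raises(InputError, match="mismatch"):
            fit_predict(table, other, default_spec("svm", "fused"))

    def test_oversized_knn_clamped_with_warning(self):
        table = blob_table(n_subjects=2, rows_per_class=3)
        spec = ClassifierSpec(
            "knn", {"n_neighbors": 500, "distance": "euclidean", "weights": "equal"}
        )
        with pytest.warns(UserWarning, match="clamping"):
            preds = fit_predict(table, table.iloc[[0]], spec)
        assert len(preds) == 1


class TestLosocv:
    def test_fold_count_and_pooled_mass(self):
        table = blob_table(n_subjects=5, rows_per_class=4)
        report = losocv(table, default_spec("svm", "fused"))
        assert len(report.folds) == 5
        held_out = [f.held_out_subject for f in report.folds]
        assert sorted(held_out) == sorted(set(table["subject"]))
        assert report.pooled_confusion.sum() == len(table)
        for fold in report.folds:
            n_rows = (table["subject"] == fold.held_out_subject).sum()
            assert fold.confusion.sum() == n_rows

    def test_training_rows_never_include_held_out_subject(self):
        table = blob_table(n_subjects=4)
        report = losocv(table, default_spec("discriminant", "fused"))
        for fold in report.folds:
            assert fold.held_out_subject not in fold.train_subjects
            assert len(fold.train_subjects) == 3

    def test_no_leakage_fitted_state_ignores_test_rows(self):
        """Mutating the held-out subject's rows leaves the fold's fitted
        scaler and MRMR selection untouched."""
        table_a = blob_table(n_subjects=4, n_features=6)
        table_b = table_a.copy()
        mask = table_b["subject"] == "S01"
        feat_cols = [c for c in table_b.columns if c.startswith("f")]
        table_b.loc[mask, feat_cols] = 999.0

        est_a, cols_a, _ = fit_fold(
            table_a, "S01", default_spec("svm", "fused"), k_features=3
        )
        est_b, cols_b, _ = fit_fold(
            table_b, "S01", default_spec("svm", "fused"), k_features=3
        )
        assert cols_a == cols_b
        np.testing.assert_array_equal(
            est_a.named_steps["scale"].mean_, est_b.named_steps["scale"].mean_
        )
        np.testing.assert_array_equal(
            est_a.named_steps["scale"].scale_, est_b.named_steps["scale"].scale_
        )

    def test_separable_blobs_high_accuracy_shuffled_near_chance(self):
        table = blob_table(n_subjects=6, rows_per_class=6, separation=8.0)
        report = losocv(table, default_spec("svm", "fused"))
        assert report.mean["accuracy"] > 90.0

        accs = []
        for s in range(5):
            shuffled = blob_table(
                n_subjects=6, rows_per_class=6, separation=8.0,
                seed=50 + s, shuffle_labels=True,
            )
            accs.append(losocv(shuffled, default_spec("svm", "fused")).mean["accuracy"])
        assert abs(np.mean(accs) - 100 / 3) < 15.0

    def test_global_vs_per_fold_ranking_modes(self):
        table = blob_table(n_subjects=4, n_features=6)
        for mode in ("per_fold", "global"):
            report = losocv(
                table, default_spec("svm", "fused"), k_features=3, ranking_mode=mode
            )
            assert all(len(f.selected_features) == 3 for f in report.folds)

    def test_missing_class_warns_but_proceeds(self):
        table = blob_table(n_subjects=3)
        table = table[~((table["subject"] == "S01") & (table["class"] == "HP"))]
        with pytest.warns(UserWarning, match="missing classes"):
            report = losocv(table, default_spec("discriminant", "fused"))
        assert len(report.folds) == 3

    def test_single_subject_rejected(self):
        table = blob_table(n_subjects=1)
        with pytest.raises(InputError):
            losocv(table, default_spec("svm", "fused"))
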