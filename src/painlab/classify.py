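"""Classifier specs, leave-one-subject-out cross-validation, and metrics.

Three classifier families are supported with fixed, pre-tuned default
hyperparameters per measure mode (the values a Bayesian search selected
on the original cohort): discriminant analysis with gamma/delta
regularisation, k-nearest neighbours, and support vector machines.
Evaluation is leave-one-subject-out (LOSOCV): every subject's epochs form
one held-out test fold; standardisation statistics and, in per-fold mode,
the MRMR ranking are fitted on the training subjects only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import pinvh
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import CLASS_LABELS, InputError
from .mrmr import mrmr_rank, select_top_k

__all__ = [
    "ClassifierSpec",
    "default_spec",
    "CVReport",
    "FoldResult",
    "compute_metrics",
    "fit_predict",
    "fit_fold",
    "losocv",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameter map."""

    family: str  # discriminant | knn | svm
    hyperparameters: dict = field(default_factory=dict)


# Pre-tuned hyperparameters per (family, measure mode).
_DEFAULTS: dict[tuple[str, str], dict] = {
    ("discriminant", "hbo2"): {
        "discriminant_type": "pseudo_linear",
        "gamma": 7.55e-4,
        "delta": 3.51e-5,
    },
    ("discriminant", "hhb"): {
        "discriminant_type": "linear",
        "gamma": 0.0025,
        "delta": 2.96e-5,
    },
    ("discriminant", "fused"): {
        "discriminant_type": "diag_linear",
        "gamma": 0.006,
        "delta": 2.12e-5,
    },
    ("knn", "hbo2"): {
        "n_neighbors": 211,
        "distance": "chebyshev",
        "weights": "inverse",
    },
    ("knn", "hhb"): {"n_neighbors": 1, "distance": "cosine", "weights": "inverse"},
    ("knn", "fused"): {
        "n_neighbors": 25,
        "distance": "cityblock",
        "weights": "equal",
    },
    ("svm", "hbo2"): {
        "coding": "one_vs_all",
        "kernel": "polynomial",
        "polynomial_order": 3,
        "box_constraint": 2.1888,
    },
    ("svm", "hhb"): {
        "coding": "one_vs_all",
        "kernel": "polynomial",
        "polynomial_order": 3,
        "box_constraint": 10.3923,
    },
    ("svm", "fused"): {
        "coding": "one_vs_one",
        "kernel": "gaussian",
        "box_constraint": 980.4894,
        "kernel_scale": 13.2018,
    },
}


def default_spec(family: str, mode: str) -> ClassifierSpec:
    """Pre-tuned spec for a classifier family and measure mode."""
    key = (family, mode)
    if key not in _DEFAULTS:
        raise InputError(f"no default hyperparameters for family={family!r}, mode={mode!r}")
    return ClassifierSpec(family=family, hyperparameters=dict(_DEFAULTS[key]))


class RegularisedDiscriminant(BaseEstimator, ClassifierMixin):
    """Linear discriminant with pooled covariance and gamma/delta
    regularisation.

    ``gamma`` blends the pooled covariance toward its diagonal,
    ``delta`` zeroes small linear coefficients. ``diag_linear`` uses the
    diagonal only; ``pseudo_linear`` inverts via the pseudo-inverse.
    """

    def __init__(
        self,
        discriminant_type: str = "linear",
        gamma: float = 0.0,
        delta: float = 0.0,
    ):
        self.discriminant_type = discriminant_type
        self.gamma = gamma
        self.delta = delta

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        n, p = X.shape
        k = self.classes_.size
        self.means_ = np.vstack([X[y_idx == c].mean(axis=0) for c in range(k)])
        self.priors_ = np.bincount(y_idx, minlength=k) / n
        resid = X - self.means_[y_idx]
        cov = (resid.T @ resid) / max(n - k, 1)
        if self.discriminant_type == "diag_linear":
            cov = np.diag(np.diag(cov))
        elif self.gamma > 0:
            cov = (1 - self.gamma) * cov + self.gamma * np.diag(np.diag(cov))
        # Keep the problem well-posed for degenerate pooled covariances.
        cov = cov + 1e-12 * np.eye(p)
        if self.discriminant_type == "pseudo_linear":
            cov_inv = pinvh(cov)
        else:
            try:
                cov_inv = np.linalg.inv(cov)
            except np.linalg.LinAlgError:
                cov_inv = pinvh(cov)
        self.coef_ = self.means_ @ cov_inv  # (k, p)
        if self.delta > 0:
            self.coef_[np.abs(self.coef_) <= self.delta] = 0.0
        self.intercept_ = (
            -0.5 * np.einsum("ij,ij->i", self.coef_, self.means_)
            + np.log(np.maximum(self.priors_, 1e-300))
        )
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_.T + self.intercept_

    def predict(self, X):
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]


def _build_estimator(spec: ClassifierSpec, n_train: int):
    hp = spec.hyperparameters
    if spec.family == "discriminant":
        clf = RegularisedDiscriminant(
            discriminant_type=hp.get("discriminant_type", "linear"),
            gamma=hp.get("gamma", 0.0),
            delta=hp.get("delta", 0.0),
        )
    elif spec.family == "knn":
        k = int(hp.get("n_neighbors", 5))
        if k > n_train:
            warnings.warn(
                f"n_neighbors={k} exceeds training size {n_train}; clamping",
                stacklevel=2,
            )
            k = n_train
        metric = {
            "chebyshev": "chebyshev",
            "cosine": "cosine",
            "cityblock": "manhattan",
            "euclidean": "euclidean",
        }[hp.get("distance", "euclidean")]
        weights = {"inverse": "distance", "equal": "uniform"}[
            hp.get("weights", "equal")
        ]
        clf = KNeighborsClassifier(n_neighbors=k, metric=metric, weights=weights)
    elif spec.family == "svm":
        kernel = hp.get("kernel", "gaussian")
        c = float(hp.get("box_constraint", 1.0))
        if kernel == "gaussian":
            scale = float(hp.get("kernel_scale", 1.0))
            svc = SVC(C=c, kernel="rbf", gamma=1.0 / scale**2)
        elif kernel == "polynomial":
            svc = SVC(
                C=c,
                kernel="poly",
                degree=int(hp.get("polynomial_order", 3)),
                gamma="scale",
                coef0=1.0,
            )
        else:
            raise InputError(f"unknown svm kernel {kernel!r}")
        if hp.get("coding", "one_vs_one") == "one_vs_all":
            clf = OneVsRestClassifier(svc)
        else:
            clf = svc
    else:
        raise InputError(f"unknown classifier family {spec.family!r}")

    standardise = hp.get("standardise", True)
    if standardise:
        return Pipeline([("scale", StandardScaler()), ("clf", clf)])
    return Pipeline([("clf", clf)])


def _split_xy(table: pd.DataFrame, feature_cols: list[str]):
    return table[feature_cols].to_numpy(dtype=np.float64), table["class"].to_numpy()


def _feature_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("subject", "class")]


def fit_predict(
    train_rows: pd.DataFrame, test_rows: pd.DataFrame, spec: ClassifierSpec
) -> np.ndarray:
    """Fit on the training rows, predict the test rows.

    Standardisation statistics come from the training rows only.
    Deterministic: no configured family uses random initialisation.
    """
    cols = _feature_cols(train_rows)
    test_cols = _feature_cols(test_rows)
    if cols != test_cols:
        raise InputError(
            f"feature column mismatch between train {cols} and test {test_cols}"
        )
    X_tr, y_tr = _split_xy(train_rows, cols)
    est = _build_estimator(spec, len(train_rows))
    est.fit(X_tr, y_tr)
    if len(test_rows) == 0:
        return np.array([], dtype=y_tr.dtype)
    X_te, _ = _split_xy(test_rows, cols)
    return est.predict(X_te)


def compute_metrics(confusion: np.ndarray) -> dict[str, float]:
    """Accuracy and macro one-vs-rest sensitivity/specificity/F1, in percent.

    ``confusion[i, j]`` counts true class i predicted as class j (class
    order as in the report). Per-class metrics undefined for a class with
    no true (or no negative) instances are excluded from the macro mean.
    """
    c = np.asarray(confusion, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise InputError("confusion matrix must be square")
    if np.any(c < 0):
        raise InputError("confusion matrix entries must be non-negative")
    total = c.sum()
    if total == 0:
        raise InputError("confusion matrix is all zero")
    acc = np.trace(c) / total
    sens, spec, f1 = [], [], []
    for i in range(c.shape[0]):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens.append(tp / (tp + fn) if tp + fn > 0 else np.nan)
        spec.append(tn / (tn + fp) if tn + fp > 0 else np.nan)
        f1.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return {
            "accuracy": 100 * acc,
            "sensitivity": 100 * np.nanmean(sens),
            "specificity": 100 * np.nanmean(spec),
            "f1": 100 * np.nanmean(f1),
        }


@dataclass
class FoldResult:
    held_out_subject: str
    confusion: np.ndarray  # 3x3, rows = true class in CLASS_LABELS order
    metrics: dict[str, float]
    selected_features: list[str]
    train_subjects: list[str]


@dataclass
class CVReport:
    folds: list[FoldResult]
    class_labels: tuple[str, ...]
    mean: dict[str, float]
    std: dict[str, float]

    @property
    def pooled_confusion(self) -> np.ndarray:
        return np.sum([f.confusion for f in self.folds], axis=0)

    def summary(self) -> str:
        parts = [
            f"{k.capitalize()}: {self.mean[k]:.2f} ± {self.std[k]:.2f}%"
            for k in ("accuracy", "sensitivity", "specificity", "f1")
        ]
        return "; ".join(parts)


def _confusion(y_true, y_pred, labels) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(labels)}
    c = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        c[index[t], index[p]] += 1
    return c


def fit_fold(
    table: pd.DataFrame,
    held_out: str,
    spec: ClassifierSpec,
    k_features: int | None = None,
    ranking_mode: str = "per_fold",
    global_ranking: list[str] | None = None,
    n_bins: int = 10,
):
    """Fit one LOSOCV fold; returns (estimator, selected feature columns,
    training subject list). All fitted state depends only on the training
    rows — the held-out subject's data never enters fitting."""
    train = table[table["subject"] != held_out]
    if train.empty:
        raise InputError(f"no training rows when holding out {held_out!r}")
    cols = _feature_cols(table)
    if k_features is not None:
        if ranking_mode == "per_fold":
            ranking = mrmr_rank(train, n_bins=n_bins, feature_columns=cols)
            cols = select_top_k(ranking, k_features)
        elif ranking_mode == "global":
            if global_ranking is None:
                raise InputError("global ranking_mode requires a precomputed ranking")
            cols = global_ranking[:k_features]
        else:
            raise InputError(f"unknown ranking_mode {ranking_mode!r}")
    X_tr, y_tr = _split_xy(train, cols)
    est = _build_estimator(spec, len(train))
    est.fit(X_tr, y_tr)
    train_subjects = list(dict.fromkeys(train["subject"]))
    return est, cols, train_subjects


def losocv(
    table: pd.DataFrame,
    spec: ClassifierSpec,
    k_features: int | None = None,
    ranking_mode: str = "per_fold",
    n_bins: int = 10,
    class_labels: tuple[str, ...] = CLASS_LABELS,
) -> CVReport:
    """Leave-one-subject-out cross-validation.

    Each subject is held out exactly once; standardisation and (in
    per-fold mode) the MRMR ranking are refitted on the remaining
    subjects. Metrics are aggregated as mean ± sample std across folds.
    """
    subjects = list(dict.fromkeys(table["subject"]))
    if len(subjects) < 2:
        raise InputError("losocv requires at least 2 subjects")
    for sid in subjects:
        present = set(table.loc[table["subject"] == sid, "class"])
        if not set(class_labels) <= present:
            warnings.warn(
                f"subject {sid} is missing classes "
                f"{sorted(set(class_labels) - present)}; fold proceeds",
                stacklevel=2,
            )

    global_ranking = None
    if k_features is not None and ranking_mode == "global":
        ranking = mrmr_rank(table, n_bins=n_bins, feature_columns=_feature_cols(table))
        global_ranking = ranking.ordered_features

    folds: list[FoldResult] = []
    for sid in subjects:
        est, cols, train_subjects = fit_fold(
            table, sid, spec, k_features, ranking_mode, global_ranking, n_bins
        )
        test = table[table["subject"] == sid]
        X_te, y_te = _split_xy(test, cols)
        y_pred = est.predict(X_te)
        conf = _confusion(y_te, y_pred, class_labels)
        folds.append(
            FoldResult(
                held_out_subject=sid,
                confusion=conf,
                metrics=compute_metrics(conf),
                selected_features=list(cols),
                train_subjects=train_subjects,
            )
        )

    keys = ("accuracy", "sensitivity", "specificity", "f1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = {
            k: float(np.nanmean([f.metrics[k] for f in folds])) for k in keys
        }
        std = {
            k: float(np.nanstd([f.metrics[k] for f in folds], ddof=1)) for k in keys
        }
    return CVReport(folds=folds, class_labels=class_labels, mean=mean, std=std)
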