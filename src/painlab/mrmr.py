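"""Minimum Redundancy Maximum Relevance (MRMR) feature ranking.

Greedy forward selection under the difference (MID) scheme: the first
feature maximises mutual information with the class; each subsequent
feature maximises

    relevance(f) - mean_{s in selected} MI(f, s)

Continuous features are quantile-discretised (default 10 bins) before the
plug-in mutual-information estimate. Ties break by input column order, so
the ranking is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError

__all__ = [
    "RankingResult",
    "mutual_information",
    "discretise",
    "mrmr_rank",
    "select_top_k",
]


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information (nats) of two discrete sequences.

    Estimated from the joint empirical distribution; symmetric,
    non-negative, zero when the empirical table factorises.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("mutual_information requires two equal-length 1-D sequences")
    if x.size < 2:
        raise InputError("mutual_information requires >= 2 samples")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx = xi.max() + 1
    ny = yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    n = joint.sum()
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def discretise(column: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Quantile binning into at most ``n_bins`` bins (duplicated quantile
    edges collapse, so low-cardinality columns get fewer bins)."""
    col = np.asarray(column, dtype=np.float64)
    edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(col, edges)


@dataclass
class RankingResult:
    ordered_features: list[str]
    scores: dict[str, float]  # MRMR score at selection time
    relevance: dict[str, float]  # MI with the class, nats
    redundancy: dict[str, float]  # mean MI with already-selected, at selection


def mrmr_rank(
    table: pd.DataFrame,
    n_bins: int = 10,
    label_column: str = "class",
    feature_columns: list[str] | None = None,
) -> RankingResult:
    """Rank all feature columns of a table by greedy MID MRMR."""
    if label_column not in table.columns:
        raise InputError(f"table has no label column {label_column!r}")
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in (label_column, "subject")
        ]
    if len(feature_columns) < 1:
        raise InputError("mrmr_rank requires at least one feature column")

    y = table[label_column].to_numpy()
    disc = {f: discretise(table[f].to_numpy(), n_bins) for f in feature_columns}
    relevance = {f: mutual_information(disc[f], y) for f in feature_columns}

    selected: list[str] = []
    scores: dict[str, float] = {}
    redundancy: dict[str, float] = {}
    remaining = list(feature_columns)
    pair_mi: dict[tuple[str, str], float] = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information(disc[a], disc[b])
        return pair_mi[key]

    while remaining:
        best = None
        best_score = -np.inf
        best_red = 0.0
        for f in remaining:  # input order; strict > keeps the earliest on ties
            red = (
                float(np.mean([mi_pair(f, s) for s in selected])) if selected else 0.0
            )
            score = relevance[f] - red
            if score > best_score:
                best, best_score, best_red = f, score, red
        assert best is not None
        selected.append(best)
        scores[best] = best_score
        redundancy[best] = best_red
        remaining.remove(best)

    return RankingResult(selected, scores, relevance, redundancy)


def select_top_k(ranking: RankingResult, k: int) -> list[str]:
    """First ``k`` feature names of the ranking."""
    n = len(ranking.ordered_features)
    if not 1 <= k <= n:
        raise InputError(f"k must lie in 1..{n}, got {k}")
    return ranking.ordered_features[:k]
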