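"""Feature-level statistical comparison across the three pain classes.

Per feature: Kolmogorov–Smirnov normality screening, one-way ANOVA across
Baseline / Low Pain / High Pain, and Bonferroni-adjusted post hoc pairwise
comparisons using the pooled ANOVA mean square error. Homogeneity of
variance is reported (a Levene-type ANOVA on absolute deviations from
group means) but never gates the analysis.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _st

from .core import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "ks_normality",
    "one_way_anova",
    "levene_homogeneity",
    "bonferroni_posthoc",
    "feature_class_screen",
]


@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    mse: float  # within-group mean square
    ss_between: float
    ss_within: float


def ks_normality(x: np.ndarray) -> tuple[float, float]:
    """One-sample KS statistic of x against a normal with x's estimated
    mean and (sample) sd, with the asymptotic p-value (no Lilliefors
    correction)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < 5:
        raise InputError("ks_normality requires at least 5 values")
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise InputError("ks_normality: zero variance input")
    res = _st.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(res.statistic), float(res.pvalue)


def _as_groups(groups: list[np.ndarray]) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(gs) < 2:
        raise InputError("need at least 2 groups")
    for i, g in enumerate(gs):
        if g.ndim != 1 or g.size < 2:
            raise InputError(f"group {i} must be 1-D with at least 2 values")
    return gs


def one_way_anova(
    groups: list[np.ndarray], labels: list[str] | None = None
) -> AnovaResult:
    """Classical between/within decomposition.

    F = (SSB / df_between) / (SSW / df_within) with df = (k-1, N-k);
    p from the F distribution.
    """
    gs = _as_groups(groups)
    if labels is None:
        labels = [f"g{i}" for i in range(len(gs))]
    ns = np.array([g.size for g in gs])
    means = np.array([g.mean() for g in gs])
    grand = np.concatenate(gs).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(np.sum((g - m) ** 2) for g, m in zip(gs, means)))
    df_b = len(gs) - 1
    df_w = int(ns.sum()) - len(gs)
    mse = ssw / df_w
    F = (ssb / df_b) / mse if mse > 0 else (np.inf if ssb > 0 else 0.0)
    p = float(_st.f.sf(F, df_b, df_w)) if np.isfinite(F) else 0.0
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means=dict(zip(labels, means.tolist())),
        mse=mse,
        ss_between=ssb,
        ss_within=ssw,
    )


def levene_homogeneity(groups: list[np.ndarray]) -> AnovaResult:
    """Levene-type homogeneity check: ANOVA on absolute deviations from
    each group's mean. Reported only; never gates the analysis."""
    gs = _as_groups(groups)
    return one_way_anova([np.abs(g - g.mean()) for g in gs])


def bonferroni_posthoc(
    groups: list[np.ndarray],
    labels: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise comparisons with Bonferroni adjustment.

    Uses the pooled ANOVA MSE: std error = sqrt(MSE (1/n_a + 1/n_b)),
    raw p from the t distribution on the within df, adjusted
    p = min(1, m * p_raw) with m the number of unordered pairs.
    Both Bonferroni-adjusted and unadjusted confidence bounds are
    reported; rows come in both orders, as in standard post hoc tables.
    """
    gs = _as_groups(groups)
    if len(labels) != len(gs) or len(set(labels)) != len(labels):
        raise InputError("labels must be unique and match the number of groups")
    res = one_way_anova(gs, list(labels))
    m = len(gs) * (len(gs) - 1) // 2
    rows = []
    for (i, a), (j, b) in itertools.permutations(enumerate(labels), 2):
        diff = float(gs[i].mean() - gs[j].mean())
        se = float(np.sqrt(res.mse * (1 / gs[i].size + 1 / gs[j].size)))
        if se > 0:
            t = diff / se
            p_raw = float(2 * _st.t.sf(abs(t), res.df_within))
        else:
            p_raw = 1.0 if diff == 0 else 0.0
        p_adj = min(1.0, m * p_raw)
        crit_adj = float(_st.t.ppf(1 - alpha / (2 * m), res.df_within))
        crit_raw = float(_st.t.ppf(1 - alpha / 2, res.df_within))
        rows.append(
            {
                "group_one": a,
                "group_two": b,
                "mean_diff": diff,
                "std_error": se,
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "ci_lower": diff - crit_adj * se,
                "ci_upper": diff + crit_adj * se,
                "ci_lower_unadjusted": diff - crit_raw * se,
                "ci_upper_unadjusted": diff + crit_raw * se,
                "significant": p_adj <= alpha,
            }
        )
    return pd.DataFrame(rows)


def feature_class_screen(
    table: pd.DataFrame,
    alpha: float = 0.05,
    label_column: str = "class",
) -> dict[str, dict]:
    """ANOVA + Bonferroni post hoc for every feature column of the table.

    Rows with undefined (NaN) values for a feature are screened out for
    that feature only, with the count logged. Returns, per feature:
    ``anova``, ``posthoc`` (DataFrame), ``levene``, and ``n_dropped``.
    """
    if table.empty:
        return {}
    feature_cols = [c for c in table.columns if c not in (label_column, "subject")]
    labels = [c for c in dict.fromkeys(table[label_column])]
    out: dict[str, dict] = {}
    for feat in feature_cols:
        sub = table[[label_column, feat]]
        n_dropped = int(sub[feat].isna().sum())
        if n_dropped:
            logger.info("feature %s: dropped %d undefined rows", feat, n_dropped)
            sub = sub.dropna()
        groups = [
            sub.loc[sub[label_column] == lab, feat].to_numpy() for lab in labels
        ]
        if any(g.size < 2 for g in groups):
            logger.warning("feature %s: a class has < 2 defined rows; skipped", feat)
            continue
        anova = one_way_anova(groups, labels)
        posthoc = bonferroni_posthoc(groups, labels, alpha)
        out[feat] = {
            "anova": anova,
            "posthoc": posthoc,
            "levene": levene_homogeneity(groups),
            "n_dropped": n_dropped,
        }
    return out


def posthoc_table(screen: dict[str, dict]) -> pd.DataFrame:
    """Flatten a feature screen into one post hoc table with a ``*``
    significance marker column."""
    frames = []
    for feat, res in screen.items():
        df = res["posthoc"].copy()
        df.insert(0, "feature", feat)
        df["sig_marker"] = np.where(df["significant"], "*", "")
        frames.append(df)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
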