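"""Ten statistical features per epoch and per haemoglobin measure.

For an epoch h (length n) with unscaled first difference h' (length n-1):

    F1  log energy              sum_i log(h_i^2)          (natural log, floored)
    F2  crest factor            h_peak / h_rms
    F3  shape factor            h_rms / h_am
    F4  impulse factor          h_peak / h_am
    F5  margin factor           h_peak / h_am^2
    F6  mobility                sqrt(var(h') / var(h))
    F7  complexity              mobility(h') / mobility(h)
    F8  MAD of first derivative mean |h'_i - mean(h')|
    F9  range                   max(h) - min(h)
    F10 variation of derivative mean (h'_i - mean(h'))^2

where h_peak = max |h_i|, h_rms is the root mean square, h_am the absolute
mean, and var(.) the population variance. Derivative statistics are
normalised by the derivative's own length (n - 1). Features from the two
measures are fused by concatenation into one 20-element named row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EpochSet, InputError

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "extract_feature_vector",
    "fuse_features",
    "build_feature_table",
    "feature_columns",
]

FEATURE_NAMES = (
    "log_energy",
    "crest_factor",
    "shape_factor",
    "impulse_factor",
    "margin_factor",
    "mobility",
    "complexity",
    "mad_first_derivative",
    "range",
    "variation_first_derivative",
)

# Floor for h_i^2 inside the log-energy sum, guarding against -inf on
# exactly-zero samples.
LOG_ENERGY_FLOOR = 1e-300


@dataclass
class FeatureVector:
    """One epoch's ten features plus provenance for fusion pairing."""

    values: dict[str, float]
    subject_id: str = ""
    class_label: str = ""
    condition: str = ""
    onset_s: float = float("nan")
    undefined: tuple[str, ...] = field(default_factory=tuple)

    @property
    def ok(self) -> bool:
        return not self.undefined


def extract_feature_vector(
    epoch: np.ndarray,
    subject_id: str = "",
    class_label: str = "",
    condition: str = "",
    onset_s: float = float("nan"),
) -> FeatureVector:
    """Compute the ten features for one epoch.

    Degenerate epochs do not raise: features whose denominators vanish
    (constant epoch for mobility/complexity, zero absolute mean for the
    amplitude ratios) are set to NaN and listed in ``undefined`` so the
    caller can drop the row with a logged reason.
    """
    h = np.asarray(epoch, dtype=np.float64)
    if h.ndim != 1 or h.size < 3:
        raise InputError("extract_feature_vector requires a 1-D epoch of length >= 3")
    n = h.size
    d = np.diff(h)
    dd = np.diff(d)

    h2 = h * h
    n_floored = int(np.count_nonzero(h2 < LOG_ENERGY_FLOOR))
    if n_floored:
        logger.debug("log_energy: floored %d near-zero samples", n_floored)
    f1 = float(np.sum(np.log(np.maximum(h2, LOG_ENERGY_FLOOR))))

    h_peak = float(np.max(np.abs(h)))
    h_rms = float(math.sqrt(np.mean(h2)))
    h_am = float(np.mean(np.abs(h)))
    var_h = float(np.var(h))
    var_d = float(np.var(d))
    var_dd = float(np.var(dd)) if dd.size else 0.0
    d_bar = float(np.mean(d))

    undefined: list[str] = []
    nan = float("nan")

    f2 = h_peak / h_rms if h_rms > 0 else nan
    if h_rms == 0:
        undefined.append("crest_factor")
    if h_am > 0:
        f3 = h_rms / h_am
        f4 = h_peak / h_am
        f5 = h_peak / h_am**2
    else:
        f3 = f4 = f5 = nan
        undefined += ["shape_factor", "impulse_factor", "margin_factor"]

    if var_h > 0:
        f6 = math.sqrt(var_d / var_h)
    else:
        f6 = nan
        undefined.append("mobility")
    if var_h > 0 and var_d > 0:
        f7 = math.sqrt(var_dd / var_d) / math.sqrt(var_d / var_h)
    else:
        f7 = nan
        undefined.append("complexity")

    f8 = float(np.mean(np.abs(d - d_bar)))
    f9 = float(np.ptp(h))
    f10 = float(np.mean((d - d_bar) ** 2))

    values = dict(
        zip(FEATURE_NAMES, (f1, f2, f3, f4, f5, f6, f7, f8, f9, f10))
    )
    return FeatureVector(
        values=values,
        subject_id=subject_id,
        class_label=class_label,
        condition=condition,
        onset_s=onset_s,
        undefined=tuple(undefined),
    )


def fuse_features(hbo2: FeatureVector, hhb: FeatureVector) -> dict[str, float]:
    """Concatenate the two measures' features into one 20-value named row,
    ΔHBO2 first (``_hbo2`` suffix) then ΔHHB (``_hhb``)."""
    if hbo2 is None or hhb is None:
        raise InputError("fuse_features requires both measure vectors")
    same_window = (
        hbo2.subject_id == hhb.subject_id
        and (
            (math.isnan(hbo2.onset_s) and math.isnan(hhb.onset_s))
            or hbo2.onset_s == hhb.onset_s
        )
    )
    if not same_window:
        raise InputError(
            f"fuse_features: mismatched pairing "
            f"({hbo2.subject_id}@{hbo2.onset_s}s vs {hhb.subject_id}@{hhb.onset_s}s)"
        )
    row = {f"{k}_hbo2": v for k, v in hbo2.values.items()}
    row.update({f"{k}_hhb": v for k, v in hhb.values.items()})
    return row


def feature_columns(mode: str) -> list[str]:
    """Ordered feature column names for a given measure mode."""
    if mode == "fused":
        return [f"{k}_hbo2" for k in FEATURE_NAMES] + [
            f"{k}_hhb" for k in FEATURE_NAMES
        ]
    if mode in ("hbo2", "hhb"):
        return list(FEATURE_NAMES)
    raise InputError(f"mode must be hbo2, hhb or fused, got {mode!r}")


def _check_alignment(a: EpochSet, b: EpochSet) -> None:
    if len(a) != len(b):
        raise InputError(
            f"epoch sets are misaligned: {len(a)} vs {len(b)} epochs"
        )
    bad = [
        (i, (x.subject_id, x.onset_s, x.class_label), (y.subject_id, y.onset_s, y.class_label))
        for i, (x, y) in enumerate(zip(a.epochs, b.epochs))
        if (x.subject_id, x.onset_s, x.class_label)
        != (y.subject_id, y.onset_s, y.class_label)
    ]
    if bad:
        raise InputError(f"epoch sets are misaligned at windows: {bad[:5]}")


def build_feature_table(
    epochs_hbo2: EpochSet | None,
    epochs_hhb: EpochSet | None,
    mode: str = "fused",
) -> pd.DataFrame:
    """One row per epoch: subject, class, and the named feature values.

    Rows with undefined features (degenerate epochs) are dropped, with the
    count logged. In fused mode the two epoch sets must be aligned window
    for window.
    """
    cols = feature_columns(mode)
    header = ["subject", "class"] + cols

    if mode == "fused":
        if epochs_hbo2 is None or epochs_hhb is None:
            raise InputError("fused mode requires both epoch sets")
        _check_alignment(epochs_hbo2, epochs_hhb)
        rows: list[dict] = []
        n_dropped = 0
        for ea, eb in zip(epochs_hbo2.epochs, epochs_hhb.epochs):
            va = extract_feature_vector(
                ea.series, ea.subject_id, ea.class_label, ea.condition, ea.onset_s
            )
            vb = extract_feature_vector(
                eb.series, eb.subject_id, eb.class_label, eb.condition, eb.onset_s
            )
            if not (va.ok and vb.ok):
                n_dropped += 1
                logger.warning(
                    "dropping epoch %s@%ss: undefined features %s",
                    ea.subject_id,
                    ea.onset_s,
                    va.undefined + vb.undefined,
                )
                continue
            row = {"subject": ea.subject_id, "class": ea.class_label}
            row.update(fuse_features(va, vb))
            rows.append(row)
    else:
        epochs = epochs_hbo2 if mode == "hbo2" else epochs_hhb
        if epochs is None:
            raise InputError(f"mode {mode!r} requires the corresponding epoch set")
        rows = []
        n_dropped = 0
        for ep in epochs.epochs:
            v = extract_feature_vector(
                ep.series, ep.subject_id, ep.class_label, ep.condition, ep.onset_s
            )
            if not v.ok:
                n_dropped += 1
                logger.warning(
                    "dropping epoch %s@%ss: undefined features %s",
                    ep.subject_id,
                    ep.onset_s,
                    v.undefined,
                )
                continue
            row = {"subject": ep.subject_id, "class": ep.class_label}
            row.update(v.values)
            rows.append(row)

    if n_dropped:
        logger.info("build_feature_table: dropped %d degenerate epochs", n_dropped)
    return pd.DataFrame(rows, columns=header)
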