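"""Filtering, re-referencing, averaging, and epoching of retained channels.

Each retained channel passes through a 4th-order Butterworth low-pass at
0.16 Hz (zero-phase by default), suppressing cardiac and respiratory
pulsation. Common average referencing (CAR) subtracts the cross-channel
mean at every sample to remove systemic noise shared by all channels.
The channels are then averaged into a single time series per measure,
which is segmented into labelled 10 s epochs (Baseline / Low Pain / High
Pain), with six extra rest-period windows added per subject to balance
the baseline class at 12 observations per class.

Note on operation order: applying CAR to a channel set and then averaging
those same channels yields the zero sequence identically. The default
pipeline therefore averages the filtered (non-CAR) channels for the
epoch path and applies CAR only in the per-channel topography path; the
literal filter→CAR→average composition remains available via
``strict_paper_order`` for documentation and testing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .core import (
    ConfigError,
    Epoch,
    EpochSet,
    Event,
    InputError,
    Recording,
    condition_to_class,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "lowpass_filter",
    "common_average_reference",
    "average_channels",
    "preprocess_to_series",
    "segment_epochs",
    "balance_baseline",
    "condition_topography",
    "cohort_topography",
]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth low-pass specification."""

    order: int = 4
    cutoff: float = 0.16  # Hz
    phase_mode: str = "zero_phase"  # zero_phase | causal

    def validate(self, sampling_rate: float) -> None:
        if self.order < 1:
            raise ConfigError("FilterSpec.order must be >= 1")
        if not 0 < self.cutoff < sampling_rate / 2:
            raise ConfigError(
                f"FilterSpec.cutoff must lie in (0, Nyquist={sampling_rate / 2} Hz), "
                f"got {self.cutoff}"
            )
        if self.phase_mode not in ("zero_phase", "causal"):
            raise ConfigError("FilterSpec.phase_mode must be zero_phase or causal")


def lowpass_filter(
    channel: np.ndarray, spec: FilterSpec, sampling_rate: float
) -> np.ndarray:
    """Apply the Butterworth low-pass along the last axis.

    Zero-phase mode runs the filter forward and backward (no phase
    distortion, squared magnitude response) with reflective padding;
    causal mode is a single forward pass.
    """
    spec.validate(sampling_rate)
    x = np.asarray(channel, dtype=np.float64)
    if x.shape[-1] <= 3 * spec.order:
        raise InputError("channel too short for the requested filter order")
    sos = _signal.butter(
        spec.order, spec.cutoff, btype="low", fs=sampling_rate, output="sos"
    )
    if spec.phase_mode == "zero_phase":
        return _signal.sosfiltfilt(sos, x, axis=-1)
    return _signal.sosfilt(sos, x, axis=-1)


def common_average_reference(channels: np.ndarray) -> np.ndarray:
    """Subtract the cross-channel mean at every sample (CAR).

    The output's cross-channel mean is zero at every sample.
    """
    mat = np.asarray(channels, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
        raise InputError("common_average_reference requires a non-empty 2-D matrix")
    return mat - mat.mean(axis=0, keepdims=True)


def average_channels(channels: np.ndarray) -> np.ndarray:
    """Sample-wise mean across channels: h_avg(k) = (1/M) sum_j H(k, j)."""
    mat = np.asarray(channels, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
        raise InputError("average_channels requires a non-empty 2-D matrix")
    return mat.mean(axis=0)


def preprocess_to_series(
    recording: Recording,
    retained: list[int],
    spec: FilterSpec = FilterSpec(),
    strict_paper_order: bool = False,
) -> np.ndarray:
    """Filter the retained channels and reduce them to one time series.

    With ``strict_paper_order`` the filtered channels are CAR-referenced
    before averaging, which is identically zero — kept only to document
    that composition.
    """
    if not retained:
        raise InputError(f"no retained channels for subject {recording.subject_id}")
    filtered = lowpass_filter(
        recording.data[np.asarray(retained, dtype=int)], spec, recording.sampling_rate
    )
    if strict_paper_order:
        filtered = common_average_reference(filtered)
    return average_channels(filtered)


def _epoch_from(
    series: np.ndarray,
    fs: float,
    onset_s: float,
    n_ep: int,
    condition: str,
    subject_id: str,
) -> Epoch | None:
    start = int(round(onset_s * fs))
    if start < 0 or start + n_ep > series.size:
        return None
    return Epoch(
        series=series[start : start + n_ep].copy(),
        class_label=condition_to_class(condition),
        condition=condition,
        subject_id=subject_id,
        onset_s=onset_s,
    )


def segment_epochs(
    series: np.ndarray,
    events: list[Event],
    sampling_rate: float,
    epoch_duration: float = 10.0,
    subject_id: str = "",
) -> EpochSet:
    """Cut the averaged series into labelled fixed-length epochs.

    One epoch per stimulus event; the baseline period is split into
    consecutive non-overlapping windows. Rest periods are not epoched
    here (see :func:`balance_baseline`). Windows extending past the end
    of the series are skipped with a warning.
    """
    series = np.asarray(series, dtype=np.float64)
    n_ep = int(round(epoch_duration * sampling_rate))
    out = EpochSet(epoch_duration=epoch_duration, sampling_rate=sampling_rate)
    for ev in events:
        if ev.label == "baseline":
            n_windows = int(ev.duration_s // epoch_duration)
            for w in range(n_windows):
                ep = _epoch_from(
                    series,
                    sampling_rate,
                    ev.onset_s + w * epoch_duration,
                    n_ep,
                    "baseline",
                    subject_id,
                )
                if ep is None:
                    warnings.warn(
                        f"baseline window at {ev.onset_s + w * epoch_duration}s "
                        "extends past the recording; skipped",
                        stacklevel=2,
                    )
                else:
                    out.epochs.append(ep)
        elif ev.label == "stimulus":
            ep = _epoch_from(
                series, sampling_rate, ev.onset_s, n_ep, ev.condition, subject_id
            )
            if ep is None:
                warnings.warn(
                    f"stimulus event at {ev.onset_s}s extends past the recording; "
                    "skipped",
                    stacklevel=2,
                )
            else:
                out.epochs.append(ep)
    return out


def balance_baseline(
    epochset: EpochSet,
    events: list[Event],
    series: np.ndarray,
    n_add: int = 6,
) -> EpochSet:
    """Add ``n_add`` rest-period epochs per subject to the baseline class.

    Rest intervals are taken earliest-first; within each interval the
    window immediately prior to the next stimulation (the last
    ``epoch_duration`` seconds of the rest) is used, where the previous
    stimulus's haemodynamic tail has decayed.
    """
    series = np.asarray(series, dtype=np.float64)
    fs = epochset.sampling_rate
    n_ep = int(round(epochset.epoch_duration * fs))
    subject = next((ep.subject_id for ep in epochset.epochs), "")
    rests = sorted(
        (ev for ev in events if ev.label == "rest"), key=lambda ev: ev.onset_s
    )
    added: list[Epoch] = []
    for ev in rests:
        if len(added) == n_add:
            break
        if ev.duration_s < epochset.epoch_duration:
            continue
        onset = ev.onset_s + ev.duration_s - epochset.epoch_duration
        ep = _epoch_from(series, fs, onset, n_ep, "rest", subject)
        if ep is not None:
            added.append(ep)
    if len(added) < n_add:
        raise InputError(
            f"balance_baseline: subject {subject!r} has only {len(added)} usable "
            f"rest windows, {n_add} required"
        )
    out = EpochSet(
        epochs=list(epochset.epochs) + added,
        epoch_duration=epochset.epoch_duration,
        sampling_rate=fs,
    )
    return out


def condition_topography(
    filtered_channels: np.ndarray,
    events: list[Event],
    sampling_rate: float,
) -> dict[str, np.ndarray]:
    """Per-channel mean activation by condition, baseline-referenced.

    For every stimulation condition present in the events, returns the
    per-channel mean signal over that condition's windows minus the
    per-channel mean over the baseline period. Conditions without events
    are omitted.
    """
    mat = np.asarray(filtered_channels, dtype=np.float64)
    if mat.ndim != 2:
        raise InputError("condition_topography requires a 2-D channel matrix")
    fs = sampling_rate

    def window_mean(evs: list[Event]) -> np.ndarray | None:
        cols: list[np.ndarray] = []
        for ev in evs:
            a = int(round(ev.onset_s * fs))
            b = int(round((ev.onset_s + ev.duration_s) * fs))
            b = min(b, mat.shape[1])
            if a < b:
                cols.append(mat[:, a:b].mean(axis=1))
        if not cols:
            return None
        return np.mean(cols, axis=0)

    base = window_mean([ev for ev in events if ev.label == "baseline"])
    if base is None:
        base = np.zeros(mat.shape[0])
    out: dict[str, np.ndarray] = {}
    conditions = {ev.condition for ev in events if ev.label == "stimulus"}
    for cond in sorted(conditions):
        m = window_mean(
            [ev for ev in events if ev.label == "stimulus" and ev.condition == cond]
        )
        if m is not None:
            out[cond] = m - base
    return out


def cohort_topography(
    per_subject: list[tuple[dict[str, np.ndarray], list[int]]],
    n_channels: int,
) -> dict[str, np.ndarray]:
    """Average per-subject topographies across subjects.

    ``per_subject`` pairs each subject's condition map (over its retained
    channels, in retained order) with the retained channel indices. Each
    full-montage channel averages over the subjects that retained it;
    channels retained by no subject are NaN.
    """
    sums: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for cond_map, retained in per_subject:
        idx = np.asarray(retained, dtype=int)
        for cond, values in cond_map.items():
            if cond not in sums:
                sums[cond] = np.zeros(n_channels)
                counts[cond] = np.zeros(n_channels)
            sums[cond][idx] += values
            counts[cond][idx] += 1
    out: dict[str, np.ndarray] = {}
    for cond in sums:
        with np.errstate(invalid="ignore"):
            out[cond] = np.where(
                counts[cond] > 0, sums[cond] / np.maximum(counts[cond], 1), np.nan
            )
    return out
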