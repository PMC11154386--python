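"""Artifact-based channel rejection via the relative-range statistic.

A channel contaminated by motion spikes or square-wave artifacts has a
first difference whose range is large relative to the range of the raw
signal. The relative range

    RR = (max(x') - min(x')) / (max(x) - min(x)),   x'[i] = x[i+1] - x[i]

flags such channels: empirically, RR > 0.1 at 50 Hz indicates
contamination. Subjects losing more than 70% of their channels are
excluded from the analysis altogether.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import FlatChannelError, InputError, Recording

__all__ = [
    "ChannelRecord",
    "ChannelQCReport",
    "relative_range",
    "select_channels",
    "exclude_subjects",
]

#: RR threshold above which a channel is considered artifact-contaminated.
DEFAULT_RR_THRESHOLD = 0.1
#: Channel-removal fraction above which a subject is excluded.
DEFAULT_MAX_REMOVED_FRACTION = 0.70
#: Range below which a channel counts as flat (dead electrode), in µmol/L.
DEFAULT_FLAT_TOL = 1e-12


def relative_range(channel: np.ndarray, flat_tol: float = DEFAULT_FLAT_TOL) -> float:
    """Ratio of the range of the unscaled first difference to the range of
    the raw channel.

    Invariant to adding a constant and to multiplying by a nonzero
    constant. Raises :class:`FlatChannelError` for (near-)constant
    channels, whose ratio is undefined.
    """
    x = np.asarray(channel, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise InputError("relative_range requires a 1-D channel of length >= 3")
    denom = float(np.ptp(x))
    if denom <= flat_tol:
        raise FlatChannelError("channel range is (near) zero; treat as faulty")
    return float(np.ptp(np.diff(x))) / denom


@dataclass
class ChannelRecord:
    channel: int
    rr_value: float  # NaN for flat channels
    retained: bool
    reject_reason: str  # rr_exceeds_threshold | flat_channel | listed_faulty | none


@dataclass
class ChannelQCReport:
    subject_id: str
    channels: list[ChannelRecord] = field(default_factory=list)
    rr_threshold: float = DEFAULT_RR_THRESHOLD
    max_removed_fraction: float = DEFAULT_MAX_REMOVED_FRACTION

    @property
    def n_input_channels(self) -> int:
        return len(self.channels)

    @property
    def n_retained(self) -> int:
        return sum(c.retained for c in self.channels)

    @property
    def removed_fraction(self) -> float:
        n = self.n_input_channels
        return (n - self.n_retained) / n if n else 0.0

    @property
    def subject_excluded(self) -> bool:
        return self.removed_fraction > self.max_removed_fraction

    @property
    def retained_indices(self) -> list[int]:
        return [c.channel for c in self.channels if c.retained]

    @property
    def rejected_indices(self) -> list[int]:
        return [c.channel for c in self.channels if not c.retained]


def select_channels(
    recording: Recording,
    rr_threshold: float = DEFAULT_RR_THRESHOLD,
    faulty_list: tuple[int, ...] = (),
    flat_tol: float = DEFAULT_FLAT_TOL,
    max_removed_fraction: float = DEFAULT_MAX_REMOVED_FRACTION,
) -> ChannelQCReport:
    """Flag channels for rejection on the raw (unfiltered) recording.

    Rejection reasons, in precedence order: listed as faulty, flat
    (near-zero range), RR strictly exceeding ``rr_threshold``. The
    threshold rule is strict: RR exactly at the threshold is retained.
    The retained set is decided once per subject (conventionally on the
    ΔHBO2 recording) and applied to both measures, since optode integrity
    is a property of the channel, not of the measure.
    """
    if recording.n_channels == 0 or recording.n_samples == 0:
        raise InputError("select_channels: recording is empty")
    faulty = set(faulty_list)
    report = ChannelQCReport(
        subject_id=recording.subject_id,
        rr_threshold=rr_threshold,
        max_removed_fraction=max_removed_fraction,
    )
    for j in range(recording.n_channels):
        if j in faulty:
            try:
                rr = relative_range(recording.data[j], flat_tol)
            except FlatChannelError:
                rr = float("nan")
            report.channels.append(ChannelRecord(j, rr, False, "listed_faulty"))
            continue
        try:
            rr = relative_range(recording.data[j], flat_tol)
        except FlatChannelError:
            report.channels.append(
                ChannelRecord(j, float("nan"), False, "flat_channel")
            )
            continue
        if rr > rr_threshold:
            report.channels.append(ChannelRecord(j, rr, False, "rr_exceeds_threshold"))
        else:
            report.channels.append(ChannelRecord(j, rr, True, "none"))
    if report.n_retained == 0:
        warnings.warn(
            f"select_channels: all channels rejected for subject "
            f"{recording.subject_id}",
            stacklevel=2,
        )
    return report


def exclude_subjects(
    reports: list[ChannelQCReport],
    max_removed_fraction: float = DEFAULT_MAX_REMOVED_FRACTION,
) -> list[str]:
    """Subjects retained after the channel-loss rule, input order preserved.

    A subject is excluded only when the removed fraction strictly exceeds
    ``max_removed_fraction`` ("over 70%" is strict).
    """
    return [
        r.subject_id for r in reports if not r.removed_fraction > max_removed_fraction
    ]
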