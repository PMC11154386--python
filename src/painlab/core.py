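"""Shared domain types for the fNIRS pain-assessment pipeline.

The pipeline operates on per-subject, per-measure channel-by-sample
matrices of haemoglobin concentration changes (µmol/L) annotated with an
event stream (baseline / stimulus / rest blocks), and reduces them to
labelled 10 s epochs of a single averaged time series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class labels in canonical order: Baseline, Low Pain, High Pain.
CLASS_LABELS = ("B", "LP", "HP")

#: Stimulation conditions: Low/High intensity on Arm/Hand.
STIM_CONDITIONS = ("LA", "HA", "LH", "HH")
LOW_PAIN_CONDITIONS = ("LA", "LH")
HIGH_PAIN_CONDITIONS = ("HA", "HH")

MEASURES = ("HBO2", "HHB")


class ConfigError(ValueError):
    """A configuration value violates its invariant; names the field."""


class InputError(ValueError):
    """Invalid data passed to an operation."""


class FlatChannelError(ValueError):
    """A channel has (near-)zero range; its relative range is undefined."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; message carries the stage name."""


def condition_to_class(condition: str) -> str:
    """Map an event condition to its pain class (B / LP / HP)."""
    if condition in LOW_PAIN_CONDITIONS:
        return "LP"
    if condition in HIGH_PAIN_CONDITIONS:
        return "HP"
    if condition in ("baseline", "rest"):
        return "B"
    raise InputError(f"unknown condition: {condition!r}")


@dataclass(frozen=True)
class Event:
    """One protocol block: baseline, a stimulus repetition, or a rest."""

    label: str  # "baseline" | "stimulus" | "rest"
    condition: str  # "baseline" | "rest" | one of STIM_CONDITIONS
    onset_s: float
    duration_s: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "condition": self.condition,
            "onset_s": self.onset_s,
            "duration_s": self.duration_s,
        }


@dataclass
class Recording:
    """One measure's channel-by-sample matrix for one subject.

    ``data[j, k]`` is channel *j* at sample *k*, in µmol/L.
    """

    measure: str
    data: np.ndarray
    sampling_rate: float
    events: list[Event]
    subject_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise InputError("Recording.data must be a 2-D channel-by-sample matrix")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.measure not in MEASURES:
            raise ConfigError(f"measure must be one of {MEASURES}, got {self.measure!r}")
        end = self.n_samples / self.sampling_rate
        for ev in self.events:
            if ev.onset_s < 0 or ev.onset_s > end:
                raise InputError(
                    f"event {ev.label}/{ev.condition} at {ev.onset_s}s lies outside "
                    f"the {end}s recording"
                )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Epoch:
    """One labelled 10 s segment of the averaged time series."""

    series: np.ndarray
    class_label: str  # B | LP | HP
    condition: str  # baseline | rest | LA | HA | LH | HH
    subject_id: str
    onset_s: float


@dataclass
class EpochSet:
    """Labelled epochs of fixed duration for one measure."""

    epochs: list[Epoch] = field(default_factory=list)
    epoch_duration: float = 10.0
    sampling_rate: float = 50.0

    def __len__(self) -> int:
        return len(self.epochs)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASS_LABELS}
        for ep in self.epochs:
            counts[ep.class_label] += 1
        return counts

    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for ep in self.epochs:
            seen.setdefault(ep.subject_id, None)
        return list(seen)
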