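"""Synthetic fNIRS cohort generator.

Emulates the acquisition protocol the downstream analysis assumes: a 60 s
baseline, then counterbalanced blocks of four electrical-stimulation
conditions (low/high intensity on arm/hand), six 10 s stimulus repetitions
per condition each followed by a 40 s rest, recorded on 24 prefrontal
channels at 50 Hz for two haemoglobin measures (ΔHBO2, ΔHHB) in µmol/L.

The haemodynamic response is a double-gamma HRF convolved with the stimulus
boxcar, scaled per condition so that high-pain conditions respond more
strongly than low-pain ones and ΔHHB responses are smaller and inverted
relative to ΔHBO2. Physiological nuisance terms (cardiac ≈ 1 Hz,
respiratory ≈ 0.25 Hz, slow drift, white sensor noise) are added, and a
configurable subset of channels is contaminated with high-amplitude
spike/square-wave artifacts or left dead (flat), providing ground truth for
the channel-rejection stage.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .core import (
    ConfigError,
    Event,
    HIGH_PAIN_CONDITIONS,
    LOW_PAIN_CONDITIONS,
    Recording,
    STIM_CONDITIONS,
)

__all__ = [
    "ProtocolConfig",
    "HemodynamicModel",
    "ArtifactModel",
    "SubjectData",
    "Cohort",
    "build_events",
    "double_gamma_hrf",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Timing and geometry of the acquisition protocol."""

    n_subjects: int = 27
    sampling_rate: float = 50.0
    n_channels: int = 24
    baseline_duration: float = 60.0
    stimulus_duration: float = 10.0
    rest_duration: float = 40.0
    reps_per_condition: int = 6
    conditions: tuple[str, ...] = STIM_CONDITIONS
    counterbalance_seed: int = 0
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("baseline_duration", "stimulus_duration", "rest_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.reps_per_condition < 1:
            raise ConfigError("reps_per_condition must be >= 1")
        if self.n_channels < 2:
            raise ConfigError("n_channels must be >= 2")
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be > 0")
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if min(self.counterbalance_seed, self.rng_seed) < 0:
            raise ConfigError("rng_seed and counterbalance_seed must be >= 0")
        if len(set(self.conditions)) != len(self.conditions) or not self.conditions:
            raise ConfigError("conditions must be a non-empty list of unique labels")

    @property
    def total_duration(self) -> float:
        per_block = self.stimulus_duration + self.rest_duration
        return self.baseline_duration + (
            len(self.conditions) * self.reps_per_condition * per_block
        )


def _default_amplitudes() -> dict[str, tuple[float, float]]:
    # (ΔHBO2, ΔHHB) peak response in µmol/L; HA strongest, LA weakest,
    # ΔHHB inverted at -0.3x, matching the qualitative activation ordering.
    return {
        "LA": (0.3, -0.09),
        "LH": (0.4, -0.12),
        "HH": (0.8, -0.24),
        "HA": (1.0, -0.30),
    }


@dataclass(frozen=True)
class HemodynamicModel:
    """Response amplitudes, HRF shape, and nuisance-signal parameters.

    Amplitudes are µmol/L at the peak of the convolved response; the HRF is
    the standard double-gamma shape (6 s peak, 16 s undershoot, 1/6 ratio).
    """

    response_amplitude: dict[str, tuple[float, float]] = field(
        default_factory=_default_amplitudes
    )
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    cardiac_freq: float = 1.0
    cardiac_amplitude: float = 0.2
    respiratory_freq: float = 0.25
    respiratory_amplitude: float = 0.15
    drift_slope: float = 0.3  # µmol/L per minute, random sign per channel
    slow_wave_freq: float = 0.004  # Hz, slow vascular oscillation
    slow_wave_amplitude: float = 1.0  # µmol/L, per-channel spread applied
    white_noise_sd: float = 0.01
    channel_gain_spread: float = 0.2

    def validate(self, protocol: ProtocolConfig) -> None:
        nyquist = protocol.sampling_rate / 2
        for name in ("cardiac_freq", "respiratory_freq"):
            if not 0 < getattr(self, name) < nyquist:
                raise ConfigError(f"{name} must lie in (0, Nyquist)")
        if self.white_noise_sd < 0:
            raise ConfigError("white_noise_sd must be >= 0")
        for cond in protocol.conditions:
            if cond not in self.response_amplitude:
                raise ConfigError(f"response_amplitude missing condition {cond!r}")
        highs = [c for c in protocol.conditions if c in HIGH_PAIN_CONDITIONS]
        lows = [c for c in protocol.conditions if c in LOW_PAIN_CONDITIONS]
        for m in (0, 1):
            hi = [abs(self.response_amplitude[c][m]) for c in highs]
            lo = [abs(self.response_amplitude[c][m]) for c in lows]
            if not any(hi + lo):
                continue  # all-zero amplitudes: degenerate no-response config
            if hi and lo and min(hi) <= max(lo):
                raise ConfigError(
                    "response_amplitude: high-pain magnitudes must strictly "
                    f"exceed low-pain magnitudes (measure index {m})"
                )


@dataclass(frozen=True)
class ArtifactModel:
    """Contamination injected into a subset of channels."""

    artifact_channel_fraction: float = 0.125
    spike_amplitude: float = 10.0  # multiple of the clean channel range
    spike_rate: float = 5.0  # events per minute
    square_wave_duration: float = 2.0  # seconds
    faulty_channel_indices: tuple[int, ...] = (18, 22)  # dead optodes

    def validate(self, protocol: ProtocolConfig) -> None:
        if not 0 <= self.artifact_channel_fraction <= 1:
            raise ConfigError("artifact_channel_fraction must lie in [0, 1]")
        if self.spike_amplitude <= 0:
            raise ConfigError("spike_amplitude must be > 0")
        if self.spike_rate < 0:
            raise ConfigError("spike_rate must be >= 0")
        if self.square_wave_duration <= 0:
            raise ConfigError("square_wave_duration must be > 0")
        for idx in self.faulty_channel_indices:
            if not 0 <= idx < protocol.n_channels:
                raise ConfigError(
                    f"faulty_channel_indices: {idx} outside 0..{protocol.n_channels - 1}"
                )


@dataclass
class SubjectData:
    """Both measures for one subject plus generation ground truth."""

    subject_id: str
    hbo2: Recording
    hhb: Recording
    truth: dict


@dataclass
class Cohort:
    protocol: ProtocolConfig
    hemo: HemodynamicModel
    artifacts: ArtifactModel
    subjects: list[SubjectData]

    def __len__(self) -> int:
        return len(self.subjects)


def _subject_entropy(subject_id: str) -> int:
    # Stable across processes (unlike hash()).
    return zlib.crc32(subject_id.encode("utf-8"))


def build_events(
    protocol: ProtocolConfig, condition_order: tuple[str, ...] | None = None
) -> list[Event]:
    """Event stream for one subject: baseline, then per-condition blocks of
    (stimulus, rest) repetitions in the given (counterbalanced) order."""
    order = tuple(condition_order) if condition_order is not None else protocol.conditions
    if sorted(order) != sorted(protocol.conditions):
        raise ConfigError("condition_order must be a permutation of protocol.conditions")
    events = [Event("baseline", "baseline", 0.0, protocol.baseline_duration)]
    t = protocol.baseline_duration
    for cond in order:
        for _ in range(protocol.reps_per_condition):
            events.append(Event("stimulus", cond, t, protocol.stimulus_duration))
            t += protocol.stimulus_duration
            events.append(Event("rest", "rest", t, protocol.rest_duration))
            t += protocol.rest_duration
    return events


def double_gamma_hrf(
    sampling_rate: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma haemodynamic impulse response (unit dispersion)."""
    t = np.arange(0, length_s, 1.0 / sampling_rate)
    h = _gamma_dist.pdf(t, peak_delay) - undershoot_ratio * _gamma_dist.pdf(
        t, undershoot_delay
    )
    return h


def _neural_response(
    protocol: ProtocolConfig,
    hemo: HemodynamicModel,
    events: list[Event],
    n_samples: int,
    measure_index: int,
) -> np.ndarray:
    """HRF-convolved condition boxcars, peak-normalised then amplitude-scaled."""
    fs = protocol.sampling_rate
    hrf = double_gamma_hrf(
        fs, hemo.hrf_peak_delay, hemo.hrf_undershoot_delay, hemo.hrf_undershoot_ratio
    )
    stim_samples = int(round(protocol.stimulus_duration * fs))
    ref = np.convolve(np.ones(stim_samples), hrf)
    peak = ref.max()
    out = np.zeros(n_samples)
    for cond in protocol.conditions:
        amp = hemo.response_amplitude[cond][measure_index]
        if amp == 0:
            continue
        box = np.zeros(n_samples)
        for ev in events:
            if ev.label == "stimulus" and ev.condition == cond:
                a = int(round(ev.onset_s * fs))
                box[a : a + stim_samples] = 1.0
        resp = np.convolve(box, hrf)[:n_samples]
        if peak > 0:
            resp /= peak
        out += amp * resp
    return out


def generate_recording(
    protocol: ProtocolConfig,
    hemo: HemodynamicModel,
    art: ArtifactModel,
    subject_id: str,
) -> SubjectData:
    """Generate both measures for one subject, fully determined by
    (protocol.rng_seed, subject_id)."""
    protocol.validate()
    hemo.validate(protocol)
    art.validate(protocol)

    fs = protocol.sampling_rate
    entropy = _subject_entropy(subject_id)
    rng = np.random.default_rng(np.random.SeedSequence([protocol.rng_seed, entropy]))
    cb_rng = np.random.default_rng(
        np.random.SeedSequence([protocol.counterbalance_seed, entropy])
    )

    order = tuple(cb_rng.permutation(list(protocol.conditions)))
    events = build_events(protocol, order)
    n = int(round(protocol.total_duration * fs))
    t = np.arange(n) / fs
    n_ch = protocol.n_channels

    gains = 1.0 + hemo.channel_gain_spread * rng.uniform(-1, 1, size=n_ch)
    cardiac = hemo.cardiac_amplitude * np.sin(
        2 * np.pi * hemo.cardiac_freq * t + rng.uniform(0, 2 * np.pi)
    )
    resp = hemo.respiratory_amplitude * np.sin(
        2 * np.pi * hemo.respiratory_freq * t + rng.uniform(0, 2 * np.pi)
    )
    systemic = cardiac + resp

    faulty = tuple(sorted(art.faulty_channel_indices))
    candidates = [j for j in range(n_ch) if j not in faulty]
    n_artifact = int(round(art.artifact_channel_fraction * n_ch))
    n_artifact = min(n_artifact, len(candidates))
    artifact_channels = tuple(
        sorted(rng.choice(candidates, size=n_artifact, replace=False).tolist())
    )

    minutes = n / fs / 60.0
    n_spikes = max(1, int(round(art.spike_rate * minutes))) if n_artifact else 0
    # Shared artifact event times: a bad optode contaminates both measures.
    spike_times = {
        j: (rng.integers(0, n, size=n_spikes), rng.choice([-1.0, 1.0], size=n_spikes))
        for j in artifact_channels
    }
    sq_len = int(round(art.square_wave_duration * fs))
    square_onsets = {
        j: rng.integers(0, max(1, n - sq_len), size=2) for j in artifact_channels
    }

    recordings: dict[str, Recording] = {}
    for m_idx, measure in enumerate(("HBO2", "HHB")):
        neural = _neural_response(protocol, hemo, events, n, m_idx)
        # Drift magnitude is floored away from zero so every clean channel
        # carries a realistic slow component dominating its raw range.
        slopes = (
            hemo.drift_slope
            * rng.uniform(0.5, 1.5, size=n_ch)
            * rng.choice([-1.0, 1.0], size=n_ch)
        )
        slow_amps = hemo.slow_wave_amplitude * rng.uniform(0.5, 1.5, size=n_ch)
        slow_phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        data = np.empty((n_ch, n))
        white = rng.normal(0.0, hemo.white_noise_sd, size=(n_ch, n))
        t_min = t / 60.0
        for j in range(n_ch):
            slow = slow_amps[j] * np.sin(
                2 * np.pi * hemo.slow_wave_freq * t + slow_phases[j]
            )
            data[j] = (
                gains[j] * (neural + systemic)
                + slopes[j] * t_min
                + slow
                + white[j]
            )
        for j in faulty:
            data[j] = 0.0  # dead optode: flat line
        for j in artifact_channels:
            clean_range = float(np.ptp(data[j]))
            amp = art.spike_amplitude * clean_range
            idx, signs = spike_times[j]
            data[j, idx] += signs * amp
            for k, onset in enumerate(square_onsets[j]):
                sign = 1.0 if k % 2 == 0 else -1.0
                data[j, onset : onset + sq_len] += sign * amp
        recordings[measure] = Recording(
            measure=measure,
            data=data,
            sampling_rate=fs,
            events=events,
            subject_id=subject_id,
        )

    truth = {
        "artifact_channels": list(artifact_channels),
        "faulty_channels": list(faulty),
        "condition_order": list(order),
    }
    return SubjectData(subject_id, recordings["HBO2"], recordings["HHB"], truth)


def subject_ids(n_subjects: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n_subjects)]


def generate_cohort(
    protocol: ProtocolConfig, hemo: HemodynamicModel, art: ArtifactModel
) -> Cohort:
    """Generate ``protocol.n_subjects`` independent subjects."""
    protocol.validate()
    subjects = [
        generate_recording(protocol, hemo, art, sid)
        for sid in subject_ids(protocol.n_subjects)
    ]
    return Cohort(protocol, hemo, art, subjects)


def iter_cohort(
    protocol: ProtocolConfig, hemo: HemodynamicModel, art: ArtifactModel
):
    """Yield subjects one at a time (memory-friendly for large cohorts)."""
    protocol.validate()
    for sid in subject_ids(protocol.n_subjects):
        yield generate_recording(protocol, hemo, art, sid)
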