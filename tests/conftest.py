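"""Shared fixtures: reduced-scale synthetic cohorts for fast unit tests.

The reduced protocol keeps the 60 s baseline and 10 s stimuli but uses two
repetitions per condition and 20 s rests, so per-subject recordings are
300 s instead of 1260 s while every pipeline stage still has enough
events to operate (8 rest windows >= 6 needed for baseline balancing).
"""

from __future__ import annotations

import numpy as np
import pytest

from painlab.synth import (
    ArtifactModel,
    HemodynamicModel,
    ProtocolConfig,
    generate_cohort,
    generate_recording,
)


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    return ProtocolConfig(
        n_subjects=3,
        reps_per_condition=2,
        rest_duration=20.0,
        rng_seed=11,
        counterbalance_seed=12,
    )


@pytest.fixture(scope="session")
def quiet_hemo() -> HemodynamicModel:
    """No nuisance signals at all: pure condition responses."""
    return HemodynamicModel(
        cardiac_amplitude=0.0,
        respiratory_amplitude=0.0,
        drift_slope=0.0,
        slow_wave_amplitude=0.0,
        white_noise_sd=0.0,
        channel_gain_spread=0.0,
    )


@pytest.fixture(scope="session")
def no_artifacts() -> ArtifactModel:
    return ArtifactModel(
        artifact_channel_fraction=0.0, faulty_channel_indices=()
    )


@pytest.fixture(scope="session")
def small_cohort(small_protocol):
    return generate_cohort(small_protocol, HemodynamicModel(), ArtifactModel())


@pytest.fixture(scope="session")
def small_subject(small_protocol):
    return generate_recording(
        small_protocol, HemodynamicModel(), ArtifactModel(), "S01"
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
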