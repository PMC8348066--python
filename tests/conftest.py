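"""Shared fixtures: synthetic sessions and cohorts at the study conditions."""

from dataclasses import replace

import pytest
from hypothesis import settings

from stsfatigue.dataset_builder import BuildConfig, build_dataset
from stsfatigue.io_core import Participant
from stsfatigue.synthgen import SynthConfig, generate_cohort, generate_session

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def participant() -> Participant:
    return Participant(id="P000", age=22.0, sex="male", weight=68.0,
                       height=174.0)


@pytest.fixture(scope="session")
def noiseless_session(participant):
    """One fully deterministic session: no noise, no jitter, default effects."""
    config = SynthConfig(seed=5).noiseless()
    return generate_session(config, participant, seed=5)


@pytest.fixture(scope="session")
def noisy_session(participant):
    """One session at the default (noisy) study conditions."""
    return generate_session(SynthConfig(seed=7), participant, seed=7)


@pytest.fixture(scope="session")
def default_cohort():
    """The full 60-participant cohort at default study conditions."""
    return generate_cohort(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_dataset(default_cohort):
    return build_dataset([s for s, _ in default_cohort], BuildConfig())


@pytest.fixture(scope="session")
def clean_cohort():
    """20 participants with between-subject variability but no measurement
    noise: extraction should match generator ground truth tightly."""
    config = replace(
        SynthConfig(seed=13, n_participants=20),
        marker_noise_sd=0.0, hr_noise_sd=0.0, orientation_noise_deg=0.0,
    )
    return generate_cohort(config)
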