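"""Shared fixtures: geometry, stimulus, and one simulated block.

The simulated block is module-expensive (forward projection of two
entrained sources plus noise and artifacts over 80 s of 150-channel data),
so it is session-scoped and shared by the preprocessing and acceptance
tests.
"""

import pytest

from assrlab.cohort import ParticipantSpec, SourceParams
from assrlab.forward import HeadModel, SensorArray
from assrlab.simulate import simulate_block, ArtifactConfig
from assrlab.stimulus import StimulusSpec

FS = 1250.0


@pytest.fixture(scope="session")
def stim_spec():
    return StimulusSpec()


@pytest.fixture(scope="session")
def head():
    return HeadModel()


@pytest.fixture(scope="session")
def array():
    return SensorArray.ctf_like()


@pytest.fixture(scope="session")
def participant():
    """One young participant with a strong, known entrained source."""
    return ParticipantSpec(
        id="y000", group="young", age=25.0, pta_db=5.0,
        sin_loss_db=float("nan"), gaba={},
        sources={
            "quiet": SourceParams(7.0, 7.0, 48.0, 200.0,
                                  onset_transient=True),
            "noise": SourceParams(2.0, 2.0, 46.5, 240.0),
        })


@pytest.fixture(scope="session")
def noisy_block(participant, stim_spec, head, array):
    """An 80-s quiet block with blinks and cardiac artifacts injected."""
    return simulate_block(participant, "quiet", stim_spec, head, array,
                          block_id=0, n_trials=20, seed=3)


@pytest.fixture(scope="session")
def clean_block(participant, stim_spec, head, array):
    """Same block geometry without artifacts, with low sensor noise."""
    cfg = ArtifactConfig(blink_rate_hz=0.0, cardiac_rate_hz=0.0,
                         noise_floor_fT_sqrtHz=1.0, background_rms_nAm=1.0)
    return simulate_block(participant, "quiet", stim_spec, head, array,
                          block_id=0, n_trials=20, seed=3, artifacts=cfg)
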