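import numpy as np
import pytest

from eareog.montage import MontagePair
from eareog.pipeline import PipelineConfig, simulate_participant
from eareog.preprocess import bandpass_recording
from eareog.saccades import extract_epochs, label_epochs


@pytest.fixture(scope="session")
def noiseless_config() -> PipelineConfig:
    cfg = PipelineConfig(seed=123, participants=1, cycles=1)
    return cfg.model_copy(update={"synth": cfg.synth.noiseless()})


@pytest.fixture(scope="session")
def noiseless_saccade_run(noiseless_config):
    """One participant's noiseless saccade session: (schedule, band-passed
    recording, truth gaze, camera trace)."""
    pdata = simulate_participant(noiseless_config, 0, tasks=("saccade",))
    schedule, recording, truth, camera = pdata.saccade
    return schedule, bandpass_recording(recording), truth, camera


@pytest.fixture(scope="session")
def labelled_epochs(noiseless_saccade_run):
    schedule, filtered, _truth, _camera = noiseless_saccade_run
    epochs, skipped = extract_epochs(filtered, schedule, participant_id=0)
    assert skipped == 0
    return label_epochs(epochs)


@pytest.fixture(scope="session")
def best_pair() -> MontagePair:
    return MontagePair("L8", "R8", "horizontal")
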