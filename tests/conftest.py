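import numpy as np
import pytest

from spare_ppg.core import PipelineConfig
from spare_ppg.preprocess import bandpass
from spare_ppg.synthetic import generate_ppg

FS = 64.0


@pytest.fixture(scope="session")
def fixture_80bpm():
    """60 s constant-80-BPM three-harmonic fixture with ground truth."""
    signal, beats, true_hr = generate_ppg(60.0, FS, 80.0, seed=0)
    return signal, beats, true_hr


@pytest.fixture(scope="session")
def filtered_80bpm(fixture_80bpm):
    signal, beats, true_hr = fixture_80bpm
    return bandpass(signal), beats, true_hr


@pytest.fixture()
def config():
    return PipelineConfig()
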