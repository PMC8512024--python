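import numpy as np
import pytest

import sitsense as s
from sitsense import pipeline


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_config():
    """A fast 2-subject configuration for unit tests."""
    return s.SimulationConfig(
        durations_s={a: 20.0 for a in s.ACTIVITIES}, subject_count=2, seed=7
    )


@pytest.fixture(scope="session")
def small_recording(small_config):
    return s.generate_recording(small_config, subject_id=0)


@pytest.fixture(scope="session")
def small_windows(small_recording):
    return s.make_windows(small_recording, s.WindowSpec())


@pytest.fixture(scope="session")
def small_fm(small_windows):
    return s.extract_features(small_windows)


@pytest.fixture(scope="session")
def study_fm():
    """Feature matrix of the default study-scale synthetic dataset."""
    return pipeline.build_feature_matrix(s.PipelineConfig(seed=0))
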