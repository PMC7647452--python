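import numpy as np
import pytest

import catacrotic as cc
from catacrotic.pipeline import PipelineConfig, run_subject


@pytest.fixture(scope="session")
def clean_record():
    """Noise-free default-condition record with its ground truth."""
    return cc.simulate_record(noise=cc.NoiseParams.off(), seed=1)


@pytest.fixture(scope="session")
def default_study_results():
    """Fully processed default study (45 subjects, seed 0)."""
    study = cc.simulate_study(seed=0)
    config = PipelineConfig()
    return [run_subject(record, config) for record, _ in study]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
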