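import numpy as np
import pytest

from ecodec import features as feat_mod
from ecodec import synth
from ecodec.config import PipelineConfig


@pytest.fixture(scope="session")
def bank():
    """Default 15-band Morlet bank at the 586 Hz acquisition rate."""
    cfg = PipelineConfig()
    return feat_mod.WaveletBank.from_config(cfg.features,
                                            cfg.signal.sample_rate)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_session():
    """One 30-second synthetic session pair (297 blocks)."""
    cfg = synth.SynthConfig(session_minutes=0.5, seed=42)
    record, labels = synth.generate_session(cfg, 0)
    return cfg, record, labels
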