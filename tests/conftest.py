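import numpy as np
import pytest

from rtcn.preprocess import record_to_beats
from rtcn.synth import NoiseSpec, SynthSpec, generate_record


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_record():
    """10 s at 60 bpm, no jitter, noiseless: R peaks exactly 1000 samples apart."""
    spec = SynthSpec(duration_s=10, heart_rate_bpm=60, hr_jitter_frac=0.0,
                     noise=NoiseSpec(0, 0.3, 0, 50, 0), seed=11)
    return generate_record(spec)


@pytest.fixture(scope="session")
def noisy_record():
    spec = SynthSpec(duration_s=10, heart_rate_bpm=60, hr_jitter_frac=0.0, seed=11)
    return generate_record(spec)


@pytest.fixture(scope="session")
def sample_beats(clean_record):
    rec, _ = clean_record
    beats = record_to_beats(rec)
    assert beats
    return beats
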