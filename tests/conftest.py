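import numpy as np
import pytest

from sonecg import (CANONICAL_8, ECGRecord, FilterSpec, FMConfig,
                    SynthConfig, clip_amplitude, generate_record,
                    monitoring_filter, sonify)


@pytest.fixture(scope="session")
def sinus_record():
    """Clean-ish 10 s sinus-rhythm record with ground-truth fiducials."""
    return generate_record(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def conditioned_record(sinus_record):
    """Monitoring-filtered, amplitude-limited version of the sinus record."""
    return clip_amplitude(monitoring_filter(sinus_record, FilterSpec()), 2.5)


@pytest.fixture(scope="session")
def sonified(conditioned_record):
    return sonify(conditioned_record, FMConfig())


@pytest.fixture(scope="session")
def zero_record():
    return ECGRecord(np.zeros((8, 2500)), 250.0, CANONICAL_8)


@pytest.fixture(scope="session")
def zero_sonified(zero_record):
    return sonify(zero_record, FMConfig())
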