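import numpy as np
import pytest

from plaqueband import experiments
from plaqueband.pipeline import measure_section
from plaqueband.synthetic import generate_section


@pytest.fixture(scope="session")
def recovery_section():
    """Noise-free synthetic section plus its ground truth (shared)."""
    return experiments.recovery_section(seed=7)


@pytest.fixture(scope="session")
def recovery_measurements(recovery_section):
    """Full pipeline measurements of the noise-free section."""
    stack, _ = recovery_section
    return measure_section(stack, experiments.recovery_run_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
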