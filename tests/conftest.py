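import numpy as np
import pytest

from emgait import GaitSimParams, MLPConfig, StudyConfig, generate_subject


@pytest.fixture(scope="session")
def short_subject():
    """A 30 s synthetic subject: enough strides for all 10 slots."""
    return generate_subject(GaitSimParams(duration_s=30.0, seed=1), "S1")


@pytest.fixture(scope="session")
def short_dataset(short_subject, quick_cfg):
    from emgait.protocols import prepare_subject

    return prepare_subject(short_subject, quick_cfg)


@pytest.fixture(scope="session")
def quick_cfg():
    """Study config with a lightweight training budget for unit tests."""
    return StudyConfig(
        seed=1, mlp=MLPConfig(max_epochs=5, patience=2, seed=1)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
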