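import numpy as np
import pytest

from malprec.synthetic import GeneratorConfig, generate_windows
from malprec.windows import ProteinRecord


@pytest.fixture(scope="session")
def small_labeled_windows():
    """120 windows (60/side) with the default planted signal."""
    return generate_windows(GeneratorConfig(n_pos=60, n_neg=60, seed=101))


@pytest.fixture(scope="session")
def null_windows():
    """Exchangeable classes: effect_size 0."""
    return generate_windows(
        GeneratorConfig(n_pos=60, n_neg=60, effect_size=0.0, seed=102)
    )


@pytest.fixture()
def toy_protein():
    return ProteinRecord(id="p1", sequence="MKVAERAALEKLDANQEYKW")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
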