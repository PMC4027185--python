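import numpy as np
import pytest

from splicescreen import Pwm
from splicescreen import simulate as sim


@pytest.fixture
def toy_pwm():
    """Width-2 matrix whose best window is 'AT' with score 2."""
    return Pwm("toy", [[1, 0, 0, 0], [0, 0, 0, 1]], threshold_frac=0.9)


@pytest.fixture(scope="session")
def reference_models():
    """Donor + acceptor maxent models trained on the generator's strong corpora."""
    return sim.train_reference_models(seed=7)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
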