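import numpy as np
import pytest

from affinityscan import PWM, Background, SequenceRecord


@pytest.fixture
def uniform_pwm():
    return PWM(name="uniform", matrix=np.full((4, 3), 0.25))


@pytest.fixture
def bg_uniform():
    return Background()


@pytest.fixture
def bg_skewed():
    return Background(freqs=np.array([0.4, 0.15, 0.15, 0.3]))


@pytest.fixture
def strong_a_pwm():
    """l=1 PWM strongly preferring A (with small pseudocount-style leakage)."""
    col = np.array([[0.997], [0.001], [0.001], [0.001]])
    return PWM(name="strongA", matrix=col)


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_101)


def random_pwm(rng, l):
    m = rng.dirichlet(np.full(4, 0.8), size=l).T
    m = np.maximum(m, 1e-6)
    return PWM(name=f"rand_l{l}", matrix=m / m.sum(axis=0, keepdims=True))


def random_sequence(rng, L, seq_id="seq"):
    return SequenceRecord(id=seq_id, bases="".join(rng.choice(list("ACGT"), size=L)))
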