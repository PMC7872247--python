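import numpy as np
import pytest

from massdyn import (
    Model,
    Reaction,
    Species,
    make_linear_chain,
    make_toy_glycolysis,
)


@pytest.fixture
def ab_closed():
    """Closed A <=> B with kf = 1, Keq = 1 (eigenvalues {0, -2})."""
    return Model(
        "ab",
        [Species("A", x0=2.0), Species("B", x0=0.0)],
        [Reaction("r", {"A": 1}, {"B": 1}, kf=1.0, Keq=1.0)],
    )


@pytest.fixture
def ab_keq2():
    """Closed A <=> B with Keq = 2 and total mass 3 (equilibrium (1, 2))."""
    return Model(
        "ab2",
        [Species("A", x0=3.0), Species("B", x0=0.0)],
        [Reaction("r", {"A": 1}, {"B": 1}, kf=1.0, Keq=2.0)],
    )


@pytest.fixture
def decay_model():
    """Irreversible A -> B with kf = 1: A(t) = A0 exp(-t)."""
    return Model(
        "decay",
        [Species("A", x0=1.0), Species("B", x0=0.0)],
        [Reaction("r", {"A": 1}, {"B": 1}, kf=1.0, reversible=False)],
    )


@pytest.fixture(scope="session")
def chain3():
    return make_linear_chain(3, seed=7)


@pytest.fixture(scope="session")
def toy_gly():
    return make_toy_glycolysis(seed=0)


@pytest.fixture
def two_step_chain():
    """src -> a -> snk forcing v1 = v2 at steady state."""
    return Model(
        "c2",
        [
            Species("src", x0=1e-3, fixed=True),
            Species("a", x0=1e-3),
            Species("snk", x0=1e-3, fixed=True),
        ],
        [
            Reaction("r1", {"src": 1}, {"a": 1}, Keq=2.0),
            Reaction("r2", {"a": 1}, {"snk": 1}, Keq=2.0),
        ],
    )


def rand_positive_state(model, rng):
    return {s.id: float(v) for s, v in zip(model.species,
                                           rng.uniform(0.1, 3.0, len(model.species)))}


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
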