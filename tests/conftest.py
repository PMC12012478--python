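import numpy as np
import pytest

from otrna.elasticity import ElasticModel, trap_separation_for_force
from otrna.simulate import FoldingState, KineticScheme, Transition


@pytest.fixture(scope="session")
def model() -> ElasticModel:
    return ElasticModel()


@pytest.fixture(scope="session")
def two_state_scheme() -> KineticScheme:
    """Detailed-balance 15-nt hairpin used across modules."""
    return KineticScheme(
        states=[FoldingState("F", 0, 0.0), FoldingState("U", 15, 4.103)],
        transitions=[Transition("F", "U", 0.01327, 4.0, 1)],
        detailed_balance=True,
        name="two_state",
    )


@pytest.fixture(scope="session")
def two_state_separation(model, two_state_scheme) -> float:
    """Trap separation putting the folded state at ~11.55 pN (F1/2)."""
    return trap_separation_for_force(11.55, model, 0, 1)


@pytest.fixture(scope="session")
def three_state_scheme() -> KineticScheme:
    """Small detailed-balance ladder for occupancy/energy tests."""
    return KineticScheme(
        states=[
            FoldingState("F", 0, 0.0),
            FoldingState("I", 15, 8.0),
            FoldingState("U", 34, 14.0),
        ],
        transitions=[
            Transition("F", "I", 0.05, 2.0, 1),
            Transition("I", "U", 0.3, 2.0, 1),
        ],
        detailed_balance=True,
        name="three_state",
    )


def boltzmann_log_ratio(scheme, model, d, i, j) -> float:
    """ln(pi_j / pi_i) from the generator's total energies (oracle)."""
    _, g = scheme.total_energies(model, d)
    return float(-(g[j] - g[i]) / model.kT)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20250101)
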