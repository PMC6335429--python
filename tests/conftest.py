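import pytest

from scaffaudit import Simulation, SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim() -> Simulation:
    """One default-condition simulation shared across the suite."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def sim_telomeres() -> Simulation:
    """Simulation with telomeric repeat arrays planted at chromosome ends."""
    return simulate(SimulationConfig(seed=1, telomere_copies=50))
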