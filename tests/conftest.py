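import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def library():
    from tprtchar.elements import default_library

    return default_library()


@pytest.fixture(scope="session")
def fixture_set(library):
    from tprtchar.fixtures import build_fixture_set

    return build_fixture_set(library=library)


@pytest.fixture(scope="session")
def paper(fixture_set):
    """One full blind reproduction run shared across the suite."""
    from tprtchar.pipeline import run_paper_reproduction

    return run_paper_reproduction(fixtures=fixture_set)


@pytest.fixture(scope="session")
def sim_events(library):
    """200 noise-free simulated events with a fixed seed."""
    from tprtchar.simulator import SimulationConfig, simulate_dataset

    return simulate_dataset(200, SimulationConfig(seed=7), library=library)


@pytest.fixture(scope="session")
def sim_recovery(sim_events, library):
    """Blind characterization of the 200 simulated events."""
    from tprtchar.characterizer import characterize

    out = []
    for reference, mutant, truth in sim_events:
        call, cls = characterize(reference, mutant, library)
        out.append((reference, mutant, truth, call, cls))
    return out
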