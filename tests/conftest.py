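import pytest
from hypothesis import HealthCheck, settings

from oryzadiff import GeneModel, SimulationConfig, simulate_study

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_genes():
    """Five small non-overlapping genes on two chromosomes."""
    return [
        GeneModel("gA", 1000, "Chr1", 1001, 2000, "+", "gene A"),
        GeneModel("gB", 500, "Chr1", 3001, 3500, "-", "gene B"),
        GeneModel("gC", 2000, "Chr1", 5001, 7000, "+", "gene C"),
        GeneModel("gD", 800, "Chr2", 1001, 1800, "+", "gene D"),
        GeneModel("gE", 1200, "Chr2", 4001, 5200, "-", "gene E"),
    ]


@pytest.fixture
def overlapping_genes():
    """Two genes whose spans overlap (for the ambiguous-assignment rule)."""
    return [
        GeneModel("ovA", 1000, "Chr1", 1001, 2000, "+", ""),
        GeneModel("ovB", 1000, "Chr1", 1801, 2800, "+", ""),
    ]


@pytest.fixture(scope="session")
def small_study():
    """One scaled-down simulated study shared across read-only tests."""
    return simulate_study(SimulationConfig(n_genes=2000, n_regulated_up25=40, n_regulated_dn25=25, seed=7))
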