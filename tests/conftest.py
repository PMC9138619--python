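import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same design, fewer genes and shallower libraries."""
    from spheroseq.simulate import SimulationConfig

    return SimulationConfig(
        n_genes=4000,
        library_size=2_000_000,
        n_planted_de_per_pattern=4,
        n_cytokine_specific=20,
        marker_count_ranges={ct: (20, 40) for ct in ("NPC", "EXC", "IN", "AST", "OPC", "MG", "ENDO", "UNL")},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    from spheroseq.simulate import simulate_study

    return simulate_study(small_config)
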