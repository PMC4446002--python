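import pytest

from phregulon.synthetic import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Compact synthetic study reused across test modules."""
    cfg = SimulationConfig(
        n_genes=800,
        n_scaffolds=4,
        n_planted_genomic_clusters=4,
        seed=11,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def default_study():
    """Full-scale synthetic study at the design defaults (10k genes)."""
    return simulate_study(SimulationConfig(seed=101))
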