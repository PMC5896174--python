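import pytest

from glrscope.simulate import SimulationConfig, simulate


def small_config(**overrides) -> SimulationConfig:
    """Desk-sized generator settings shared across test modules."""
    base = dict(
        seed=11,
        n_chroms=2,
        chrom_length=2_000_000,
        n_genes=100,
        n_gfi1_peaks=300,
        n_extra_lsd1=600,
        n_extra_rcor1=200,
        n_lr_pairs=30,
        n_extra_enhancers=100,
        n_genic_marks=30,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated dataset reused by read-only tests."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def noise_free_sim():
    """Background-free tracks: window signal equals tent-kernel integrals."""
    return simulate(small_config(seed=12, background_depth=0.0))
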