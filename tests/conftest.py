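import numpy as np
import pytest

from bindexpr.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same structure as the default conditions."""
    return SimulationConfig(
        seed=11,
        n_chroms=2,
        chrom_length=5_000_000,
        n_genes=400,
        n_target_genes_up=40,
        n_target_genes_down=40,
        n_focal_peaks=200,
        n_partner_peaks=200,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config, include_signal=False)


@pytest.fixture(scope="session")
def signal_study():
    """Tiny study including both condition tracks."""
    cfg = SimulationConfig(
        seed=5,
        n_chroms=1,
        chrom_length=2_000_000,
        n_genes=100,
        n_target_genes_up=20,
        n_target_genes_down=20,
        n_focal_peaks=60,
        n_partner_peaks=60,
        baseline_step=500,
    )
    return simulate_study(cfg, include_signal=True)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
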