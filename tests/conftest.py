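import numpy as np
import pytest

from dissokit.synthetic_experiment import SimulationConfig, simulate_experiment


@pytest.fixture
def exact_config():
    """Noiseless, driftless, zero-aliquot power-law regime: the signal chain
    collapses to Beer's law and the fit must recover (K, n) exactly."""
    return SimulationConfig(
        model="power_law_capped", K=0.12, n=0.5,
        noise_sd=0.0, drift_slope=0.0, aliquot_volume=0.0, seed=1,
    )


@pytest.fixture
def bench_config():
    """Paper-default bench protocol with realistic noise and drift."""
    return SimulationConfig(seed=11)


@pytest.fixture
def bench_series(bench_config):
    series, _ = simulate_experiment(bench_config)
    return series


@pytest.fixture
def rng():
    return np.random.default_rng(20240329)
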