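import numpy as np
import pytest

from stemfill import Series, SimulationConfig, simulate_stem_moisture


@pytest.fixture
def short_series():
    """Tiny fully observed series for structural tests."""
    return Series(values=np.array([50.0, 51.0, 52.0, 51.5, 50.5, 49.5]))


@pytest.fixture
def diurnal_series():
    """A week of noisy diurnal signal (1008 points), seeded."""
    return simulate_stem_moisture(SimulationConfig(n_days=7, seed=11))


def pure_sinusoid(n_days=7, samples_per_day=144, base=50.0, amplitude=5.0, seed=0):
    """Noiseless, trend-free diurnal sinusoid."""
    return simulate_stem_moisture(
        SimulationConfig(
            n_days=n_days,
            samples_per_day=samples_per_day,
            base_level=base,
            diurnal_amplitude=amplitude,
            trend_amplitude=0.0,
            noise_sd=0.0,
            seed=seed,
        )
    )
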