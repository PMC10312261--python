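import numpy as np
import pytest

from spikenets.datatypes import SpikeData
from spikenets.synthetic import PlantedGraphConfig, generate_planted_graph


@pytest.fixture
def toy_spikes() -> SpikeData:
    """Four units in two regions over a 10 s window, hand-placed spikes."""
    return SpikeData(
        unit_ids=np.array(["a", "b", "c", "d"]),
        spike_times=[
            np.array([0.05, 0.15, 0.25]),
            np.array([0.5, 1.5, 2.5, 9.9]),
            np.array([]),
            np.arange(0.1, 10.0, 0.33),
        ],
        region_labels=np.array(["R1", "R1", "R2", "R2"]),
        window=(0.0, 10.0),
    )


@pytest.fixture(scope="session")
def planted_graph():
    """Three planted blocks of 20 with strong within-block structure."""
    return generate_planted_graph(PlantedGraphConfig(seed=42))


@pytest.fixture(scope="session")
def poisson_spikes() -> SpikeData:
    """Independent homogeneous Poisson units (no correlation structure)."""
    rng = np.random.default_rng(1234)
    duration = 120.0
    n_units = 24
    times = []
    for _ in range(n_units):
        n = rng.poisson(3.0 * duration)
        times.append(np.sort(rng.random(n) * duration))
    return SpikeData(
        unit_ids=np.arange(n_units),
        spike_times=times,
        region_labels=np.repeat([f"R{i}" for i in range(4)], 6),
        window=(0.0, duration),
    )
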