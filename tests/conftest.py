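import numpy as np
import pytest

from ccnn import simulate
from ccnn.datasets import ConnectomeDataset
from ccnn.models import ModelConfig


@pytest.fixture(scope="session")
def small_dataset():
    """30-ROI simulated dataset, 5 modified ROIs, mild noise."""
    pair = simulate.generate_base_pair(30, seed=7)
    spec = simulate.SimulationSpec(
        n_modified_rois=5, noise_weight=1.0, replicas_per_class=20, seed=7
    )
    return simulate.simulate_dataset(pair, spec)


@pytest.fixture(scope="session")
def separable_dataset():
    """Noise-free trivially separable toy: N=8, 10 instances per class."""
    n = 8
    rng = np.random.default_rng(3)
    base = np.eye(n)
    off = rng.uniform(-0.5, 0.5, size=(n, n))
    base = base + (off + off.T) / 2
    np.fill_diagonal(base, 1.0)
    other = base.copy()
    other[0, :] = other[:, 0] = 0.9
    other[0, 0] = 1.0
    data = np.empty((20, 1, n, n))
    for i in range(10):
        jitter = rng.normal(scale=0.01, size=(n, n))
        jitter = (jitter + jitter.T) / 2
        data[i, 0] = base + jitter
        jitter = rng.normal(scale=0.01, size=(n, n))
        jitter = (jitter + jitter.T) / 2
        data[10 + i, 0] = other + jitter
    return ConnectomeDataset(
        data=data,
        labels=[0] * 10 + [1] * 10,
        group_ids=list(range(20)),
        channel_names=["toy"],
    )


@pytest.fixture
def toy_config(separable_dataset):
    return ModelConfig(kind="ccnn", n_rois=8, seed=0, epochs=80)
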