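import numpy as np
import pytest

from fallwatch import fusion, sensor_sim


@pytest.fixture(scope="session")
def small_config():
    """A 20-event dataset: enough structure for fitting, fast to build."""
    return sensor_sim.SimConfig(n_events=20, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return sensor_sim.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_events(small_dataset):
    frames, _ = small_dataset
    return fusion.dataset_trajectories(frames)


@pytest.fixture(scope="session")
def noiseless_events():
    cfg = sensor_sim.SimConfig(n_events=20, seed=3).noiseless()
    frames, truths = sensor_sim.simulate_dataset(cfg)
    return fusion.dataset_trajectories(frames), truths


@pytest.fixture(scope="session")
def two_cluster_points():
    """Two well-separated 2D Gaussian clusters (separation 8 SD)."""
    rng = np.random.default_rng(42)
    a = rng.normal(loc=(0.0, 0.0), scale=1.0, size=(500, 2))
    b = rng.normal(loc=(8.0, 8.0), scale=1.0, size=(500, 2))
    return np.concatenate([a, b], axis=0)
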