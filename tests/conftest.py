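"""Shared fixtures and hypothesis configuration for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from seqrec import synthetic as syn  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_grid():
    """~110-voxel grid used throughout (20 mm spacing, 60 mm radius mask)."""
    return syn.make_grid((-60, 60, -60, 60, -60, 60), spacing=20.0)


@pytest.fixture(scope="session")
def desk_layout():
    return syn.make_channel_layout(n_mag=16, n_grad_pairs=8)


@pytest.fixture(scope="session")
def desk_leadfield(desk_grid, desk_layout):
    sites = syn.make_sensor_sites(16, radius=110.0)
    lf = syn.make_leadfield(desk_grid, sites, sigma=80.0)
    return syn.channel_leadfield(lf, desk_layout)


def make_continuous(data, sfreq, onsets=None, labels=()):
    """Minimal continuous SensorDataset around a (channels, samples) array."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    n = data.shape[0]
    return syn.SensorDataset(
        data=data,
        sfreq=float(sfreq),
        ch_names=tuple(f"CH{i}" for i in range(n)),
        ch_roles=("mag",) * n,
        grad_pairs=(),
        onsets=None if onsets is None else np.asarray(onsets, dtype=float),
        condition_labels=tuple(labels),
        is_epoched=False,
    )
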