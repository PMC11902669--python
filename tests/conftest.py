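import numpy as np
import pytest

from gridcellnet import (
    ArenaConfig,
    HeadDirectionEnsemble,
    PlaceCellEnsemble,
    generate_trajectory,
    trajectory_rng,
)


@pytest.fixture(scope="session")
def arena_cfg() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture(scope="session")
def trajectory_batch(arena_cfg):
    """1,000 default trajectories from one master seed (shared, read-only)."""
    return [
        generate_trajectory(arena_cfg, trajectory_rng(0, i)) for i in range(1000)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_place_ensemble():
    g = np.random.default_rng(7)
    centers = g.uniform(-3.2, 3.2, size=(32, 2))
    return PlaceCellEnsemble(centers, scale=0.35)


@pytest.fixture()
def small_hd_ensemble():
    g = np.random.default_rng(8)
    centers = np.pi - g.uniform(0, 2 * np.pi, size=8)
    return HeadDirectionEnsemble(centers, concentration=20.0)
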