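import numpy as np
import pytest

from poreflux.synthetic_electrolyte import SimulationConfig, SlabSpec
from poreflux.trajectory import IonTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def bulk_config():
    """Small blank-electrolyte run in the reference box."""
    return SimulationConfig(seed=42, n_steps=200, voltage=1.0)


@pytest.fixture
def pore_config():
    """Small five-layer-slab run with a 1.5 nm pore."""
    return SimulationConfig(
        seed=42,
        n_steps=200,
        voltage=1.0,
        slab=SlabSpec(pore_diameter=1.5, center_z=5.0),
    )


def random_trajectory(rng, n_frames=6, n_pairs=4, lz=10.0):
    """Random wrapped trajectory with charge-neutral +/-1 ions."""
    box = np.array([5.0, 5.0, lz])
    frames = rng.uniform(0.0, 1.0, size=(n_frames, 2 * n_pairs, 3)) * box
    charges = np.concatenate([np.ones(n_pairs), -np.ones(n_pairs)])
    return IonTrajectory(
        frames=frames,
        charges=charges,
        frame_spacing=1.0,
        box_lengths=box,
        species=["K"] * n_pairs + ["CL"] * n_pairs,
    )


@pytest.fixture
def make_trajectory(rng):
    def _make(**kwargs):
        return random_trajectory(rng, **kwargs)

    return _make
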