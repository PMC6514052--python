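import numpy as np
import pytest

from lbdkit.structio import AtomRecord, Frame, Topology, Trajectory
from lbdkit.synthetic import SyntheticSpec, make_references


@pytest.fixture(scope="session")
def toy_refs():
    """Default 60-residue open/closed reference pair (0.6 nm Cα separation)."""
    return make_references(SyntheticSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def make_point_topology(n: int, resname: str = "ALA") -> Topology:
    """n Cα pseudo-atoms, one per residue."""
    return Topology([
        AtomRecord(i + 1, "CA", resname, i + 1, "A", "C", 12.011)
        for i in range(n)
    ])


def trajectory_from_coords(coords: np.ndarray, spacing: float = 1.0,
                           top: Topology | None = None,
                           box=None) -> Trajectory:
    """Wrap an (n_frames, n_atoms, 3) array into a Trajectory."""
    coords = np.asarray(coords, float)
    top = top or make_point_topology(coords.shape[1])
    frames = [Frame(c, box=box, time=i * spacing) for i, c in enumerate(coords)]
    return Trajectory(top, frames)
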