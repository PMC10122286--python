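import numpy as np
import pytest

from myofibspat import (
    FiberSection,
    delaunay_network,
    generate_lattice_section,
    simulate_bmrf_labels,
)
from myofibspat.geometry import PruneConfig

RAW = PruneConfig(length_factor=None, clip_to_boundary=False)


@pytest.fixture(scope="session")
def lattice_points() -> FiberSection:
    """Soleus-scale jittered lattice: 1600 fibers."""
    return generate_lattice_section(40, 40, jitter=0.2, seed=101)


@pytest.fixture(scope="session")
def lattice_network(lattice_points):
    return delaunay_network(lattice_points)


@pytest.fixture(scope="session")
def small_points() -> FiberSection:
    return generate_lattice_section(12, 12, jitter=0.25, seed=7)


@pytest.fixture(scope="session")
def small_network(small_points):
    return delaunay_network(small_points)


@pytest.fixture(scope="session")
def bmrf_labels(lattice_network):
    """Weakly attractive spin field with a slow majority."""
    return simulate_bmrf_labels(lattice_network, alpha=-0.2, beta=0.06, seed=202)


def make_section(coords: np.ndarray, labels=None) -> FiberSection:
    coords = np.asarray(coords, dtype=float)
    if labels is None:
        labels = ["a"] * len(coords)
    return FiberSection(x=coords[:, 0], y=coords[:, 1], type_label=np.asarray(labels, object))
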