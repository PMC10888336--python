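import numpy as np
import pytest

from gelfun import synthdata
from gelfun.types import SpikeRaster


@pytest.fixture
def small_net():
    """30-neuron cascade network with unit weights (topology-recovery probe)."""
    net = synthdata.generate_network(30, density=0.1, n_communities=1, seed=100)
    net.weights = np.where(net.adjacency > 0, 1.0, 0.0)
    return net


@pytest.fixture
def two_neuron_net():
    """Hand-built 2-neuron net with a single edge 0 -> 1."""
    A = np.array([[0, 1], [0, 0]])
    return synthdata.GroundTruthNetwork(
        n_neurons=2,
        positions=np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]]),
        adjacency=A,
        weights=A.astype(float),
        community_labels=np.zeros(2, dtype=int),
        excitatory_mask=np.ones(2, dtype=bool),
    )


def make_raster(event_lists, duration):
    return SpikeRaster(events=[np.asarray(e, dtype=float) for e in event_lists],
                       duration=duration)
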