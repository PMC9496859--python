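import numpy as np
import pytest

from hippocampal_replay.env import GridWorld
from hippocampal_replay.hippocampus import (NetworkConfig, PlaceCellNetwork,
                                            StateEncoder)
from hippocampal_replay.memory import Outcome, TrajectorySequence, Triple


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def open_world():
    """Small open arena with start and goal in opposite corners."""
    return GridWorld(width=8, height=8, obstacles=frozenset(),
                     start=(0, 0), goal=(7, 7))


def build_tabular_network(world, position_gain=40.0):
    """Place-cell map with disjoint single-cell fields.

    One cell per free grid cell, heading-free positional encoding, and a
    position gain large enough that only the exact cell ever clears the
    striatal filter — the configuration under which the whole system
    reduces to tabular Q-learning.
    """
    encoder = StateEncoder(position_gain=position_gain, include_heading=False)
    net = PlaceCellNetwork(NetworkConfig(max_cells=world.width * world.height))
    net.preallocate(world, encoder)
    cell_index = {cell: i for i, cell in enumerate(sorted(world.free_cells()))}
    return net, encoder, cell_index


def corridor_world(n, reward_scheme="standard"):
    """Length-n east-bound corridor: start (0,0), goal (n,0)."""
    return GridWorld(width=n + 1, height=1, obstacles=frozenset(),
                     start=(0, 0), goal=(n, 0), reward_scheme=reward_scheme)


def corridor_sequence(world, net, encoder, cell_index):
    """The goal-reaching east-walk recorded as a high-reward sequence."""
    from hippocampal_replay.env import ACTION_NAMES

    east = ACTION_NAMES.index("E")
    n = world.goal[0]
    triples, cell_ids = [], []
    for x in range(n):
        reward = world.rewards["goal"] if x == n - 1 else world.rewards["step"]
        triples.append(Triple((x, 0), encoder.encode(world, (x, 0), east),
                              east, reward))
        cell_ids.append(cell_index[(x, 0)])
    return TrajectorySequence(triples, cell_ids, Outcome.HIGH)
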