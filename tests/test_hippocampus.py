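import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippocampal_replay.env import ACTION_NAMES, GridWorld
from hippocampal_replay.hippocampus import (NetworkConfig, PlaceCellNetwork,
                                            StateEncoder)


@pytest.fixture
def net():
    return PlaceCellNetwork(NetworkConfig())


class TestEncoder:
    def test_corner_with_stay_heading(self, open_world):
        enc = StateEncoder(position_gain=1.0)
        vec = enc.encode(open_world, (0, 0), None)
        # 5 of 8 neighbours are off-grid; stay maps to angle 0
        assert np.allclose(vec, [0.0, 0.0, 1.0, 0.0, 5.0 / 8.0])

    def test_interior_heading_north(self, open_world):
        enc = StateEncoder(position_gain=6.0)
        vec = enc.encode(open_world, (4, 4), ACTION_NAMES.index("N"))
        assert np.allclose(vec, [24.0, 24.0, 0.0, 1.0, 0.0], atol=1e-12)

    def test_injective_in_position(self, open_world):
        enc = StateEncoder()
        seen = {tuple(enc.encode(open_world, c)) for c in open_world.free_cells()}
        assert len(seen) == len(open_world.free_cells())

    def test_field_radius_matches_activation(self, open_world):
        cfg = NetworkConfig()
        enc = StateEncoder()
        radius = enc.field_radius(cfg)
        net = PlaceCellNetwork(cfg)
        net.recruit(enc.encode(open_world, (4, 4)), 0.0)
        # at exactly the field radius the rate equals the 0.5 level
        probe = np.array([(4 + radius) * enc.position_gain,
                          4 * enc.position_gain, 1.0, 0.0, 0.0])
        assert net.activate(probe, 0.0)[0] == pytest.approx(0.5, abs=1e-9)


class TestActivation:
    def test_exact_match_fires_at_one(self, net, rng):
        w = rng.normal(size=5)
        net.recruit(w, 0.0)
        assert net.activate(w, 0.0)[0] == pytest.approx(1.0)

    def test_unit_state_distance_value(self, net):
        """Gaussian drive with the published gains: a=5, s_t=0.6, sigma=0.7."""
        net.recruit(np.zeros(5), 0.0)
        probe = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        expected = math.exp(-(0.6 / 5) ** 2 / (2 * 0.49))
        assert net.activate(probe, 0.0)[0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_state_distance(self, net):
        net.recruit(np.zeros(5), 0.0)
        rates = [net.activate(np.array([d, 0, 0, 0, 0]), 0.0)[0]
                 for d in np.linspace(0, 5, 20)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_memory_channel_reduces_activation(self, net):
        net.recruit(np.zeros(5), 0.0)
        assert net.activate(np.zeros(5), 1.0)[0] < net.activate(np.zeros(5), 0.0)[0]

    def test_rates_bounded(self, net, rng):
        for _ in range(20):
            net.recruit(rng.normal(size=5), 0.0)
        for _ in range(50):
            rates = net.activate(rng.normal(size=5) * 10, rng.random())
            assert np.all(rates > 0) and np.all(rates <= 1)

    def test_empty_pool_signals(self, net):
        with pytest.raises(ValueError):
            net.activate(np.zeros(5), 0.0)


class TestWinner:
    def test_argmax(self, net):
        assert net.winner(np.array([0.2, 0.9, 0.1])) == 1

    def test_tie_breaks_to_lowest_id(self, net):
        assert net.winner(np.array([0.5, 0.5])) == 0

    def test_single_cell(self, net):
        assert net.winner(np.array([0.3])) == 0


class TestWeightUpdate:
    def test_full_step_copies_input(self, open_world):
        net = PlaceCellNetwork(NetworkConfig(delta=0.999999))
        net.recruit(np.zeros(5), 0.0)
        target = np.array([1.0, 2.0, 0.0, 0.0, 0.5])
        net.update_weights(0, target, 1.0)
        assert np.allclose(net.W_S[0], target, atol=1e-5)

    def test_half_step(self):
        net = PlaceCellNetwork(NetworkConfig(delta=0.5))
        net.recruit(np.zeros(5), 0.0)
        net.update_weights(0, np.array([1.0, 0, 0, 0, 0]), 0.0)
        assert np.allclose(net.W_S[0], [0.5, 0, 0, 0, 0])

    @settings(deadline=None)
    @given(st.floats(0.05, 0.95),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5),
           st.lists(st.floats(-5, 5), min_size=5, max_size=5))
    def test_contraction_by_one_minus_delta(self, delta, w0, target):
        """Each winner update shrinks the weight error by exactly (1 - delta)."""
        net = PlaceCellNetwork(NetworkConfig(delta=delta))
        net.recruit(np.array(w0, dtype=float), 0.0)
        target = np.array(target, dtype=float)
        before = np.linalg.norm(net.W_S[0] - target)
        net.update_weights(0, target, 0.0)
        after = np.linalg.norm(net.W_S[0] - target)
        assert after == pytest.approx((1 - delta) * before, abs=1e-9)


class TestObserve:
    def test_empty_pool_recruits(self, net):
        rates, winner = net.observe(np.zeros(5), 0.0)
        assert len(net) == 1 and winner == 0
        assert np.allclose(rates, [1.0])

    def test_repeated_input_is_a_fixed_point(self, net, rng):
        w = rng.normal(size=5)
        for _ in range(10):
            net.observe(w, 0.0)
        assert len(net) == 1
        assert np.allclose(net.W_S[0], w)

    def test_grid_sweep_covers_arena_within_pool_cap(self):
        world = GridWorld(20, 20, frozenset(), (2, 2), (16, 16))
        enc = StateEncoder()
        net = PlaceCellNetwork(NetworkConfig())
        for cell in world.free_cells():
            net.observe(enc.encode(world, cell), 0.0)
        assert 1 < len(net) <= 400
        # self-organization: every grid cell now has a winner whose
        # activation clears the recruitment threshold
        for cell in world.free_cells():
            rates = net.activate(enc.encode(world, cell), 0.0)
            assert rates.max() >= net.cfg.recruit_threshold

    def test_pool_never_exceeds_cap(self, rng):
        net = PlaceCellNetwork(NetworkConfig(max_cells=5))
        for _ in range(50):
            net.observe(rng.normal(size=5) * 100, 0.0)
        assert len(net) == 5
        assert net.saturation_warnings > 0

    def test_pool_size_non_decreasing(self, open_world, rng):
        enc = StateEncoder()
        net = PlaceCellNetwork(NetworkConfig())
        sizes = []
        for _ in range(100):
            cell = (int(rng.integers(8)), int(rng.integers(8)))
            net.observe(enc.encode(open_world, cell), 0.0)
            sizes.append(len(net))
        assert sizes == sorted(sizes)


class TestSerialization:
    def test_json_round_trip_is_exact(self, open_world, rng):
        enc = StateEncoder()
        net = PlaceCellNetwork(NetworkConfig())
        for _ in range(30):
            cell = (int(rng.integers(8)), int(rng.integers(8)))
            net.observe(enc.encode(open_world, cell), 0.0)
        net.q_values[:] = rng.normal(size=net.q_values.shape)
        net.add_reactivations([0, 0, 1])
        clone = PlaceCellNetwork.from_json(net.to_json())
        assert len(clone) == len(net)
        assert np.array_equal(clone.W_S, net.W_S)
        assert np.array_equal(clone.W_M, net.W_M)
        assert np.array_equal(clone.q_values, net.q_values)
        assert np.array_equal(clone.reactivation_counts, net.reactivation_counts)

    def test_json_file_round_trip(self, tmp_path, net):
        net.recruit(np.arange(5.0), 0.0)
        path = tmp_path / "map.json"
        net.to_json(path)
        clone = PlaceCellNetwork.from_json(path)
        assert np.array_equal(clone.W_S, net.W_S)
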