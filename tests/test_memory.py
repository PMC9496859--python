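import numpy as np
import pytest

from hippocampal_replay.env import ACTION_NAMES, GridWorld
from hippocampal_replay.memory import (MemoryVault, Outcome, SpliceError,
                                       TrajectorySequence, Triple,
                                       classify_episode, construct_virtual,
                                       find_intersections, refresh_virtual,
                                       select_intersection)

E, N, NE = (ACTION_NAMES.index(a) for a in ("E", "N", "NE"))


def walk(cells, cell_ids, rewards=None, outcome=Outcome.LOW):
    """Build a sequence from a list of grid cells (state vectors are the
    raw coordinates; sufficient for vault logic, which never decodes them)."""
    if rewards is None:
        rewards = [-10.0] * len(cells)
    triples = [Triple(tuple(c), np.array([c[0], c[1], 0, 0, 0], dtype=float),
                      E, r) for c, r in zip(cells, rewards)]
    return TrajectorySequence(triples, list(cell_ids), outcome)


@pytest.fixture
def world():
    return GridWorld(10, 10, frozenset(), (0, 0), (9, 9))


class TestClassify:
    def test_goal_episode_is_high(self, world):
        seq = walk([(8, 8), (9, 8)], [0, 1], rewards=[-10.0, 100.0])
        got = classify_episode(seq.triples, seq.cell_ids, world, True)
        assert got.outcome == Outcome.HIGH
        assert got.total_reward == 90.0

    def test_threshold_episode_is_low(self, world):
        cells = [(i % 2, 0) for i in range(301)]
        seq = walk(cells, range(301))
        got = classify_episode(seq.triples, seq.cell_ids, world, False)
        assert got.outcome == Outcome.LOW

    def test_unterminated_episode_rejected(self, world):
        seq = walk([(0, 0), (1, 0)], [0, 1])
        with pytest.raises(ValueError):
            classify_episode(seq.triples, seq.cell_ids, world, False)

    def test_empty_episode_rejected(self, world):
        with pytest.raises(ValueError):
            classify_episode([], [], world, False)


class TestVault:
    def test_store_routes_by_outcome(self, world):
        vault = MemoryVault()
        vault.store(walk([(0, 0)], [0], rewards=[100.0], outcome=Outcome.HIGH))
        vault.store(walk([(0, 0)], [0]))
        assert len(vault.high) == 1 and len(vault.low) == 1

    def test_fifo_eviction_preserves_order(self):
        vault = MemoryVault(capacity_low=5)
        for i in range(6):
            vault.store(walk([(i, 0)], [i]))
        assert len(vault.low) == 5
        assert [s.cell_ids[0] for s in vault.low] == [1, 2, 3, 4, 5]

    def test_adjacency_invariant_enforced(self):
        with pytest.raises(ValueError):
            walk([(0, 0), (5, 5)], [0, 1])

    def test_jsonl_round_trip(self, tmp_path, world):
        vault = MemoryVault()
        vault.store(walk([(0, 0), (1, 1)], [0, 1], rewards=[-10.0, 100.0],
                         outcome=Outcome.HIGH))
        vault.store(walk([(3, 3), (3, 4)], [5, 6]))
        path = tmp_path / "vault.jsonl"
        vault.dump_jsonl(path)
        clone = MemoryVault.load_jsonl(path)
        assert len(clone.high) == 1 and len(clone.low) == 1
        orig, copy = vault.high[0], clone.high[0]
        assert copy.cell_ids == orig.cell_ids
        assert copy.total_reward == orig.total_reward
        for a, b in zip(orig.triples, copy.triples):
            assert a.cell == b.cell and a.action == b.action
            assert a.reward == b.reward
            assert np.array_equal(a.state_vec, b.state_vec)


class TestIntersections:
    def test_identical_single_cell_sequences(self):
        low = walk([(0, 0)], [7])
        high = walk([(0, 0)], [7], rewards=[100.0], outcome=Outcome.HIGH)
        assert find_intersections(low, high) == [(7, 0, 0)]

    def test_disjoint_sequences(self):
        low = walk([(0, 0), (1, 0)], [1, 2])
        high = walk([(5, 5), (6, 6)], [3, 4], outcome=Outcome.HIGH)
        assert find_intersections(low, high) == []

    def test_last_in_low_first_in_high(self):
        low = walk([(0, 0), (1, 0), (2, 0), (1, 0)], [1, 2, 3, 2])
        high = walk([(0, 1), (1, 1), (2, 1)], [5, 2, 6], outcome=Outcome.HIGH)
        assert find_intersections(low, high) == [(2, 3, 1)]

    def test_selection_prefers_longest_low_prefix(self):
        picked = select_intersection([(1, 2, 0), (9, 7, 3), (4, 4, 1)])
        assert picked == (9, 7, 3)

    def test_selection_tie_breaks_on_high_suffix(self):
        assert select_intersection([(1, 5, 9), (2, 5, 3)]) == (2, 5, 3)

    def test_empty_list_signals(self):
        with pytest.raises(ValueError):
            select_intersection([])


class TestConstructVirtual:
    def test_degenerate_splice_of_identical_paths(self, world):
        cells = [(0, 0), (1, 0), (2, 0)]
        high = walk(cells, [0, 1, 2], rewards=[-10, -10, 100.0],
                    outcome=Outcome.HIGH)
        low = walk(cells, [0, 1, 2], rewards=[-10, -10, 100.0])
        virtual = construct_virtual(low, high, (2, 2, 2), world)
        assert virtual.outcome == Outcome.VIRTUAL
        assert virtual.states == cells
        assert virtual.triples[-1].reward == 100.0

    def test_splice_length_bookkeeping(self, world):
        # low ends exactly at the splice cell; high starts there
        low = walk([(0, 0), (1, 0), (2, 0), (3, 0), (4, 0)], [0, 1, 2, 3, 4])
        high = walk([(4, 0), (4, 1), (4, 2)], [4, 8, 9],
                    rewards=[-10, -10, 100.0], outcome=Outcome.HIGH)
        virtual = construct_virtual(low, high, (4, 4, 0), world)
        assert len(virtual) == len(low) + len(high) - 1
        assert virtual.states.count((4, 0)) == 1

    def test_virtual_path_ends_at_goal_reward(self, world):
        low = walk([(0, 0), (0, 1), (0, 2)], [0, 1, 2])
        high = walk([(0, 2), (1, 2), (2, 2)], [2, 5, 6],
                    rewards=[-10, -10, 100.0], outcome=Outcome.HIGH)
        virtual = construct_virtual(low, high, (2, 2, 0), world)
        assert virtual.triples[-1].reward == world.rewards["goal"]

    def test_non_adjacent_junction_rejected(self, world):
        low = walk([(0, 0), (1, 0)], [0, 9])
        high = walk([(5, 5), (6, 5)], [9, 7], rewards=[-10, 100.0],
                    outcome=Outcome.HIGH)
        with pytest.raises(SpliceError):
            construct_virtual(low, high, (9, 1, 0), world)


class TestRefreshVirtual:
    def test_no_high_sequences_changes_nothing(self, world):
        vault = MemoryVault()
        vault.store(walk([(0, 0)], [0]))
        assert refresh_virtual(vault, world) == 0
        assert len(vault.virtual) == 0

    def test_single_crossing_builds_one_virtual(self, world):
        vault = MemoryVault()
        vault.store(walk([(0, 0), (0, 1), (0, 2)], [0, 1, 2]))
        vault.store(walk([(0, 2), (1, 2), (2, 2)], [2, 5, 6],
                         rewards=[-10, -10, 100.0], outcome=Outcome.HIGH))
        assert refresh_virtual(vault, world) == 1
        assert len(vault.virtual) == 1

    def test_duplicate_construction_deduplicated(self, world):
        vault = MemoryVault()
        vault.store(walk([(0, 0), (0, 1), (0, 2)], [0, 1, 2]))
        vault.store(walk([(0, 2), (1, 2), (2, 2)], [2, 5, 6],
                         rewards=[-10, -10, 100.0], outcome=Outcome.HIGH))
        refresh_virtual(vault, world)
        assert refresh_virtual(vault, world) == 0
        assert len(vault.virtual) == 1

    def test_every_virtual_is_grid_valid_and_goal_terminated(self, world):
        """No reverse splice survives: every stored virtual path reaches
        the goal reward through grid-adjacent states."""
        vault = MemoryVault()
        # several parallel low walks and one high walk crossing them
        for k in range(5):
            cells = [(i, k) for i in range(6)]
            vault.store(walk(cells, [10 * k + i for i in range(6)]))
        high_cells = [(3, j) for j in range(5)]
        vault.store(walk(high_cells, [10 * j + 3 for j in range(5)],
                         rewards=[-10] * 4 + [100.0], outcome=Outcome.HIGH))
        refresh_virtual(vault, world)
        assert len(vault.virtual) >= 1
        for seq in vault.virtual:
            assert seq.triples[-1].reward == world.rewards["goal"]
            for a, b in zip(seq.states, seq.states[1:]):
                assert max(abs(a[0] - b[0]), abs(a[1] - b[1])) <= 1
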