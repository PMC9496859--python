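"""Episode memory: trajectory sequences, the memory vault, virtual paths.

Every episode is recorded as an ordered list of (state, action, reward)
triples together with the winning place cell at each step.  Episodes that
reach the goal are high-reward sequences; episodes that terminate because
the accumulated penalty crossed the failure threshold (or the step cap)
are low-reward sequences.  Both kinds are kept in bounded FIFO stores.

The vault's distinctive operation is virtual-path construction: when a
low-reward and a high-reward sequence pass through a common place cell
(an intersection), the low prefix up to that cell is spliced to the high
suffix after it, producing a goal-reaching trajectory the agent never
actually travelled.  Among multiple intersections the one giving the
longest low prefix is preferred, so the spliced path credits as much of
the failed exploration as possible.  Only the prefix-low/suffix-high
combination is ever kept — the reverse splice cannot reach the goal and
is never produced.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from enum import Enum
from itertools import product

import numpy as np

from .env import GridWorld

__all__ = ["Outcome", "Triple", "TrajectorySequence", "MemoryVault",
           "classify_episode", "find_intersections", "select_intersection",
           "construct_virtual", "refresh_virtual", "SpliceError"]

#: Episode failure thresholds: cumulative reward at or below which, or a
#: step count at which, an exploration is declared failed.
FAIL_REWARD_THRESHOLD = -3000.0
STEP_CAP = 500


class Outcome(str, Enum):
    HIGH = "high"
    LOW = "low"
    VIRTUAL = "virtual"


class SpliceError(ValueError):
    """Raised when a splice would produce a grid-invalid trajectory."""


@dataclass(frozen=True)
class Triple:
    """One recorded step: pre-step state, executed action, reward."""

    cell: tuple
    state_vec: np.ndarray
    action: int
    reward: float


@dataclass
class TrajectorySequence:
    triples: list
    cell_ids: list
    outcome: Outcome
    total_reward: float = None

    def __post_init__(self):
        if len(self.triples) != len(self.cell_ids):
            raise ValueError("triples and cell_ids must have equal length")
        if self.total_reward is None:
            self.total_reward = float(sum(t.reward for t in self.triples))
        self._check_adjacency()

    def _check_adjacency(self):
        for prev, nxt in zip(self.triples, self.triples[1:]):
            dx = abs(prev.cell[0] - nxt.cell[0])
            dy = abs(prev.cell[1] - nxt.cell[1])
            if max(dx, dy) > 1:
                raise ValueError(
                    f"non-adjacent consecutive states {prev.cell} -> {nxt.cell}")

    def __len__(self):
        return len(self.triples)

    @property
    def states(self):
        return [t.cell for t in self.triples]

    def dedup_key(self):
        return tuple(self.cell_ids)


def classify_episode(seq_triples, cell_ids, world: GridWorld,
                     reached_goal: bool,
                     fail_threshold: float = FAIL_REWARD_THRESHOLD) -> TrajectorySequence:
    """Classify a finished episode as a high- or low-reward sequence.

    High iff the final step earned the goal reward; low iff the episode
    ended on the cumulative-penalty threshold or the step cap.  An episode
    that terminated for neither reason is not classifiable.
    """
    if not seq_triples:
        raise ValueError("cannot classify an empty episode")
    total = float(sum(t.reward for t in seq_triples))
    goal_reward = world.rewards["goal"]
    if reached_goal:
        if seq_triples[-1].reward != goal_reward:
            raise ValueError("goal-reaching episode must end on the goal reward")
        outcome = Outcome.HIGH
    elif total <= fail_threshold or len(seq_triples) >= STEP_CAP:
        outcome = Outcome.LOW
    else:
        raise ValueError("episode not terminated: neither goal nor failure")
    return TrajectorySequence(list(seq_triples), list(cell_ids), outcome, total)


@dataclass
class MemoryVault:
    """Bounded FIFO stores of low, high and virtual sequences."""

    capacity_high: int = 20
    capacity_low: int = 50
    capacity_virtual: int = 50
    high: deque = field(default_factory=deque)
    low: deque = field(default_factory=deque)
    virtual: deque = field(default_factory=deque)

    def __post_init__(self):
        self.high = deque(self.high, maxlen=self.capacity_high)
        self.low = deque(self.low, maxlen=self.capacity_low)
        self.virtual = deque(self.virtual, maxlen=self.capacity_virtual)

    def store(self, seq: TrajectorySequence):
        if seq.outcome == Outcome.HIGH:
            self.high.append(seq)
        elif seq.outcome == Outcome.LOW:
            self.low.append(seq)
        elif seq.outcome == Outcome.VIRTUAL:
            if seq.dedup_key() not in {s.dedup_key() for s in self.virtual}:
                self.virtual.append(seq)
        return self

    def replayable(self):
        """Reward-associated sequences eligible for replay (high + virtual)."""
        return list(self.high) + list(self.virtual)

    # -- serialization (JSON lines, one sequence per line) ---------------
    def dump_jsonl(self, path):
        with open(path, "w") as handle:
            for kind in ("high", "low", "virtual"):
                for seq in getattr(self, kind):
                    handle.write(json.dumps(_seq_to_dict(seq)) + "\n")

    @classmethod
    def load_jsonl(cls, path, **capacities) -> "MemoryVault":
        vault = cls(**capacities)
        with open(path) as handle:
            for line in handle:
                if line.strip():
                    vault.store(_seq_from_dict(json.loads(line)))
        return vault


def _seq_to_dict(seq: TrajectorySequence) -> dict:
    return {
        "outcome": seq.outcome.value,
        "total_reward": seq.total_reward,
        "cell_ids": [int(c) for c in seq.cell_ids],
        "triples": [{"cell": list(t.cell),
                     "state_vec": np.asarray(t.state_vec).tolist(),
                     "action": int(t.action),
                     "reward": float(t.reward)} for t in seq.triples],
    }


def _seq_from_dict(payload: dict) -> TrajectorySequence:
    triples = [Triple(tuple(t["cell"]), np.array(t["state_vec"]),
                      t["action"], t["reward"]) for t in payload["triples"]]
    return TrajectorySequence(triples, list(payload["cell_ids"]),
                              Outcome(payload["outcome"]),
                              payload["total_reward"])


# -- intersections and virtual-path construction --------------------------

def find_intersections(low: TrajectorySequence, high: TrajectorySequence):
    """Place cells visited by both sequences.

    Returns one entry per shared cell id: (cell_id, last index of that id
    in the low sequence, first index in the high sequence).  Taking the
    last low occurrence maximises the exploration credit of the prefix;
    taking the first high occurrence minimises redundancy of the suffix.
    """
    if not low.triples or not high.triples:
        raise ValueError("both sequences must be non-empty")
    first_in_high = {}
    for idx, cid in enumerate(high.cell_ids):
        first_in_high.setdefault(cid, idx)
    last_in_low = {}
    for idx, cid in enumerate(low.cell_ids):
        if cid in first_in_high:
            last_in_low[cid] = idx
    return [(cid, low_idx, first_in_high[cid])
            for cid, low_idx in sorted(last_in_low.items())]


def select_intersection(intersections):
    """Prefer the longest low prefix; break ties by the longest remaining
    high suffix, then by the lowest cell id."""
    if not intersections:
        raise ValueError("no intersection: no virtual path can be built")
    return max(intersections, key=lambda item: (item[1], -item[2], -item[0]))


def construct_virtual(low: TrajectorySequence, high: TrajectorySequence,
                      intersection, world: GridWorld) -> TrajectorySequence:
    """Splice low[0..low_idx] with high[high_idx+1..] at a shared cell.

    The splice cell appears once.  The result must be grid-valid
    (consecutive states adjacent) and end on the goal reward; a splice
    whose junction states are not adjacent is rejected — this can happen
    when the shared place cell's field covers more than one grid cell.
    """
    cid, low_idx, high_idx = intersection
    if low.cell_ids[low_idx] != cid or high.cell_ids[high_idx] != cid:
        raise ValueError("intersection indices do not match the cell id")
    triples = low.triples[:low_idx + 1] + high.triples[high_idx + 1:]
    cell_ids = low.cell_ids[:low_idx + 1] + high.cell_ids[high_idx + 1:]
    if not triples or triples[-1].reward != world.rewards["goal"]:
        raise SpliceError("virtual path does not end on the goal reward")
    try:
        return TrajectorySequence(triples, cell_ids, Outcome.VIRTUAL)
    except ValueError as err:
        raise SpliceError(str(err)) from err


def refresh_virtual(vault: MemoryVault, world: GridWorld,
                    pair_budget: int = 30) -> int:
    """Construct virtual paths from stored (low, high) pairs.

    Evaluates at most ``pair_budget`` pairs per call, newest sequences
    first; deduplicated results are appended to the virtual store.
    Returns the number of virtual sequences added.
    """
    added = 0
    evaluated = 0
    for low, high in product(reversed(vault.low), reversed(vault.high)):
        if evaluated >= pair_budget:
            break
        evaluated += 1
        intersections = find_intersections(low, high)
        if not intersections:
            continue
        try:
            virtual = construct_virtual(
                low, high, select_intersection(intersections), world)
        except SpliceError:
            continue
        if virtual.dedup_key() not in {s.dedup_key() for s in vault.virtual}:
            vault.virtual.append(virtual)
            added += 1
    return added
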