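"""Striatal action-selection layer.

Eight groups of action neurons (the compass movements) plus stay read the
place-cell map through a binary filter F_i = [v_i > theta]: only the most
active cells take part in valuation and learning.  The state-action value
is the filtered mean of the contributing cells' q entries,

    Q(s, a) = sum_i q_i(a) F_i / sum_i F_i,

and TD learning distributes the same prediction error
r + gamma * max_a' Q(s', a') - Q(s, a) to every gated cell.  Action choice
is epsilon-greedy over the eight movements once the map carries value; on
a cold map (all filtered values zero) the agent either picks a uniformly
random action (probability P) or keeps its current direction, which makes
early exploration a persistent walk rather than pure diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import N_ACTIONS, N_MOVES, STAY
from .hippocampus import PlaceCellNetwork

__all__ = ["PolicyConfig", "activation_filter", "active_cells",
           "state_action_value", "action_values", "select_action", "td_update"]


@dataclass(frozen=True)
class PolicyConfig:
    """Action-selection and TD-learning parameters.

    ``cold_start`` picks the behaviour on an all-zero value row:
    ``"persistent"`` is the striatal rule (random action with probability
    P, otherwise keep the current direction); ``"uniform"`` falls through
    to plain epsilon-greedy with uniform tie-breaking, the behaviour of
    the tabular baselines.
    """

    epsilon: float = 0.1
    p_random: float = 0.5
    theta: float = 0.5
    alpha: float = 0.3
    gamma: float = 0.9
    cold_start: str = "persistent"

    def __post_init__(self):
        for name in ("epsilon", "p_random", "theta", "gamma"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} outside (0, 1)")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha outside (0, 1]")
        if self.cold_start not in ("persistent", "uniform"):
            raise ValueError("cold_start must be 'persistent' or 'uniform'")


def activation_filter(rates: np.ndarray, theta: float) -> np.ndarray:
    """Binary place-cell filter: 1 iff v_i > theta (strict)."""
    return (np.asarray(rates) > theta).astype(np.int8)


def active_cells(rates: np.ndarray, theta: float) -> np.ndarray:
    """Indices of filter-passing cells, falling back to the winner.

    When no cell clears theta the single most active cell stands in, so
    the value function stays defined everywhere on the map.
    """
    rates = np.asarray(rates)
    idx = np.flatnonzero(rates > theta)
    if idx.size == 0:
        idx = np.array([int(np.argmax(rates))])
    return idx


def state_action_value(pool: PlaceCellNetwork, active: np.ndarray,
                       action: int) -> float:
    """Filtered mean of the active cells' q entries for one action."""
    n = len(active)
    if n == 0:
        raise ValueError("state_action_value undefined with no active cell")
    if n == 1:
        return float(pool.q_values[active[0], action])
    return float(pool.q_values[active, action].sum() / n)


def action_values(pool: PlaceCellNetwork, active: np.ndarray) -> np.ndarray:
    """All 9 filtered action values at once."""
    n = len(active)
    if n == 0:
        raise ValueError("action_values undefined with no active cell")
    if n == 1:
        return pool.q_values[active[0]]
    return pool.q_values[active].sum(axis=0) / n


def select_action(q_row: np.ndarray, cfg: PolicyConfig,
                  rng: np.random.Generator, last_action=None,
                  blocked=None) -> int:
    """Pick an action from a 9-entry value row.

    Cold start (all values zero, ``persistent`` mode): uniformly random
    with probability P, else repeat the last executed action (a random
    movement on the first step of an episode).  Otherwise epsilon-greedy:
    the argmax over the 8 movement actions with probability 1 - epsilon
    (ties uniform), else a uniformly random action.

    ``blocked`` is the radius-1 lidar occupancy (8 compass entries).
    When given, the cold-start branches detour around sensed obstacles:
    random picks range over the unblocked movements and a blocked
    current direction is re-drawn instead of repeated.
    """
    q_row = np.asarray(q_row)
    if cfg.cold_start == "persistent" and np.all(q_row == 0.0):
        keep = rng.random() >= cfg.p_random
        if keep and last_action is not None and last_action != STAY \
                and (blocked is None or not blocked[last_action]):
            return int(last_action)
        if blocked is None:
            return int(rng.integers(N_ACTIONS if not keep else N_MOVES))
        open_moves = np.flatnonzero(np.asarray(blocked)[:N_MOVES] == 0)
        if open_moves.size == 0:
            return STAY
        return int(open_moves[rng.integers(open_moves.size)])
    if rng.random() < cfg.epsilon:
        if blocked is None:
            return int(rng.integers(N_ACTIONS))
        choices = np.append(np.flatnonzero(np.asarray(blocked)[:N_MOVES] == 0),
                            STAY)
        return int(choices[rng.integers(choices.size)])
    moves = q_row[:N_MOVES]
    best = np.flatnonzero(moves == moves.max())
    if best.size == 1:
        return int(best[0])
    return int(best[rng.integers(best.size)])


def td_update(pool: PlaceCellNetwork, active_t: np.ndarray, action: int,
              reward: float, active_next, cfg: PolicyConfig,
              terminal: bool = False) -> float:
    """One gated TD step; returns the TD error.

    ``active_next`` may be None when ``terminal`` (the max-term is 0).
    Every cell gated at the current state receives the same alpha-scaled
    error on the taken action's q entry; all other cells are untouched.
    """
    if len(active_t) == 0:
        return 0.0
    q_sa = state_action_value(pool, active_t, action)
    if terminal:
        target = reward
    else:
        target = reward + cfg.gamma * float(action_values(pool, active_next).max())
    td_error = target - q_sa
    if len(active_t) == 1:
        pool.q_values[active_t[0], action] += cfg.alpha * td_error
    else:
        pool.q_values[active_t, action] += cfg.alpha * td_error
    return td_error
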