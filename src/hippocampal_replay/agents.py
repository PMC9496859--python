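"""Navigation agents: the hippocampus-striatum replay agent and the two
tabular reinforcement-learning baselines it is compared against.

All agents present the same stepping interface to the episode runner:
``begin_episode`` / ``policy_step`` / ``transition`` / ``end_episode``,
and all draw from the runner's single random stream, so that two agents
run with the same seed see identical action perturbations whenever their
decisions coincide.
"""

from __future__ import annotations

import numpy as np

from .env import ActionOutcome, GridWorld, N_ACTIONS, lidar_scan
from .hippocampus import NetworkConfig, PlaceCellNetwork, StateEncoder
from .memory import (FAIL_REWARD_THRESHOLD, MemoryVault, Triple,
                     classify_episode)
from .replay import ReplaySchedule, consolidate
from .striatum import (PolicyConfig, action_values, active_cells,
                       select_action, td_update)

__all__ = ["ReplayAgent", "QLambdaAgent", "RandomReplayAgent",
           "baseline_qlearn", "baseline_random_er"]


class _AgentBase:
    def __init__(self, policy: PolicyConfig):
        self.policy = policy
        self.last_action = None

    def begin_episode(self):
        self.last_action = None

    def q_row(self, world: GridWorld, state) -> np.ndarray:
        raise NotImplementedError

    def policy_step(self, world, state, rng) -> int:
        return select_action(self.q_row(world, state), self.policy, rng,
                             self.last_action)

    def transition(self, world, state, outcome: ActionOutcome, rng):
        raise NotImplementedError

    def end_episode(self, world, reached_goal: bool):
        pass


class ReplayAgent(_AgentBase):
    """Place-cell cognitive map + striatal selection + memory replay.

    During navigation the place-cell network self-organises over the
    visited states, the striatum learns gated action values online, and
    every finished episode is classified and stored in the memory vault.
    After each episode the vault is consolidated: virtual paths are
    spliced from stored low x high pairs and all reward-associated
    sequences are replayed through the map.
    """

    def __init__(self, policy: PolicyConfig | None = None,
                 network: PlaceCellNetwork | None = None,
                 encoder: StateEncoder | None = None,
                 vault: MemoryVault | None = None,
                 schedule: ReplaySchedule | None = None,
                 consolidation: bool = True,
                 lidar_masking: bool = True,
                 fail_threshold: float = FAIL_REWARD_THRESHOLD):
        super().__init__(policy or PolicyConfig())
        self.network = network or PlaceCellNetwork(NetworkConfig())
        self.encoder = encoder or StateEncoder()
        self.vault = vault or MemoryVault()
        self.schedule = schedule or ReplaySchedule()
        self.consolidation = consolidation
        self.lidar_masking = lidar_masking
        self.fail_threshold = fail_threshold
        self.replay_log = None  # set to a list to collect TD diagnostics
        self._reset_episode_record()

    def _reset_episode_record(self):
        self._triples = []
        self._cell_ids = []
        self._stash = None

    def begin_episode(self):
        super().begin_episode()
        self._reset_episode_record()

    def policy_step(self, world, state, rng):
        # the agent detours around lidar-sensed obstacles while exploring
        blocked = lidar_scan(world, state) if self.lidar_masking else None
        return select_action(self.q_row(world, state), self.policy, rng,
                             self.last_action, blocked=blocked)

    def q_row(self, world, state):
        s_vec = self.encoder.encode(world, state, self.last_action)
        rates, winner = self.network.observe(s_vec, 0.0)
        active = active_cells(rates, self.policy.theta)
        self._stash = (s_vec, winner, active)
        return action_values(self.network, active)

    def transition(self, world, state, outcome, rng):
        s_vec, winner, active = self._stash
        self._triples.append(Triple(tuple(state), s_vec,
                                    outcome.executed_action, outcome.reward))
        self._cell_ids.append(winner)
        next_vec = self.encoder.encode(world, outcome.next_state,
                                       outcome.executed_action)
        next_rates = self.network.activate(next_vec, 0.0)
        next_active = active_cells(next_rates, self.policy.theta)
        td_update(self.network, active, outcome.executed_action,
                  outcome.reward, next_active, self.policy,
                  terminal=outcome.reached_goal)
        self.last_action = outcome.executed_action

    def end_episode(self, world, reached_goal):
        if not self._triples:
            return
        seq = classify_episode(self._triples, self._cell_ids, world,
                               reached_goal, self.fail_threshold)
        self.vault.store(seq)
        if self.consolidation:
            consolidate(self.vault, self.network, self.schedule,
                        self.policy, world, log=self.replay_log)
        self._reset_episode_record()

    def export_snapshot(self, path):
        """Cognitive map plus policy parameters in one JSON container."""
        import json
        from dataclasses import asdict

        payload = {"policy": asdict(self.policy),
                   "encoder": asdict(self.encoder),
                   "network": json.loads(self.network.to_json())}
        with open(path, "w") as handle:
            json.dump(payload, handle)

    @classmethod
    def from_snapshot(cls, path, **kwargs):
        import json

        with open(path) as handle:
            payload = json.load(handle)
        net = PlaceCellNetwork.from_json(json.dumps(payload["network"]))
        return cls(policy=PolicyConfig(**payload["policy"]),
                   network=net,
                   encoder=StateEncoder(**payload["encoder"]), **kwargs)


class QLambdaAgent(_AgentBase):
    """Tabular Watkins' Q(lambda) with replacing eligibility traces.

    Traces decay by gamma * lambda along greedy runs and are cut whenever
    the executed action was not greedy (Watkins' rule — the convergent
    form of Q-learning with traces; uncut traces diverge under off-policy
    bootstrapping on long episodes).  With lambda = 1 one goal episode
    along a greedy path assigns the full discounted return to every
    state-action pair on it; lambda = 0 recovers one-step Q-learning.
    """

    def __init__(self, world: GridWorld, policy: PolicyConfig | None = None,
                 lambda_: float = 1.0):
        super().__init__(policy or PolicyConfig())
        self.lambda_ = float(lambda_)
        self.Q = np.zeros((world.width, world.height, N_ACTIONS))
        self._traces = np.zeros_like(self.Q)

    def q_row(self, world, state):
        return self.Q[state[0], state[1]]

    def transition(self, world, state, outcome, rng):
        x, y = state
        action = outcome.executed_action
        nx, ny = outcome.next_state
        greedy = self.Q[x, y, action] >= self.Q[x, y].max()
        bootstrap = 0.0 if outcome.reached_goal else self.Q[nx, ny].max()
        td_error = outcome.reward + self.policy.gamma * bootstrap - self.Q[x, y, action]
        self._traces *= self.policy.gamma * self.lambda_
        self._traces[x, y, action] = 1.0
        self.Q += self.policy.alpha * td_error * self._traces
        if not greedy:
            self._traces[:] = 0.0
        self.last_action = action

    def end_episode(self, world, reached_goal):
        self._traces[:] = 0.0


class RandomReplayAgent(_AgentBase):
    """Tabular Q-learning with uniform random experience replay.

    Single transitions go into a ring buffer; each environment step
    replays a uniform batch with one-step Q updates (batch targets are
    computed against the pre-update table).  All learning happens through
    replay, so a buffer of size 1 degenerates to on-policy Q-learning.
    """

    def __init__(self, world: GridWorld, policy: PolicyConfig | None = None,
                 buffer_size: int = 10_000, batch_size: int = 32):
        super().__init__(policy or PolicyConfig())
        self.Q = np.zeros((world.width, world.height, N_ACTIONS))
        self.buffer_size = int(buffer_size)
        self.batch_size = int(batch_size)
        self._buffer = np.zeros((self.buffer_size, 7))  # x y a r nx ny term
        self._size = 0
        self._head = 0

    def q_row(self, world, state):
        return self.Q[state[0], state[1]]

    def transition(self, world, state, outcome, rng):
        row = (state[0], state[1], outcome.executed_action, outcome.reward,
               outcome.next_state[0], outcome.next_state[1],
               float(outcome.reached_goal))
        self._buffer[self._head] = row
        self._head = (self._head + 1) % self.buffer_size
        self._size = min(self._size + 1, self.buffer_size)
        self._replay_batch(rng)
        self.last_action = outcome.executed_action

    def _replay_batch(self, rng):
        if self._size <= self.batch_size:
            idx = np.arange(self._size)
        else:
            idx = rng.integers(self._size, size=self.batch_size)
        batch = self._buffer[idx]
        x, y, a = batch[:, 0].astype(int), batch[:, 1].astype(int), batch[:, 2].astype(int)
        nx, ny = batch[:, 4].astype(int), batch[:, 5].astype(int)
        bootstrap = self.Q[nx, ny].max(axis=1) * (1.0 - batch[:, 6])
        td_error = batch[:, 3] + self.policy.gamma * bootstrap - self.Q[x, y, a]
        np.add.at(self.Q, (x, y, a), self.policy.alpha * td_error)


def baseline_qlearn(world: GridWorld, policy: PolicyConfig | None = None,
                    lambda_: float = 1.0) -> QLambdaAgent:
    """Plain Q-learning baseline (alpha 0.3, gamma 0.9, lambda 1)."""
    return QLambdaAgent(world, policy, lambda_)


def baseline_random_er(world: GridWorld, policy: PolicyConfig | None = None,
                       buffer_size: int = 10_000,
                       batch_size: int = 32) -> RandomReplayAgent:
    """Uniform random experience-replay baseline."""
    return RandomReplayAgent(world, policy, buffer_size, batch_size)
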