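"""Episode loop, experiment runner, metrics and signal-propagation maps.

The experiment surface reproduces the comparative water-maze studies:
per-episode returns and step counts, 30-episode window totals of reward
received, the stabilized average over the last 16 windows, success-rate
learning curves for the relocated-platform task, and the per-cell
signal-strength / reactivation maps drawn over the arena.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .agents import ReplayAgent, baseline_qlearn, baseline_random_er
from .env import GridWorld, free_cell_graph, make_maze, relocate, step
from .hippocampus import NetworkConfig, PlaceCellNetwork, StateEncoder
from .memory import FAIL_REWARD_THRESHOLD, STEP_CAP
from .replay import ReplaySchedule
from .striatum import PolicyConfig, action_values, active_cells

logger = logging.getLogger("hippocampal_replay")

__all__ = ["RunConfig", "ExperimentResult", "run_episode", "run_experiment",
           "make_agent", "signal_maps", "episodes_to_criterion",
           "junction_reactivation", "compare_agents"]

AGENT_NAMES = ("replay", "qlearn", "qlearn_random_er")

#: Window length for the stabilization statistic (the published block
#: grouping) and the number of trailing windows averaged.
STABILIZATION_WINDOW = 30
STABILIZATION_BLOCKS = 16


@dataclass
class RunConfig:
    """Everything needed to reproduce one training run."""

    agent: str = "replay"
    env_kind: str = "open"
    episodes: int = 600
    seed: int = 0
    reward_scheme: str = "standard"
    random_start: bool = False
    start: tuple | None = None
    goal: tuple | None = None
    step_cap: int = STEP_CAP
    fail_threshold: float = FAIL_REWARD_THRESHOLD
    window: int = STABILIZATION_WINDOW
    stabilization_blocks: int = STABILIZATION_BLOCKS
    policy: dict = field(default_factory=dict)
    network: dict = field(default_factory=dict)
    schedule: dict = field(default_factory=dict)
    encoder: dict = field(default_factory=dict)
    er_buffer_size: int = 10_000
    er_batch_size: int = 32
    qlambda: float = 1.0

    def __post_init__(self):
        if self.agent not in AGENT_NAMES:
            raise ValueError(f"unknown agent {self.agent!r}")

    def build_world(self) -> GridWorld:
        world = make_maze(self.env_kind, self.seed, self.reward_scheme)
        if self.start or self.goal:
            world = relocate(world, self.start, self.goal)
        return world

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ExperimentResult:
    per_episode_return: list
    per_episode_steps: list
    per_episode_success: list
    window_returns: list
    stabilized_average: float
    reactivation_map: np.ndarray
    signal_strength_map: np.ndarray
    seed: int
    config: RunConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "episode": np.arange(1, len(self.per_episode_return) + 1),
            "return": self.per_episode_return,
            "steps": self.per_episode_steps,
            "success": self.per_episode_success,
        })

    def recompute_stabilized_average(self, window=None, blocks=None) -> float:
        """Recompute the stabilization statistic from the episode log."""
        window = window or (self.config.window if self.config else STABILIZATION_WINDOW)
        blocks = blocks or (self.config.stabilization_blocks if self.config
                            else STABILIZATION_BLOCKS)
        totals = window_totals(self.per_episode_return, window)
        return stabilized_average(totals, blocks)


def window_totals(returns, window: int = STABILIZATION_WINDOW):
    """Total reward received in consecutive non-overlapping blocks."""
    returns = np.asarray(returns, dtype=float)
    n_blocks = len(returns) // window
    if n_blocks == 0:
        return []
    trimmed = returns[:n_blocks * window].reshape(n_blocks, window)
    return trimmed.sum(axis=1).tolist()


def stabilized_average(totals, blocks: int = STABILIZATION_BLOCKS) -> float:
    if not totals:
        return float("nan")
    if len(totals) < blocks:
        logger.warning("only %d stabilization windows available (wanted %d)",
                       len(totals), blocks)
    return float(np.mean(totals[-blocks:]))


def make_agent(name: str, world: GridWorld, cfg: RunConfig | None = None):
    cfg = cfg or RunConfig(agent=name)
    policy_kwargs = dict(cfg.policy)
    if name == "replay":
        policy = PolicyConfig(**policy_kwargs)
        return ReplayAgent(
            policy=policy,
            network=PlaceCellNetwork(NetworkConfig(**cfg.network)),
            encoder=StateEncoder(**cfg.encoder),
            schedule=ReplaySchedule(**cfg.schedule),
            fail_threshold=cfg.fail_threshold,
        )
    # the tabular baselines use plain epsilon-greedy from the start
    policy_kwargs.setdefault("cold_start", "uniform")
    policy = PolicyConfig(**policy_kwargs)
    if name == "qlearn":
        return baseline_qlearn(world, policy, cfg.qlambda)
    if name == "qlearn_random_er":
        return baseline_random_er(world, policy, cfg.er_buffer_size,
                                  cfg.er_batch_size)
    raise ValueError(f"unknown agent {name!r}")


def run_episode(agent, world: GridWorld, rng: np.random.Generator,
                start=None, random_start: bool = False,
                step_cap: int = STEP_CAP,
                fail_threshold: float = FAIL_REWARD_THRESHOLD):
    """One navigation from the starting point to goal or failure.

    Returns (total_return, steps, success).  Draw order per episode:
    optionally one draw for the random start cell, then per step the
    policy draws followed by the action-perturbation draw.
    """
    if random_start:
        candidates = [c for c in sorted(world.free_cells()) if c != world.goal]
        state = candidates[rng.integers(len(candidates))]
    else:
        state = tuple(start) if start is not None else world.start
    agent.begin_episode()
    total, steps, success = 0.0, 0, False
    while True:
        action = agent.policy_step(world, state, rng)
        outcome = step(world, state, action, rng)
        agent.transition(world, state, outcome, rng)
        total += outcome.reward
        steps += 1
        state = outcome.next_state
        if outcome.reached_goal:
            success = True
            break
        if total <= fail_threshold or steps >= step_cap:
            break
    agent.end_episode(world, success)
    return total, steps, success


def run_experiment(cfg: RunConfig) -> ExperimentResult:
    """Train one agent for ``cfg.episodes`` episodes; fully seed-deterministic."""
    world = cfg.build_world()
    agent = make_agent(cfg.agent, world, cfg)
    rng = np.random.default_rng(cfg.seed)
    logger.info("run agent=%s env=%s episodes=%d seed=%d config=%s",
                cfg.agent, cfg.env_kind, cfg.episodes, cfg.seed,
                cfg.config_hash())
    returns, steps_list, successes = [], [], []
    for _ in range(cfg.episodes):
        total, steps, success = run_episode(
            agent, world, rng, random_start=cfg.random_start,
            step_cap=cfg.step_cap, fail_threshold=cfg.fail_threshold)
        returns.append(total)
        steps_list.append(steps)
        successes.append(success)
    totals = window_totals(returns, cfg.window)
    strength, reactivation = signal_maps(agent, world)
    return ExperimentResult(returns, steps_list, successes, totals,
                            stabilized_average(totals, cfg.stabilization_blocks),
                            reactivation, strength, cfg.seed, cfg)


def signal_maps(agent, world: GridWorld):
    """(signal_strength_map, reactivation_map) over the arena grid.

    Strength at a grid cell is the best filtered action value of the
    trained map there, normalized to [0, 1] by the map maximum (negative
    values clip to 0).  Reactivation at a grid cell sums the replay
    reactivation counts of the place cells whose field centre falls on it.
    Tabular agents have no place cells: their strength map comes from the
    Q table and their reactivation map is zero.
    """
    strength = np.zeros((world.width, world.height))
    reactivation = np.zeros((world.width, world.height))
    if isinstance(agent, ReplayAgent):
        net, encoder = agent.network, agent.encoder
        if len(net) > 0:
            for cell in world.free_cells():
                rates = net.activate(encoder.encode(world, cell), 0.0)
                active = active_cells(rates, agent.policy.theta)
                strength[cell] = action_values(net, active).max()
            for cid in range(len(net)):
                gx, gy = net.assigned_grid_cell(cid, encoder)
                if world.in_grid((gx, gy)):
                    reactivation[gx, gy] += net.reactivation_counts[cid]
    else:
        for cell in world.free_cells():
            strength[cell] = agent.Q[cell[0], cell[1]].max()
    np.clip(strength, 0.0, None, out=strength)
    peak = strength.max()
    if peak > 0:
        strength /= peak
    return strength, reactivation


def episodes_to_criterion(successes, window: int = 30, rate: float = 0.9):
    """First episode index (1-based) whose trailing window clears ``rate``.

    Returns None when the criterion is never met.
    """
    flags = np.asarray(successes, dtype=float)
    if len(flags) < window:
        return None
    csum = np.concatenate([[0.0], np.cumsum(flags)])
    trailing = (csum[window:] - csum[:-window]) / window
    hits = np.flatnonzero(trailing >= rate)
    if hits.size == 0:
        return None
    return int(hits[0]) + window


def junction_reactivation(world: GridWorld, reactivation_map: np.ndarray):
    """Mean reactivation at junction vs corridor cells.

    Junctions are free cells of degree >= 3 in the 4-connected free-cell
    graph; corridor cells have degree exactly 2.
    """
    graph = free_cell_graph(world, connectivity=4)
    junctions = [c for c in graph if graph.degree(c) >= 3]
    corridors = [c for c in graph if graph.degree(c) == 2]
    mean_at = lambda cells: float(np.mean([reactivation_map[c] for c in cells])) \
        if cells else float("nan")
    return mean_at(junctions), mean_at(corridors)


def compare_agents(env_kind: str = "open", reward_scheme: str = "amplified",
                   episodes: int = 600, seeds=range(10),
                   random_start: bool = True, agents=AGENT_NAMES,
                   **cfg_overrides) -> pd.DataFrame:
    """Run several agents on shared seeds; one row per (agent, seed)."""
    rows = []
    for seed in seeds:
        for name in agents:
            cfg = RunConfig(agent=name, env_kind=env_kind, episodes=episodes,
                            seed=int(seed), reward_scheme=reward_scheme,
                            random_start=random_start, **cfg_overrides)
            result = run_experiment(cfg)
            rows.append({"agent": name, "seed": int(seed),
                         "stabilized_average": result.stabilized_average,
                         "mean_return": float(np.mean(result.per_episode_return)),
                         "success_rate": float(np.mean(result.per_episode_success))})
    return pd.DataFrame(rows)


def comparison_summary(table: pd.DataFrame) -> dict:
    """Stabilized averages per agent and the relative improvement (%)."""
    means = table.groupby("agent")["stabilized_average"].mean().to_dict()
    summary = {"stabilized_average": means}
    reference = means.get("qlearn_random_er", 0.0)
    if "replay" in means and reference > 0:
        summary["relative_improvement_pct"] = 100.0 * (
            means["replay"] / reference - 1.0)
    return summary
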