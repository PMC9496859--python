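"""Offline reactivation of stored trajectory sequences.

Replay walks a high-reward or virtual sequence forward, step by step, as
if the agent were re-experiencing it: the network is re-activated with
each stored state vector and the memory channel driven to 1, and every
cell passing the striatal filter receives a standard Q-learning update

    Q(s_j, a_j) <- Q(s_j, a_j) + alpha [R_j + gamma max_a' Q(s_{j+1}, a') - Q(s_j, a_j)]

(the terminal triple uses a zero max-term).  Because one forward pass
propagates the terminal reward exactly one step backwards, n passes over
a length-n corridor reproduce the credit assignment of an eligibility
trace with lambda = 1 — without any trace parameter.  Input weights are
frozen during replay; only q-values and reactivation counts change.

Low-reward sequences never replay: they are subconscious storage, raw
material for virtual-path construction only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hippocampus import PlaceCellNetwork
from .memory import MemoryVault, Outcome, TrajectorySequence, refresh_virtual
from .striatum import PolicyConfig, active_cells

__all__ = ["ReplaySchedule", "replay_sequence", "consolidate",
           "sequence_gates", "write_replay_log"]

#: Column order of replay-log rows collected by ``replay_sequence``.
LOG_COLUMNS = ("round", "sequence_id", "pass", "step", "cell_id", "td_error")


def write_replay_log(log, path):
    """Write collected (round, sequence, pass, step, cell, TD-error) rows
    to CSV for diagnostics."""
    import pandas as pd

    pd.DataFrame(log, columns=LOG_COLUMNS).to_csv(path, index=False)

#: Memory-channel drive during replay (live navigation uses 0).
REPLAY_MEMORY_INPUT = 1.0


@dataclass(frozen=True)
class ReplaySchedule:
    """Consolidation budgets.

    ``niter`` caps the total TD steps per consolidation round and
    ``p_runs`` caps the (low, high) pairs examined per virtual-path
    refresh, following the published budgets (1000 and 30).
    ``passes_per_sequence`` = None derives the pass count from the longest
    eligible sequence (capped at 50), which guarantees full reward
    propagation along any corridor shorter than the cap.
    """

    passes_per_sequence: int | None = None
    rounds: int = 1
    niter: int = 1000
    p_runs: int = 30

    def __post_init__(self):
        if self.passes_per_sequence is not None and self.passes_per_sequence < 1:
            raise ValueError("passes_per_sequence must be positive")
        if min(self.rounds, self.niter, self.p_runs) < 1:
            raise ValueError("all schedule counts must be positive")


def sequence_gates(seq: TrajectorySequence, pool: PlaceCellNetwork,
                   theta: float):
    """Active-cell index arrays for every triple, under replay drive.

    Activations are computed in one vectorised sweep (weights are frozen
    during replay, so gates are valid for any number of passes).
    """
    cfg = pool.cfg
    states = np.array([t.state_vec for t in seq.triples])
    diff = states[:, None, :] - pool.W_S[None, :, :]
    d_state = np.sqrt(np.einsum("tid,tid->ti", diff, diff))
    d_mem = np.abs(pool.W_M[:, 0] - REPLAY_MEMORY_INPUT)
    drive = (cfg.s_gate / cfg.a) * d_state + (cfg.m_gate / cfg.b) * d_mem
    rates = np.exp(-(drive ** 2) / (2.0 * cfg.sigma_pc ** 2))
    mask = rates > theta
    empty = ~mask.any(axis=1)
    if empty.any():  # winner fallback for uncovered replayed states
        mask[empty, rates[empty].argmax(axis=1)] = True
    rows, cols = np.nonzero(mask)
    splits = np.searchsorted(rows, np.arange(1, len(seq)))
    return np.split(cols, splits)


def replay_sequence(seq: TrajectorySequence, pool: PlaceCellNetwork,
                    cfg: PolicyConfig, gates=None, max_steps=None,
                    log=None, log_context=(0, 0, 0)) -> int:
    """One forward replay pass; returns the number of TD steps applied."""
    if seq.outcome not in (Outcome.HIGH, Outcome.VIRTUAL):
        raise ValueError("only high-reward and virtual sequences replay")
    if gates is None:
        gates = sequence_gates(seq, pool, cfg.theta)
    q = pool.q_values
    n_s = len(seq)
    steps = n_s if max_steps is None else min(n_s, max_steps)
    last = n_s - 1
    for j in range(steps):
        triple = seq.triples[j]
        active = gates[j]
        if len(active) == 1:
            q_sa = q[active[0], triple.action]
        else:
            q_sa = q[active, triple.action].sum() / len(active)
        if j == last:
            target = triple.reward
        else:
            nxt = gates[j + 1]
            if len(nxt) == 1:
                bootstrap = q[nxt[0]].max()
            else:
                bootstrap = (q[nxt].sum(axis=0) / len(nxt)).max()
            target = triple.reward + cfg.gamma * bootstrap
        td_error = target - q_sa
        if len(active) == 1:
            q[active[0], triple.action] += cfg.alpha * td_error
        else:
            q[active, triple.action] += cfg.alpha * td_error
        pool.add_reactivations(active)
        if log is not None:
            rnd, seq_id, pass_idx = log_context
            for cid in active:
                log.append((rnd, seq_id, pass_idx, j, int(cid), float(td_error)))
    return steps


def consolidate(vault: MemoryVault, pool: PlaceCellNetwork,
                schedule: ReplaySchedule, cfg: PolicyConfig, world,
                log=None) -> int:
    """One consolidation: refresh virtual paths, then replay the vault.

    Replays every high and virtual sequence ``passes_per_sequence`` times
    (or enough passes for full propagation when unset), interleaved, with
    the total TD-step budget capped at ``niter`` per round.  Returns the
    total TD steps applied.
    """
    total_steps = 0
    for rnd in range(schedule.rounds):
        refresh_virtual(vault, world, pair_budget=schedule.p_runs)
        # newest memories first: they are the most task-relevant, and the
        # niter budget may not reach the back of the vault
        sequences = (list(reversed(vault.high))
                     + list(reversed(vault.virtual)))
        if not sequences:
            return total_steps
        passes = schedule.passes_per_sequence
        if passes is None:
            passes = min(50, max(len(s) for s in sequences))
        gate_cache = [None] * len(sequences)  # computed only when replayed
        budget = schedule.niter
        for pass_idx in range(passes):
            for seq_id, seq in enumerate(sequences):
                if budget <= 0:
                    break
                if gate_cache[seq_id] is None:
                    gate_cache[seq_id] = sequence_gates(seq, pool, cfg.theta)
                done = replay_sequence(seq, pool, cfg, gates=gate_cache[seq_id],
                                       max_steps=budget, log=log,
                                       log_context=(rnd, seq_id, pass_idx))
                budget -= done
                total_steps += done
            if budget <= 0:
                break
    return total_steps
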