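"""Two-layer place-cell network forming the cognitive map.

Each place cell is a Gaussian-tuned unit over a joint input: a 5-component
environment-state channel (position, heading, local occupancy) and a
1-component memory channel that is 0 during live navigation and 1 while a
stored sequence is being replayed offline.  The firing rate of cell *i* is

    v_i = exp(-[(s_t/a) * ||S - W_S,i||  +  (m_t/b) * |M - W_M,i|]^2 / (2 sigma_pc^2))

with Euclidean norms, channel gains s_t, m_t, channel dimensions a, b and
place-field width sigma_pc.  Plasticity is winner-take-all: only the most
active cell moves its weights toward the current input, by a fraction
delta per presentation.  A new cell is recruited (weights copied from the
input) whenever the winning activation falls below the recruitment
threshold, i.e. no existing field covers the input.  Each cell also
carries a 9-entry action-value vector, so the value function lives
distributed across the map; those q-values are written by the striatal
layer and by offline replay, never by the competitive learning here.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .env import STAY, GridWorld, action_angle, lidar_scan
from .env import N_ACTIONS

__all__ = ["NetworkConfig", "StateEncoder", "PlaceCell", "PlaceCellNetwork"]

STATE_DIM = 5
MEMORY_DIM = 1


@dataclass(frozen=True)
class NetworkConfig:
    """Place-cell network parameters.

    sigma_pc, delta, s_gate, m_gate, a, b follow the published parameter
    table (0.7, 0.5, 0.6, 0.4, 5, 1).  ``recruit_threshold`` is the
    minimum winning activation below which a new cell is recruited; its
    default equals the striatal filter threshold so that every state the
    agent visits ends up covered by at least one field.  ``activation_floor``
    (0.0065) is kept as a numerical floor on reported rates.
    """

    sigma_pc: float = 0.7
    delta: float = 0.5
    s_gate: float = 0.6
    m_gate: float = 0.4
    a: int = STATE_DIM
    b: int = MEMORY_DIM
    recruit_threshold: float = 0.5
    activation_floor: float = 0.0065
    max_cells: int = 400

    def __post_init__(self):
        for name in ("sigma_pc", "delta", "s_gate", "m_gate"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name}={value} outside (0, 1)")
        if not 0.0 <= self.recruit_threshold <= 1.0:
            raise ValueError("recruit_threshold outside [0, 1]")
        if self.max_cells < 1:
            raise ValueError("max_cells must be positive")


@dataclass(frozen=True)
class StateEncoder:
    """Maps (cell, heading, lidar) to the 5-component state vector.

    Components: (x * position_gain, y * position_gain, cos theta,
    sin theta, occupied-neighbour fraction), where theta is the compass
    angle of the last executed action (0 for stay / episode start).

    ``position_gain`` sets the spatial scale of the place code: with the
    default network gains the half-activation field radius is
    sigma_pc * a * sqrt(2 ln 2) / (s_gate * position_gain) grid cells,
    i.e. ~1.1 cells at the default gain of 6 — local enough that fields
    never straddle a corridor wall (free cells separated by a wall are at
    least 2 apart), while adjacent cells along a path still share fields.  ``include_heading``
    disables the heading components (useful for purely positional codes,
    e.g. the tabular-equivalence analysis).
    """

    position_gain: float = 6.0
    include_heading: bool = True

    def encode(self, world: GridWorld, cell, last_action=None) -> np.ndarray:
        x, y = cell
        theta = action_angle(STAY if last_action is None else last_action)
        occupancy = float(lidar_scan(world, cell).mean())
        if self.include_heading:
            head = (math.cos(theta), math.sin(theta))
        else:
            head = (0.0, 0.0)
        return np.array([x * self.position_gain, y * self.position_gain,
                         head[0], head[1], occupancy])

    def field_radius(self, cfg: NetworkConfig, level: float = 0.5) -> float:
        """Grid-cell radius at which activation drops to ``level``."""
        return (cfg.sigma_pc * cfg.a * math.sqrt(-2.0 * math.log(level))
                / (cfg.s_gate * self.position_gain))


@dataclass
class PlaceCell:
    """Read-only view of one cell, used for export and inspection."""

    id: int
    W_S: np.ndarray
    W_M: np.ndarray
    q_values: np.ndarray
    reactivation_count: int


class PlaceCellNetwork:
    """Growable pool of place cells (stored as arrays for speed)."""

    def __init__(self, cfg: NetworkConfig | None = None):
        self.cfg = cfg or NetworkConfig()
        self._n = 0
        cap = self.cfg.max_cells
        self._W_S = np.zeros((cap, STATE_DIM))
        self._W_M = np.zeros((cap, MEMORY_DIM))
        self._q = np.zeros((cap, N_ACTIONS))
        self._react = np.zeros(cap, dtype=np.int64)
        self.saturation_warnings = 0

    # -- pool views -------------------------------------------------------
    def __len__(self):
        return self._n

    @property
    def W_S(self):
        return self._W_S[:self._n]

    @property
    def W_M(self):
        return self._W_M[:self._n]

    @property
    def q_values(self):
        return self._q[:self._n]

    @property
    def reactivation_counts(self):
        return self._react[:self._n]

    def cell(self, cell_id: int) -> PlaceCell:
        if not 0 <= cell_id < self._n:
            raise IndexError(cell_id)
        return PlaceCell(cell_id, self._W_S[cell_id].copy(),
                         self._W_M[cell_id].copy(), self._q[cell_id].copy(),
                         int(self._react[cell_id]))

    # -- dynamics ---------------------------------------------------------
    def activate(self, s_in: np.ndarray, m_in: float) -> np.ndarray:
        """Firing rates of every cell for a joint (state, memory) input."""
        n = self._n
        if n == 0:
            raise ValueError("empty pool: recruitment required")
        cfg = self.cfg
        diff = self._W_S[:n] - s_in
        d_state = np.sqrt(np.einsum("id,id->i", diff, diff))
        drive = (cfg.s_gate / cfg.a) * d_state
        d_mem = np.abs(self._W_M[:n, 0] - m_in)
        drive += (cfg.m_gate / cfg.b) * d_mem
        drive *= drive
        drive /= -2.0 * cfg.sigma_pc ** 2
        return np.exp(drive)

    @staticmethod
    def winner(rates: np.ndarray) -> int:
        """Index of the most active cell; ties go to the lowest id."""
        if len(rates) == 0:
            raise ValueError("winner undefined for an empty rate vector")
        return int(np.argmax(rates))

    def update_weights(self, cell_id: int, s_in: np.ndarray, m_in: float):
        """Winner-take-all step: move the winner's weights toward the input."""
        delta = self.cfg.delta
        self._W_S[cell_id] += delta * (np.asarray(s_in) - self._W_S[cell_id])
        self._W_M[cell_id] += delta * (float(m_in) - self._W_M[cell_id])

    def recruit(self, s_in: np.ndarray, m_in: float) -> int:
        if self._n >= self.cfg.max_cells:
            raise RuntimeError("pool at max_cells")
        idx = self._n
        self._W_S[idx] = np.asarray(s_in)
        self._W_M[idx] = float(m_in)
        self._n += 1
        return idx

    def observe(self, s_in: np.ndarray, m_in: float = 0.0,
                learn: bool = True):
        """One live presentation: activate, recruit-or-update, return rates.

        Returns ``(rates, winner_id)``.  When the pool is empty or the
        winning activation is below the recruitment threshold (and the
        pool has room), a new cell is recruited at the input and becomes
        the winner with activation 1.  Otherwise the winner's weights are
        moved toward the input (if ``learn``).
        """
        if self._n == 0:
            idx = self.recruit(s_in, m_in)
            return np.ones(1), idx
        rates = self.activate(s_in, m_in)
        win = self.winner(rates)
        if rates[win] < self.cfg.recruit_threshold:
            if self._n < self.cfg.max_cells:
                idx = self.recruit(s_in, m_in)
                rates = np.append(rates, 1.0)
                return rates, idx
            self.saturation_warnings += 1
        if learn:
            self.update_weights(win, s_in, m_in)
        return rates, win

    def preallocate(self, world: GridWorld, encoder: StateEncoder):
        """Seed one cell per free grid cell (heading from the encoder's
        stay convention), in row-major order.  Gives fixed, lattice-like
        place fields; recruitment then never fires for visited states."""
        for cell in sorted(world.free_cells()):
            self.recruit(encoder.encode(world, cell), 0.0)
        return self

    # -- bookkeeping used by replay --------------------------------------
    def add_reactivations(self, cell_ids):
        np.add.at(self._react, np.asarray(cell_ids, dtype=np.int64), 1)

    def assigned_grid_cell(self, cell_id: int, encoder: StateEncoder):
        """Grid cell at a place cell's field centre (rounded)."""
        gain = encoder.position_gain
        x = int(round(self._W_S[cell_id, 0] / gain))
        y = int(round(self._W_S[cell_id, 1] / gain))
        return (x, y)

    # -- serialization ----------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "config": {k: getattr(self.cfg, k) for k in
                       ("sigma_pc", "delta", "s_gate", "m_gate", "a", "b",
                        "recruit_threshold", "activation_floor", "max_cells")},
            "cells": [{
                "id": i,
                "W_S": self._W_S[i].tolist(),
                "W_M": self._W_M[i].tolist(),
                "q_values": self._q[i].tolist(),
                "reactivation_count": int(self._react[i]),
            } for i in range(self._n)],
        }
        text = json.dumps(payload)
        if path is not None:
            with open(path, "w") as handle:
                handle.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PlaceCellNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as handle:
                payload = json.load(handle)
        net = cls(NetworkConfig(**payload["config"]))
        for cell in payload["cells"]:
            idx = net.recruit(np.array(cell["W_S"]), 0.0)
            net._W_M[idx] = np.array(cell["W_M"])
            net._q[idx] = np.array(cell["q_values"])
            net._react[idx] = cell["reactivation_count"]
        return net
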