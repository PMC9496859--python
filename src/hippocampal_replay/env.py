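"""Discrete 2-D water-maze environments.

The task family is a grid-world analogue of the Morris water maze: a
20 x 20 arena with a hidden goal platform, optional obstacles, eight
compass movement actions plus "stay", stochastic action execution (the
intended move is carried out with probability 0.8, otherwise one of the
two compass-adjacent moves is executed), a radius-1 lidar, and a sparse
reward schedule (large positive at the goal, large negative on obstacle
hits, small negative per ordinary step).

Coordinates are 0-based ``(x, y)`` with x rightward and y upward.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "ACTION_NAMES",
    "ACTION_VECTORS",
    "N_ACTIONS",
    "N_MOVES",
    "STAY",
    "GridWorld",
    "ActionOutcome",
    "step",
    "reward_of",
    "lidar_scan",
    "make_maze",
    "load_maze",
    "save_maze",
    "world_from_ascii",
    "world_to_ascii",
    "free_cell_graph",
]

# Compass order, clockwise from north; index 8 is the stay action.
ACTION_NAMES = ("N", "NE", "E", "SE", "S", "SW", "W", "NW", "stay")
ACTION_VECTORS = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
    (0, 0),
)
N_ACTIONS = 9
N_MOVES = 8
STAY = 8

#: Execution probability of the intended movement; the remaining mass is
#: split evenly between the two compass-adjacent movements.
P_INTENDED = 0.8

REWARD_SCHEMES = {
    "standard": {"obstacle": -100.0, "goal": 100.0, "step": -10.0},
    "amplified": {"obstacle": -500.0, "goal": 1000.0, "step": -10.0},
}


def action_angle(action: int) -> float:
    """Compass angle (radians, east = 0, counter-clockwise) of a movement.

    The stay action maps to angle 0 by convention.
    """
    if action == STAY:
        return 0.0
    dx, dy = ACTION_VECTORS[action]
    return math.atan2(dy, dx)


@dataclass(frozen=True)
class GridWorld:
    """A discrete maze: arena geometry, obstacles, start, goal, rewards.

    Invariants checked at construction: start/goal in-grid and free, and
    the goal reachable from the start under 8-connected moves.
    """

    width: int = 20
    height: int = 20
    obstacles: frozenset = field(default_factory=frozenset)
    start: tuple = (2, 2)
    goal: tuple = (16, 16)
    reward_scheme: str = "standard"
    rng_seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "obstacles", frozenset(
            (int(x), int(y)) for x, y in self.obstacles))
        object.__setattr__(self, "start", (int(self.start[0]), int(self.start[1])))
        object.__setattr__(self, "goal", (int(self.goal[0]), int(self.goal[1])))
        if self.reward_scheme not in REWARD_SCHEMES:
            raise ValueError(f"unknown reward scheme {self.reward_scheme!r}")
        for name, cell in (("start", self.start), ("goal", self.goal)):
            if not self.in_grid(cell):
                raise ValueError(f"{name} {cell} outside the {self.width}x{self.height} grid")
            if cell in self.obstacles:
                raise ValueError(f"{name} {cell} lies on an obstacle")
        for cell in self.obstacles:
            if not self.in_grid(cell):
                raise ValueError(f"obstacle {cell} outside the grid")
        if self.bfs_distance(self.start, self.goal) is None:
            raise ValueError("goal is not reachable from start")

    # -- geometry ---------------------------------------------------------
    def in_grid(self, cell) -> bool:
        x, y = cell
        return 0 <= x < self.width and 0 <= y < self.height

    def is_free(self, cell) -> bool:
        return self.in_grid(cell) and tuple(cell) not in self.obstacles

    def free_cells(self):
        return [(x, y) for x in range(self.width) for y in range(self.height)
                if (x, y) not in self.obstacles]

    def bfs_distance(self, source, target):
        """8-connected shortest path length between two free cells, or None."""
        source, target = tuple(source), tuple(target)
        if not (self.is_free(source) and self.is_free(target)):
            return None
        seen = {source: 0}
        queue = deque([source])
        while queue:
            cell = queue.popleft()
            if cell == target:
                return seen[cell]
            x, y = cell
            for dx, dy in ACTION_VECTORS[:N_MOVES]:
                nxt = (x + dx, y + dy)
                if nxt not in seen and self.is_free(nxt):
                    seen[nxt] = seen[cell] + 1
                    queue.append(nxt)
        return None

    @property
    def rewards(self) -> dict:
        return REWARD_SCHEMES[self.reward_scheme]


@dataclass(frozen=True)
class ActionOutcome:
    next_state: tuple
    reward: float
    hit_obstacle: bool
    reached_goal: bool
    executed_action: int


def reward_of(world: GridWorld, *, hit_obstacle: bool = False,
              reached_goal: bool = False) -> float:
    """Reward for one transition under the world's active scheme."""
    scheme = world.rewards
    if hit_obstacle:
        return scheme["obstacle"]
    if reached_goal:
        return scheme["goal"]
    return scheme["step"]


def step(world: GridWorld, state, intended_action: int,
         rng: np.random.Generator) -> ActionOutcome:
    """Execute one (stochastic) action from ``state``.

    The intended movement is executed with probability 0.8; otherwise one
    of its two compass-adjacent movements is executed, chosen uniformly.
    Stay is never perturbed.  A move into an obstacle or off-grid leaves
    the agent in place and earns the obstacle penalty.
    """
    state = tuple(state)
    if not world.is_free(state):
        raise ValueError(f"state {state} is not a free in-grid cell")
    if not 0 <= intended_action < N_ACTIONS:
        raise ValueError(f"action index {intended_action} out of range")

    executed = intended_action
    if intended_action != STAY:
        u = rng.random()
        if u >= P_INTENDED:
            shift = 1 if u < P_INTENDED + (1.0 - P_INTENDED) / 2.0 else -1
            executed = (intended_action + shift) % N_MOVES

    dx, dy = ACTION_VECTORS[executed]
    target = (state[0] + dx, state[1] + dy)
    if executed != STAY and not world.is_free(target):
        return ActionOutcome(state, reward_of(world, hit_obstacle=True),
                             True, False, executed)
    reached = target == world.goal
    return ActionOutcome(target, reward_of(world, reached_goal=reached),
                         False, reached, executed)


def lidar_scan(world: GridWorld, state) -> np.ndarray:
    """Radius-1 occupancy of the 8 neighbours in compass order (1 = blocked).

    Off-grid neighbours read as blocked.  Scans are cached per world
    (worlds are immutable), so repeated calls are dictionary lookups.
    """
    cache = world.__dict__.get("_scan_cache")
    if cache is None:
        cache = {}
        object.__setattr__(world, "_scan_cache", cache)
    state = tuple(state)
    scan = cache.get(state)
    if scan is None:
        x, y = state
        scan = np.array([0.0 if world.is_free((x + dx, y + dy)) else 1.0
                         for dx, dy in ACTION_VECTORS[:N_MOVES]])
        cache[state] = scan
    return scan


# -- maze generation ------------------------------------------------------

def make_maze(kind: str, seed: int = 0, reward_scheme: str = "standard",
              max_retries: int = 50) -> GridWorld:
    """Build one of the 20x20 water-maze task variants.

    kinds: ``open`` (no internal obstacles), ``blocks`` (rectangular
    obstacles between start and goal), ``u_shape`` (a U-shaped trap whose
    opening faces the start), ``complex`` (a seeded corridor maze with
    start at (2, 2) and the goal in the upper-right region — a procedural
    analogue of the published complex maze, not a replica).
    """
    builders = {"open": _open_maze, "blocks": _blocks_maze,
                "u_shape": _u_shape_maze, "complex": _complex_maze}
    if kind not in builders:
        raise ValueError(f"unknown maze kind {kind!r}")
    for attempt in range(max_retries):
        try:
            return builders[kind](int(seed) + attempt, reward_scheme)
        except ValueError:
            continue
    raise RuntimeError(f"could not generate a solvable {kind!r} maze "
                       f"in {max_retries} attempts")


def _open_maze(seed, reward_scheme):
    return GridWorld(20, 20, frozenset(), (2, 2), (16, 16), reward_scheme, seed)


def _blocks_maze(seed, reward_scheme):
    rng = np.random.default_rng(seed)
    obstacles = set()
    # Two or three rectangular blocks strewn across the start->goal diagonal.
    for _ in range(int(rng.integers(2, 4))):
        w, h = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        x0 = int(rng.integers(5, 14 - w))
        y0 = int(rng.integers(5, 14 - h))
        obstacles.update((x0 + i, y0 + j) for i in range(w) for j in range(h))
    obstacles.discard((2, 2))
    obstacles.discard((16, 16))
    return GridWorld(20, 20, frozenset(obstacles), (2, 2), (16, 16),
                     reward_scheme, seed)


def _u_shape_maze(seed, reward_scheme):
    # U-shaped trap between start (lower left) and goal (upper right),
    # its opening facing the start: left wall missing.
    obstacles = set()
    x0, x1, y0, y1 = 7, 12, 7, 12
    obstacles.update((x, y0) for x in range(x0, x1 + 1))   # bottom arm
    obstacles.update((x, y1) for x in range(x0, x1 + 1))   # top arm
    obstacles.update((x1, y) for y in range(y0, y1 + 1))   # back wall
    return GridWorld(20, 20, frozenset(obstacles), (2, 2), (16, 16),
                     reward_scheme, seed)


def _complex_maze(seed, reward_scheme):
    """Recursive-division corridor maze on a 10x10 lattice in the 20x20 grid.

    Lattice nodes sit at even coordinates (2i, 2j); passage cells between
    adjacent nodes start open and recursive division closes all passages
    along each splitting wall except one door.  Corridors are one cell
    wide, branch points (free-graph degree >= 3) are plentiful, and —
    unlike depth-first carving — solution paths stay close to the
    Manhattan distance, as in the published multi-corridor maze.
    """
    rng = np.random.default_rng(seed)
    n = 10
    closed = set()  # closed passages as frozenset of two lattice nodes

    def divide(x0, y0, w, h):
        if w < 2 and h < 2:
            return
        horizontal = h > w or (h == w and rng.random() < 0.5)
        if horizontal and h < 2:
            horizontal = False
        if not horizontal and w < 2:
            horizontal = True
        if horizontal:
            wy = y0 + 1 + int(rng.integers(h - 1))  # wall under row wy
            door = x0 + int(rng.integers(w))
            for x in range(x0, x0 + w):
                if x != door:
                    closed.add(frozenset(((x, wy - 1), (x, wy))))
            divide(x0, y0, w, wy - y0)
            divide(x0, wy, w, y0 + h - wy)
        else:
            wx = x0 + 1 + int(rng.integers(w - 1))
            door = y0 + int(rng.integers(h))
            for y in range(y0, y0 + h):
                if y != door:
                    closed.add(frozenset(((wx - 1, y), (wx, y))))
            divide(x0, y0, wx - x0, h)
            divide(wx, y0, x0 + w - wx, h)

    divide(0, 0, n, n)
    free = {(2 * i, 2 * j) for i in range(n) for j in range(n)}
    for i in range(n):
        for j in range(n):
            for di, dj in ((1, 0), (0, 1)):
                ni, nj = i + di, j + dj
                if ni < n and nj < n and \
                        frozenset(((i, j), (ni, nj))) not in closed:
                    free.add((2 * i + di, 2 * j + dj))
    obstacles = frozenset((x, y) for x in range(20) for y in range(20)
                          if (x, y) not in free)
    return GridWorld(20, 20, obstacles, (2, 2), (16, 16), reward_scheme, seed)


def free_cell_graph(world: GridWorld, connectivity: int = 4):
    """The free-cell adjacency graph (networkx), 4- or 8-connected.

    4-connectivity is the natural notion for classifying corridor-maze
    cells: corridor cells have degree 2, junction cells degree >= 3.
    """
    import networkx as nx

    vectors = (ACTION_VECTORS[0], ACTION_VECTORS[2], ACTION_VECTORS[4],
               ACTION_VECTORS[6]) if connectivity == 4 else ACTION_VECTORS[:N_MOVES]
    graph = nx.Graph()
    graph.add_nodes_from(world.free_cells())
    for x, y in world.free_cells():
        for dx, dy in vectors:
            if world.is_free((x + dx, y + dy)):
                graph.add_edge((x, y), (x + dx, y + dy))
    return graph


# -- serialization --------------------------------------------------------

def save_maze(world: GridWorld, path):
    spec = {
        "width": world.width,
        "height": world.height,
        "obstacles": sorted([list(c) for c in world.obstacles]),
        "start": list(world.start),
        "goal": list(world.goal),
        "reward_scheme": world.reward_scheme,
        "rng_seed": world.rng_seed,
    }
    with open(path, "w") as handle:
        yaml.safe_dump(spec, handle, sort_keys=True)


def load_maze(path) -> GridWorld:
    with open(path) as handle:
        spec = yaml.safe_load(handle)
    return GridWorld(
        width=spec["width"], height=spec["height"],
        obstacles=frozenset(tuple(c) for c in spec["obstacles"]),
        start=tuple(spec["start"]), goal=tuple(spec["goal"]),
        reward_scheme=spec.get("reward_scheme", "standard"),
        rng_seed=spec.get("rng_seed", 0),
    )


def world_from_ascii(art: str, reward_scheme: str = "standard",
                     rng_seed: int = 0) -> GridWorld:
    """Parse a ``#``/``.``/``S``/``G`` maze drawing.

    The top text row is the highest y row (maps are drawn the way they
    are looked at).
    """
    rows = [line for line in art.strip("\n").splitlines()]
    height = len(rows)
    width = max(len(r) for r in rows)
    obstacles, start, goal = set(), None, None
    for row_idx, row in enumerate(rows):
        y = height - 1 - row_idx
        for x, char in enumerate(row):
            if char == "#":
                obstacles.add((x, y))
            elif char == "S":
                start = (x, y)
            elif char == "G":
                goal = (x, y)
    if start is None or goal is None:
        raise ValueError("maze art must mark both S and G")
    return GridWorld(width, height, frozenset(obstacles), start, goal,
                     reward_scheme, rng_seed)


def world_to_ascii(world: GridWorld) -> str:
    rows = []
    for y in reversed(range(world.height)):
        row = []
        for x in range(world.width):
            if (x, y) == world.start:
                row.append("S")
            elif (x, y) == world.goal:
                row.append("G")
            elif (x, y) in world.obstacles:
                row.append("#")
            else:
                row.append(".")
        rows.append("".join(row))
    return "\n".join(rows)


def relocate(world: GridWorld, start=None, goal=None) -> GridWorld:
    """A copy of the world with the platform and/or start moved."""
    return replace(world, start=start or world.start, goal=goal or world.goal)
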