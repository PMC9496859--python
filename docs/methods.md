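# Methods

This note documents the model implemented by `hippocampal_replay`, the
choices made where the design was genuinely open, and what the test suite
does and does not establish.

## Task family

The environment is a discrete Morris-water-maze analogue: a 20 × 20 grid
with a hidden goal platform, optional obstacles, and a radius-1 lidar.
The agent chooses among eight compass movements and "stay". Movement is
stochastic: the intended move executes with probability 0.8, otherwise
one of the two compass-adjacent moves executes (stay is never perturbed).
A move into an obstacle or off the grid leaves the agent in place.
Rewards are constants per transition: −100 / +100 / −10 for obstacle,
goal and ordinary step (standard scheme), or −500 / +1000 / −10
(amplified scheme, used in the comparative experiments to make reward
differences easier to observe). Diagonal moves only check the target
cell, so a diagonal step may cut a wall corner; corridor mazes are built
on a lattice where this has no effect on connectivity.

An episode runs from the start cell until the goal is reached, the
accumulated reward drops to a failure threshold, or a 500-step cap.
The failure threshold is an energy budget. Its default, −3000, allows
roughly 300 ordinary steps in an open arena. In the corridor maze, where
execution noise alone makes the expected cost ≈ −28 per step, the same
*exploration* budget corresponds to a deeper threshold, so the
complex-maze experiments run with −15000 (≈ 500 effective steps, i.e.
the step cap binds). With the open-field default the maze task is not
explorable at all: every agent, including tabular Q-learning, fails to
reach the goal even once in a thousand episodes.

## Place-cell network

Each place cell is a Gaussian unit over a joint input: a 5-component
state channel and a 1-component memory channel,

    v_i = exp( −[ (s_t/a)·‖S − W_S,i‖ + (m_t/b)·|M − W_M,i| ]² / (2 σ_pc²) )

with the published gains s_t = 0.6, m_t = 0.4, dimensions a = 5, b = 1
and field width σ_pc = 0.7. The memory channel is 0 during navigation
and 1 during offline replay, so replay is a distinguishable network
state. Plasticity is winner-take-all: the most active cell moves its
weights toward the input by δ = 0.5 per presentation; ties break to the
lowest cell id. Each cell carries a 9-entry action-value vector — the
value function lives distributed over the map.

**State encoding.** The state vector is
(x·g, y·g, cos θ, sin θ, occupied-neighbour fraction), with θ the
compass angle of the last executed action. The position gain g sets the
spatial resolution of the code: the half-activation field radius is
σ_pc·a·√(2 ln 2)/(s_t·g) grid cells. The default g = 6 gives a radius of
≈ 1.15 cells, chosen so that (i) cells neighbouring along a path share
fields (generalisation), (ii) fields never straddle a corridor wall
(free cells separated by a wall are ≥ 2 apart in the lattice mazes —
larger fields let obstacle penalties and values bleed through walls and
navigation in corridor mazes collapses), and (iii) position dominates
the heading components in the winner competition. An encoder flag can
drop the heading terms, which is how the tabular-reduction analysis
configures purely positional, single-cell fields.

**Recruitment.** A new cell is recruited (weights copied from the input)
when the winning activation falls below a threshold. The threshold
defaults to the striatal filter level θ = 0.5, so recruitment fires
exactly when no existing field covers the state: the map then tiles the
visited arena at field resolution with no dead zones. Any recruitment
level far below the filter level necessarily leaves regions where no
cell passes the filter and no value can be learned (the ratio of
recruitment radius to field radius is √(ln ρ / ln θ) independent of the
input scale), which is why the small published constant ρ = 0.0065 is
retained in the config only as a numerical floor, not as the recruitment
rule. The pool is growable and capped (400 cells by default); when the
cap is reached the winner is updated anyway and a saturation counter
increments.

## Striatal action selection

A binary filter F_i = [v_i > θ], θ = 0.5, picks the cells that
participate in valuation. The state-action value is the filtered mean
Q(s,a) = Σ q_i(a)F_i / ΣF_i, and TD learning applies the shared error
r + γ·max_a′ Q(s′,a′) − Q(s,a) (α = 0.3, γ = 0.9) to every gated cell's
entry for the executed action; cells failing the filter are untouched.
When no cell clears θ, the single most active cell stands in, so the
value function is defined everywhere.

Action choice: on an all-zero value row (cold start) the agent takes a
uniformly random action with probability P = 0.5, otherwise keeps its
current direction — a persistent walk, which explores far faster than
diffusion. Once values exist, selection is ε-greedy (ε = 0.1) with the
greedy argmax ranging over the eight movements (stay is reachable only
through exploration). The agent uses its lidar while exploring: random
picks range over the unblocked movements and a blocked current direction
is re-drawn. In an open arena this changes nothing (nothing is blocked);
in corridor mazes it is the difference between exploring and burning the
failure budget against walls. The tabular baselines have no lidar and
use plain ε-greedy with uniform tie-breaking.

## Memory vault and virtual paths

Every episode is recorded as state–action–reward triples (executed
actions, not intended) plus the winning place cell per step, classified
**high** (goal reached) or **low** (failure threshold / step cap), and
stored in bounded FIFO vaults (high 20, low 50, virtual 50). Low
sequences never replay; they are raw material for construction.

Virtual-path construction splices a low and a high sequence at a shared
place cell: the low prefix up to its *last* visit of the shared cell is
concatenated with the high suffix after its *first* visit. Among
multiple shared cells the one maximising the low prefix is chosen (ties:
longest high suffix, then lowest cell id). Only this prefix-low /
suffix-high combination is ever produced — the reverse splice cannot end
at the goal. The splice is validated for grid adjacency at the junction
(shared place cells can cover more than one grid cell) and rejected
otherwise. Results are deduplicated by their place-cell id tuple.
Construction examines at most 30 (low, high) pairs per consolidation,
newest first, matching the published construction budget.

## Replay and consolidation

After every episode the vault consolidates: virtual paths are refreshed,
then high and virtual sequences are replayed forward, triple by triple,
with the network re-activated from the stored state vectors and the
memory channel driven to 1. Each gated cell receives a standard
Q-learning update; the terminal triple uses a zero bootstrap; input
weights are frozen during replay and every gated (cell, step) event
increments that cell's reactivation count (the quantity drawn in the
signal-propagation maps). One forward pass moves the terminal reward
exactly one step back, so n passes over a length-n corridor reproduce
the λ = 1 eligibility-trace assignment without a trace parameter — this
is verified to 1e−9 against a value-iteration oracle. Per consolidation
the pass count adapts to the longest stored sequence (capped at 50) and
the total TD-step budget is N_iter = 1000, replayed newest-first so a
tight budget is spent on the most recent memories.

Propagation speed is budget-limited: with 500-step stored sequences only
two passes fit in one consolidation, so long wandering successes
propagate their reward over many episodes rather than at once. This is
visible in the corridor maze, where goal-reaching stays rare long after
the first success; with γ = 0.9 the goal signal is in any case barely
distinguishable from the step-cost background beyond ≈ 20 steps.

## Baselines

*Plain Q-learning*: tabular, Watkins' Q(λ) with replacing traces and
λ = 1 (α, γ, ε shared with the main agent). Traces are cut on non-greedy
actions; naive uncut traces were tried first and diverge to overflow on
long noisy episodes, which is the standard failure of off-policy TD(1).
On a fresh table a greedy goal run is never cut, so one episode assigns
the full discounted return along the path (the closed-form property).

*Uniform random experience replay*: tabular Q-learning whose learning
happens entirely through replay of a 10,000-transition ring buffer —
each environment step stores the transition and replays a uniform batch
of 32 with one-step backups against the pre-update table. A buffer of
size 1 therefore degenerates exactly to on-policy Q-learning. Buffer and
batch sizes are not published; these are conventional values and are
exposed in the run configuration.

## Experiments and metrics

Runs are fully deterministic per seed: one Generator drives, in order,
the optional random-start draw, the policy draws and the action
perturbation each step. Per-episode return, steps and success are
logged; the comparison statistic groups returns into consecutive
30-episode blocks (the published block size) and reports the **block
total** reward; the stabilized average is the mean of the last 16 block
totals. (Block totals, not means: the published stabilization values are
several times the goal reward and can only be window aggregates.) The
comparison study trains each agent for 600 episodes with a random start
cell per episode on the amplified-reward open maze, so the stabilization
window covers episodes 121–600 — past the initial learning phase of all
three agents. The relocated-platform study uses standard rewards, start
(2, 2), goal (17, 17), and defines "reliably reaches the platform" as
the first episode whose trailing 30-episode training success rate is
≥ 90%.

Signal maps: per grid cell, strength is the best filtered action value
(normalized to [0, 1] by the map maximum, negatives clipped), and
reactivation sums the replay counts of the cells whose field centre
rounds to that grid cell. Junction analysis classifies free cells by
degree in the 4-connected free-cell graph (junction ≥ 3, corridor = 2);
the complex-maze study runs 900 episodes per seed so that every seed has
goal-reaching episodes to consolidate.

## What the synthetic environments do and do not show

The generators reproduce the published task *family* — open arena,
block obstacles, U-trap, and a 20 × 20 recursive-division corridor maze
with start (2, 2) and the goal in the upper-right region — not the exact
published obstacle layouts, which are printed only as figures. Results
on these mazes therefore test the mechanisms (replay propagation,
virtual-path splicing, junction reactivation), not pixel-level
reproduction. The grid world also idealises away continuous dynamics,
real lidar beam models and 3-D physics, so success here does not imply
performance on a physical robot.

## Known limitations

- With γ = 0.9 and −10 step costs, goals further than ≈ 20 steps sit in
  a nearly flat value landscape; the corridor-maze agent finds and
  consolidates the goal but does not lock into a stable short path.
- The stabilized comparison depends on where the stabilization window
  falls on the learning curve: the replay agent's advantage is learning
  speed, and once all agents converge the tabular baselines are no
  longer dominated.
- Replay-time gating is narrower than live gating (the memory-channel
  mismatch subtracts a fixed 0.4 from the Gaussian drive), so replay
  writes values onto fewer cells than navigation reads from.
- Virtual paths are spliced at exactly one intersection and only from
  real low × high pairs; virtual × virtual recombination is excluded.
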