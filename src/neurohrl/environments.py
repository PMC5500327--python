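"""Continuous-time task environments.

Each environment is a callable usable as a :class:`~neurohrl.nef_core.Node`
function with input = the agent's action vector and output
``[state..., reward, termination_pulse, terminal_flag]``.  Agents interact
with environments only through this port contract; the internal transition
and reward machinery is never exposed to the agent (black-box contract).

Three tasks are provided:

* :class:`GridNavEnv` — a 5x5 grid with a fixed goal; each transition takes a
  random 600-900 ms delay, reward 1 in the goal state and 0 elsewhere.  A
  discrete :class:`GridWorld` core backs the tabular baseline.
* :class:`DeliveryEnv` — a continuous 2D arena; the agent must reach the
  pickup location to collect a package and then the delivery location to be
  rewarded.  Position is encoded by Gaussian place cells; the package flag is
  appended as a two-dimensional one-hot.
* :class:`StimuliEnv` — an 18-stimulus (2 colours x 3 shapes x 3
  orientations) stimulus-response task with flat (arbitrary) or hierarchical
  (colour-selects-rule) response mappings, 500 ms presentations and +-1.5
  feedback pulses of 100 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .nef_core import _stable_seed

PULSE_WIDTH = 0.01
KICKOFF_TIME = 0.3

CARDINALS = {"N": np.array([0.0, 1.0]), "S": np.array([0.0, -1.0]),
             "E": np.array([1.0, 0.0]), "W": np.array([-1.0, 0.0])}
CARDINAL_ORDER = ("N", "S", "E", "W")
CARDINAL_VECTORS = np.array([CARDINALS[k] for k in CARDINAL_ORDER])


def decode_action(x, vectors, threshold=0.3):
    """Nearest action index for a (noisy) action vector, or None if ~zero."""
    x = np.asarray(x, float)
    if np.linalg.norm(x) < threshold:
        return None
    return int(np.argmax(np.asarray(vectors, float) @ x))


# ---------------------------------------------------------------------------
# Grid navigation
# ---------------------------------------------------------------------------

class GridWorld:
    """Discrete core of the navigation task (used by the tabular baseline).

    Cells are (col, row), 0-based, origin bottom-left.  Off-grid moves leave
    the position unchanged.  Reward 1 on entering the goal; episodes end
    there.
    """

    def __init__(self, size: int = 5, goal=(4, 4)):
        self.size = size
        self.goal = tuple(goal)
        self.n_states = size * size
        self.n_actions = 4

    def index(self, cell):
        return cell[0] * self.size + cell[1]

    def cell(self, idx):
        return divmod(idx, self.size)

    def reset(self, rng) -> int:
        while True:
            cell = (rng.integers(self.size), rng.integers(self.size))
            if cell != self.goal:
                return self.index(cell)

    def move(self, cell, a: int):
        d = CARDINAL_VECTORS[a]
        nxt = (int(np.clip(cell[0] + d[0], 0, self.size - 1)),
               int(np.clip(cell[1] + d[1], 0, self.size - 1)))
        return nxt

    def step(self, s: int, a: int):
        nxt = self.move(self.cell(s), a)
        done = nxt == self.goal
        return self.index(nxt), (1.0 if done else 0.0), done

    def manhattan(self, cell) -> int:
        return abs(cell[0] - self.goal[0]) + abs(cell[1] - self.goal[1])


@dataclass
class Trial:
    start: tuple
    steps: int
    optimal: int
    t_end: float

    @property
    def latency(self) -> int:
        return self.steps - self.optimal


class GridNavEnv:
    """Continuous-time wrapper: fixed-point moves with 600-900 ms delays.

    The agent state is the (x, y) cell centre scaled to [-1, 1]^2.  On
    reaching the goal the agent dwells there for one further cycle with
    reward 1 before the episode terminates and restarts from a random cell;
    that dwell step is not counted in the trial's step count.
    """

    def __init__(self, size: int = 5, goal=(4, 4), delay=(0.6, 0.9),
                 seed: int = 0):
        self.world = GridWorld(size, goal)
        self.delay = delay
        self.rng = np.random.default_rng(_stable_seed(seed, "gridnav"))
        self.state_dim = 2
        self.size_in = 2
        self.action_vectors = CARDINAL_VECTORS
        self.trials: list[Trial] = []
        self.pos = self.world.cell(self.world.reset(self.rng))
        self._start = self.pos
        self._steps = 0
        self.in_goal = False
        self._next_t = KICKOFF_TIME
        self._pulse_until = -1.0
        self._terminal = False
        self._out = np.zeros(2 + 3)

    def _scaled(self, cell):
        s = self.world.size - 1
        return np.array([cell[0] / s * 2 - 1, cell[1] / s * 2 - 1])

    def sample_delay(self):
        return self.rng.uniform(*self.delay)

    def __call__(self, t, x):
        if t >= self._next_t:
            self._terminal = False
            if self.in_goal:
                # goal dwell complete: episode ends, restart
                self.trials.append(Trial(self._start, self._steps,
                                         self.world.manhattan(self._start),
                                         t))
                self.pos = self.world.cell(self.world.reset(self.rng))
                self._start = self.pos
                self._steps = 0
                self.in_goal = False
                self._terminal = True
            else:
                a = decode_action(x, self.action_vectors)
                if a is not None:
                    self.pos = self.world.move(self.pos, a)
                if t > KICKOFF_TIME:
                    self._steps += 1
                if self.pos == self.world.goal:
                    self.in_goal = True
            self._pulse_until = t + PULSE_WIDTH
            self._next_t = t + self.sample_delay()
        out = self._out
        out[:2] = self._scaled(self.pos)
        out[2] = 1.0 if self.in_goal else 0.0
        out[3] = 1.0 if t < self._pulse_until else 0.0
        out[4] = 1.0 if (t < self._pulse_until and self._terminal) else 0.0
        return out


# ---------------------------------------------------------------------------
# Delivery task
# ---------------------------------------------------------------------------

@dataclass
class DeliveryConfig:
    n_cells: int = 36
    cell_width: float = 0.15
    pickup: tuple = (0.25, 0.75)
    dropoff: tuple = (0.75, 0.25)
    region_radius: float = 0.15
    step_length: float = 0.25
    delay: tuple = (0.6, 0.9)
    reward: float = 1.5


def place_cell_encode(position, centres, width: float) -> np.ndarray:
    """Gaussian place-cell activations: ``exp(-||p - c||^2 / (2 w^2))``."""
    p = np.asarray(position, float)
    d2 = np.sum((np.asarray(centres, float) - p) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width ** 2))


class DeliveryEnv:
    """Continuous 2D pickup-and-delivery with place-cell state encoding.

    State = place-cell activations concatenated with the package flag
    ([1, 0] = empty-handed, [0, 1] = carrying).  Entering the pickup region
    collects the package; entering the dropoff region while carrying starts a
    one-cycle reward dwell, after which the episode resets to a random
    position.
    """

    NO_PACKAGE = np.array([1.0, 0.0])
    PACKAGE = np.array([0.0, 1.0])

    def __init__(self, config: Optional[DeliveryConfig] = None, seed: int = 0,
                 geometry_seed: int = 0, dt: float = 0.001):
        self.cfg = config or DeliveryConfig()
        self.dt = dt
        self.rng = np.random.default_rng(_stable_seed(seed, "delivery"))
        # geometry (place-cell centres) is seeded separately so it can be
        # held fixed across runs
        grng = np.random.default_rng(_stable_seed(geometry_seed, "cells"))
        self.centres = grng.uniform(0, 1, size=(self.cfg.n_cells, 2))
        self.state_dim = self.cfg.n_cells + 2
        self.size_in = 2
        self.action_vectors = CARDINAL_VECTORS
        self.pos = self.rng.uniform(0, 1, 2)
        self.package = False
        self.rewarding = False
        self._terminal = False
        self._next_t = KICKOFF_TIME
        self._pulse_until = -1.0
        self.deliveries: list[float] = []
        self.pickups: list[float] = []
        self.cum_reward = 0.0
        self.reward_series: list[tuple] = []
        self._series_next = 0.0
        self._out = np.zeros(self.state_dim + 3)

    # -- encoding helpers -------------------------------------------------
    def encode_position(self, p) -> np.ndarray:
        return place_cell_encode(p, self.centres, self.cfg.cell_width)

    def state_of(self, p, package: bool) -> np.ndarray:
        flag = self.PACKAGE if package else self.NO_PACKAGE
        return np.concatenate([self.encode_position(p), flag])

    def sample_states(self, n, rng, extra_dims: int = 0) -> np.ndarray:
        """Representative states for Q-population encoder sampling."""
        base = self.cfg.n_cells + 2  # place cells + package flag
        out = np.zeros((n, base + extra_dims))
        for i in range(n):
            s = self.state_of(rng.uniform(0, 1, 2), rng.random() < 0.5)
            if extra_dims:
                c = np.zeros(extra_dims)
                c[rng.integers(extra_dims)] = 1.0
                s = np.concatenate([s, c])
            out[i] = s
        return out

    def in_region(self, p, centre) -> bool:
        return bool(np.linalg.norm(np.asarray(p) - np.asarray(centre))
                    < self.cfg.region_radius)

    def sample_delay(self):
        return self.rng.uniform(*self.cfg.delay)

    # -- dynamics ---------------------------------------------------------
    def _move(self, pos, a):
        if a is None:
            return pos
        return np.clip(pos + self.cfg.step_length * CARDINAL_VECTORS[a], 0, 1)

    def __call__(self, t, x):
        reward_now = self.cfg.reward if self.rewarding else 0.0
        self.cum_reward += reward_now * self.dt
        if t >= self._series_next:
            self.reward_series.append((t, self.cum_reward))
            self._series_next = t + 1.0
        if t >= self._next_t:
            self._terminal = False
            if self.rewarding:
                self.rewarding = False
                self.package = False
                self.pos = self.rng.uniform(0, 1, 2)
                self._terminal = True
            else:
                a = decode_action(x, self.action_vectors)
                self.pos = self._move(self.pos, a)
                if not self.package and self.in_region(self.pos, self.cfg.pickup):
                    self.package = True
                    self.pickups.append(t)
                elif self.package and self.in_region(self.pos, self.cfg.dropoff):
                    self.rewarding = True
                    self.deliveries.append(t)
            self._pulse_until = t + PULSE_WIDTH
            self._next_t = t + self.sample_delay()
        out = self._out
        key = (self.pos[0], self.pos[1], self.package)
        if getattr(self, "_state_key", None) != key:
            out[:self.state_dim] = self.state_of(self.pos, self.package)
            self._state_key = key
        out[self.state_dim] = self.cfg.reward if self.rewarding else 0.0
        out[self.state_dim + 1] = 1.0 if t < self._pulse_until else 0.0
        out[self.state_dim + 2] = (1.0 if (t < self._pulse_until and
                                           self._terminal) else 0.0)
        return out

    # -- scripted (non-neural) baselines ----------------------------------
    def optimal_steps(self, start, target) -> int:
        """Minimum number of cardinal steps from ``start`` into the target
        region (breadth-first over the reachable step lattice)."""
        from collections import deque
        start = tuple(np.round(np.asarray(start, float), 6))
        q = deque([(start, 0)])
        seen = {start}
        while q:
            p, k = q.popleft()
            if self.in_region(p, target):
                return k
            if k > 40:
                continue
            for a in range(4):
                nxt = tuple(np.round(self._move(np.asarray(p), a), 6))
                if nxt not in seen:
                    seen.add(nxt)
                    q.append((nxt, k + 1))
        return 10_000  # target region unreachable within the search budget

    def mean_optimal_iteration_time(self) -> float:
        """Analytic time for an optimal agent to go pickup -> delivery."""
        steps = self.optimal_steps(self.cfg.pickup, self.cfg.dropoff)
        return steps * float(np.mean(self.cfg.delay))


def scripted_delivery_run(cfg: DeliveryConfig, policy: str, duration: float,
                          seed: int = 0):
    """Event-level simulation of a scripted policy on the delivery task.

    ``policy`` is "random" (uniform cardinal moves) or "optimal" (always the
    action moving closest to the current target).  Returns ``(times, cum)``
    sampled at each decision, for reward-baseline and optimal-slope
    estimation.  Reward accrues exactly as in the neural-time version: one
    full decision interval of reward per delivery.
    """
    env = DeliveryEnv(cfg, seed=seed)
    rng = np.random.default_rng(_stable_seed(seed, "scripted", policy))
    t = 0.0
    pos = rng.uniform(0, 1, 2)
    package = False
    cum = 0.0
    times, series = [0.0], [0.0]
    plan_cache: dict = {}

    def plan_steps(p, target):
        # shortest path length to the target region over the move graph
        # (wall clamping can realign the step lattice with the target)
        key = (round(p[0], 4), round(p[1], 4), tuple(target))
        if key not in plan_cache:
            plan_cache[key] = env.optimal_steps(p, target)
        return plan_cache[key]

    while t < duration:
        delay = rng.uniform(*cfg.delay)
        if policy == "random":
            a = rng.integers(4)
        else:
            target = cfg.pickup if not package else cfg.dropoff
            costs = [plan_steps(env._move(pos, a2), target) for a2 in range(4)]
            a = int(np.argmin(costs))
        pos = env._move(pos, a)
        t += delay
        if not package and env.in_region(pos, cfg.pickup):
            package = True
        elif package and env.in_region(pos, cfg.dropoff):
            # reward dwell: one decision interval of reward, then reset
            dwell = rng.uniform(*cfg.delay)
            cum += cfg.reward * dwell
            t += dwell
            package = False
            pos = rng.uniform(0, 1, 2)
        times.append(t)
        series.append(cum)
    return np.asarray(times), np.asarray(series)


class ContextNavEnv(DeliveryEnv):
    """Randomised-context navigation (pretraining for transfer).

    The same arena and encoding as the delivery task, but the environment
    itself picks a target (pickup or dropoff location) each episode and
    appends the corresponding context one-hot to the state.  Reward is the
    subgoal schedule of the delivery hierarchy: +1.5 inside the commanded
    region, -0.05 elsewhere.  This recreates the subgoal structure of the
    delivery task's lower layer without its upper-layer policy.
    """

    def __init__(self, config=None, seed: int = 0, geometry_seed: int = 0,
                 r_plus: float = 1.5, r_minus: float = -0.05,
                 dt: float = 0.001):
        super().__init__(config, seed=seed, geometry_seed=geometry_seed, dt=dt)
        self.r_plus, self.r_minus = r_plus, r_minus
        self.state_dim = self.cfg.n_cells + 2 + 2
        self.targets = [np.asarray(self.cfg.pickup),
                        np.asarray(self.cfg.dropoff)]
        self.context = int(self.rng.integers(2))
        self.package = bool(self.rng.random() < 0.5)
        self.arrivals: list[float] = []
        self._out = np.zeros(self.state_dim + 3)

    def full_state(self) -> np.ndarray:
        c = np.zeros(2)
        c[self.context] = 1.0
        return np.concatenate([self.state_of(self.pos, self.package), c])

    def sample_states(self, n, rng, extra_dims: int = 0):
        return super().sample_states(n, rng, extra_dims=2)

    def __call__(self, t, x):
        if t >= self._next_t:
            self._terminal = False
            if self.rewarding:
                self.rewarding = False
                self.pos = self.rng.uniform(0, 1, 2)
                self.context = int(self.rng.integers(2))
                self.package = bool(self.rng.random() < 0.5)
                self._terminal = True
            else:
                a = decode_action(x, self.action_vectors)
                self.pos = self._move(self.pos, a)
                if self.in_region(self.pos, self.targets[self.context]):
                    self.rewarding = True
                    self.arrivals.append(t)
            self._pulse_until = t + PULSE_WIDTH
            self._next_t = t + self.sample_delay()
        out = self._out
        key = (self.pos[0], self.pos[1], self.package, self.context)
        if getattr(self, "_state_key", None) != key:
            out[:self.state_dim] = self.full_state()
            self._state_key = key
        out[self.state_dim] = self.r_plus if self.rewarding else self.r_minus
        out[self.state_dim + 1] = 1.0 if t < self._pulse_until else 0.0
        out[self.state_dim + 2] = (1.0 if (t < self._pulse_until and
                                           self._terminal) else 0.0)
        return out


# ---------------------------------------------------------------------------
# Hierarchical stimuli task
# ---------------------------------------------------------------------------

@dataclass
class StimuliTrial:
    index: int
    stimulus: tuple     # (colour, shape, orientation)
    action: Optional[int]
    correct: bool
    t_end: float


class StimuliEnv:
    """18-stimulus stimulus-response task with flat or rule-based mappings.

    Stimuli are encoded as concatenated one-hots over colour (2), shape (3)
    and orientation (3) — an 8-dimensional state.  Each stimulus is shown for
    500 ms; the response latched at that point is then rewarded +-1.5 for
    100 ms, and a new stimulus is drawn uniformly.

    In ``hier`` mode one (seeded) colour makes the correct button follow the
    shape index and the other colour the orientation index; in ``flat`` mode
    every stimulus has its own seeded random button.
    """

    N_COLOURS, N_SHAPES, N_ORIENT = 2, 3, 3
    PRESENT = 0.5
    FEEDBACK = 0.1
    REWARD = 1.5
    # upper-layer rule actions: shape rule, orientation rule, no rule
    RULE_VECTORS = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]])
    RULE_SHAPE, RULE_ORIENT, RULE_NONE = 0, 1, 2

    def __init__(self, mapping: str = "hier", seed: int = 0):
        if mapping not in ("hier", "flat"):
            raise ValueError("mapping must be 'hier' or 'flat'")
        self.mapping = mapping
        self.rng = np.random.default_rng(_stable_seed(seed, "stimuli"))
        self.state_dim = 8
        self.size_in = 3
        self.action_vectors = np.eye(3)
        # which colour is governed by the orientation rule (seeded choice)
        self.orient_colour = int(self.rng.integers(2))
        self.flat_map = {s: int(self.rng.integers(3))
                         for s in self._all_stimuli()}
        self.trials: list[StimuliTrial] = []
        self.stimulus = self._draw()
        self._trial_start = 0.0
        self._reward = 0.0
        self.in_feedback = False
        self._checked = False
        self._pulse_until = -1.0
        self._out = np.zeros(self.state_dim + 3)

    def _all_stimuli(self):
        return [(c, s, o) for c in range(self.N_COLOURS)
                for s in range(self.N_SHAPES) for o in range(self.N_ORIENT)]

    def _draw(self):
        return (int(self.rng.integers(self.N_COLOURS)),
                int(self.rng.integers(self.N_SHAPES)),
                int(self.rng.integers(self.N_ORIENT)))

    def encode(self, stim) -> np.ndarray:
        c, s, o = stim
        v = np.zeros(8)
        v[c] = 1.0
        v[2 + s] = 1.0
        v[5 + o] = 1.0
        return v

    def correct_button(self, stim) -> int:
        if self.mapping == "flat":
            return self.flat_map[stim]
        c, s, o = stim
        return o if c == self.orient_colour else s

    def rule_button(self, rule: int, stim=None) -> Optional[int]:
        """The button a given rule prescribes for a stimulus."""
        stim = stim or self.stimulus
        if rule == self.RULE_SHAPE:
            return stim[1]
        if rule == self.RULE_ORIENT:
            return stim[2]
        return None

    @property
    def state_mask(self) -> np.ndarray:
        """Inhibition mask (d_state x d_rule_action) for state abstraction.

        The shape rule inhibits colour and orientation dimensions; the
        orientation rule inhibits colour and shape dimensions; the null
        action (zero vector) inhibits nothing.
        """
        M = np.zeros((8, 2))
        M[[0, 1, 5, 6, 7], 0] = 1.0   # shape rule: keep shape block only
        M[[0, 1, 2, 3, 4], 1] = 1.0   # orientation rule: keep orientation
        return M

    def __call__(self, t, x):
        tt = t - self._trial_start
        if tt >= self.PRESENT and not self._checked:
            a = decode_action(x, self.action_vectors)
            correct = (a is not None and
                       a == self.correct_button(self.stimulus))
            self.trials.append(StimuliTrial(len(self.trials), self.stimulus,
                                            a, bool(correct),
                                            self._trial_start + self.PRESENT
                                            + self.FEEDBACK))
            self._reward = self.REWARD if correct else -self.REWARD
            self._checked = True
            self.in_feedback = True
        if tt >= self.PRESENT + self.FEEDBACK:
            self.stimulus = self._draw()
            self._trial_start = t
            self._reward = 0.0
            self._checked = False
            self.in_feedback = False
            self._pulse_until = t + PULSE_WIDTH
        out = self._out
        out[:8] = self.encode(self.stimulus)
        out[8] = self._reward
        out[9] = 1.0 if t < self._pulse_until else 0.0
        out[10] = 0.0
        return out
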