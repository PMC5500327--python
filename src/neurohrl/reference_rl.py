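"""Non-neural reference agents.

* :class:`TabularQ` — classical table-based Q-learning with the standard
  one-step update ``Q(s,a) += alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))``,
  used as the algorithmic baseline on the grid task.  Transition delays do
  not enter the update, so the variable-delay version of the task is
  identical to the instantaneous one from this agent's point of view.
* direct (perfect-precision) helpers — exact argmax selection with sampled
  Gaussian exploration noise and the closed-form integrative-discount TD
  error.  The full perfect-precision agent (neural Q populations, exact
  selection and error calculation) is built by passing
  ``precision="direct"`` to the layer configuration; see
  :class:`neurohrl.hierarchy.DirectController`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .environments import GridWorld, Trial
from .error_calculation import td_error_integrative
from .nef_core import _stable_seed


@dataclass
class TabularQ:
    n_states: int
    n_actions: int
    alpha: float = 0.2
    gamma: float = 0.9          # per-decision discount
    epsilon: float = 0.1
    seed: int = 0
    Q: np.ndarray = None

    def __post_init__(self):
        if self.Q is None:
            self.Q = np.zeros((self.n_states, self.n_actions))
        self.rng = np.random.default_rng(_stable_seed(self.seed, "tabular"))

    def select(self, s: int) -> int:
        if self.rng.random() < self.epsilon:
            return int(self.rng.integers(self.n_actions))
        q = self.Q[s]
        best = np.flatnonzero(q == q.max())
        return int(self.rng.choice(best))

    def greedy(self, s: int) -> int:
        return int(np.argmax(self.Q[s]))

    def update(self, s: int, a: int, r: float, s2: int, done: bool) -> float:
        """One TD update; returns the applied change of Q(s, a)."""
        boot = 0.0 if done else self.gamma * self.Q[s2].max()
        delta = r + boot - self.Q[s, a]
        self.Q[s, a] += self.alpha * delta
        return self.alpha * delta


def run_tabular_grid(n_trials: int = 100, seed: int = 0,
                     world: Optional[GridWorld] = None,
                     alpha: float = 0.2, gamma: float = 0.9,
                     epsilon: float = 0.1, delay=(0.6, 0.9),
                     max_steps: int = 500):
    """Event-level run of the tabular agent on the variable-delay grid.

    Returns ``(agent, trials)`` where each trial records steps taken versus
    the Manhattan-optimal count.  Delays are sampled (to keep simulated-time
    bookkeeping comparable with the neural agent) but play no algorithmic
    role.
    """
    world = world or GridWorld()
    agent = TabularQ(world.n_states, world.n_actions, alpha, gamma, epsilon,
                     seed)
    rng = np.random.default_rng(_stable_seed(seed, "tabular-env"))
    trials = []
    t = 0.0
    for _ in range(n_trials):
        s = world.reset(rng)
        start = world.cell(s)
        steps = 0
        done = False
        while not done and steps < max_steps:
            a = agent.select(s)
            s2, r, done = world.step(s, a)
            agent.update(s, a, r, s2, done)
            s = s2
            steps += 1
            t += rng.uniform(*delay)
        trials.append(Trial(start, steps, world.manhattan(start), t))
    return agent, trials


def value_iteration(world: GridWorld, gamma: float = 0.9, tol: float = 1e-10,
                    max_iter: int = 10_000) -> np.ndarray:
    """Exact Q values of the grid MDP (oracle for convergence tests)."""
    Q = np.zeros((world.n_states, world.n_actions))
    goal = world.index(world.goal)
    for _ in range(max_iter):
        Qn = np.empty_like(Q)
        for s in range(world.n_states):
            if s == goal:
                Qn[s] = 0.0
                continue
            for a in range(world.n_actions):
                s2, r, done = world.step(s, a)
                Qn[s, a] = r + (0.0 if done else gamma * Q[s2].max())
        if np.abs(Qn - Q).max() < tol:
            return Qn
        Q = Qn
    return Q


def direct_select(Q, sigma: float, rng) -> int:
    """Exact noisy-greedy selection: argmax of Gaussian-perturbed Q values."""
    Q = np.asarray(Q, float)
    if sigma > 0:
        Q = Q + sigma * rng.standard_normal(Q.size)
    return int(np.argmax(Q))


def direct_delta(r_acc, q_sa, q_spap, d_acc, terminal=False) -> float:
    """Closed-form integrative-discount TD error (perfect precision)."""
    return td_error_integrative(r_acc, q_sa, q_spap, d_acc, terminal)
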