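"""Composition of SMDP reinforcement-learning layers into a hierarchy.

A :class:`Layer` is one complete semi-Markov RL agent: a dual-training
Q network, a basal-ganglia action-selection circuit with a selection latch,
and an error-calculation network, sequenced by a cycle timer that converts
action-termination events into the TD-application and state/selection-update
windows of one SMDP cycle.

Layers are composed strictly through their ordinary ports — state input,
reward input, action output, termination events — so each layer runs its own
flat RL problem and the layers above and below it are just part of its
environment.  Three interaction styles are supported:

* **context** — the upper layer's action vector is appended to the lower
  layer's state, so the lower layer can learn context-dependent values;
* **state** — the upper layer's action vector inhibits (masks) irrelevant
  state dimensions, shrinking the lower layer's effective state space;
* **reward** — the upper layer's action defines a subgoal, and the lower
  layer's reward input is replaced by a pseudoreward that pays for reaching
  it (and a small penalty elsewhere).

Removing the upper layer and its interactions yields exactly the flat agent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from . import nef_core as nef
from . import action_values as av
from . import action_selection as asel
from . import error_calculation as ec
from .nef_core import Network, Node, _stable_seed


# ---------------------------------------------------------------------------
# Cycle timing
# ---------------------------------------------------------------------------

@dataclass
class Timing:
    """Windows (s, relative to a termination edge) of one SMDP cycle.

    The new winner is read and the TD error applied while the state memory
    still holds the pre-transition state; the latch/memory/accumulator
    updates follow in the load window.  ``learning-rate x td_width`` sets the
    effective TD step size.
    """

    td_start: float = 0.13
    td_width: float = 0.05
    load_start: float = 0.19
    load_width: float = 0.10


class Pacemaker:
    """Converts termination pulses into [td_gate, load_gate, qcur_suppress].

    The first termination after start-up and after an episode reset only
    latches a selection (no TD pulse), since the stored state/selection do
    not describe a real transition then.
    """

    def __init__(self, timing: Timing):
        self.tm = timing
        self.edge_t = None
        self.prev = 0.0
        self.skip_next = True
        self.cur_skip = True
        self.terminal = False
        self.out = np.zeros(3)

    def __call__(self, t, x):
        pulse, terminal = x[0], x[1]
        if pulse > 0.5 and self.prev <= 0.5:
            self.edge_t = t
            self.cur_skip = self.skip_next
            self.skip_next = terminal > 0.5  # post-reset transition is not real
            self.terminal = terminal > 0.5
        self.prev = pulse
        td = load = sup = 0.0
        if self.edge_t is not None:
            dt_e = t - self.edge_t
            tm = self.tm
            if tm.td_start <= dt_e < tm.td_start + tm.td_width and not self.cur_skip:
                td = 1.0
                if self.terminal:
                    sup = 1.0
            if tm.load_start <= dt_e < tm.load_start + tm.load_width:
                load = 1.0
        self.out[:] = (td, load, sup)
        return self.out


class _Recorder:
    """Logs one record per applied TD update: (t, action, delta)."""

    def __init__(self, n_actions):
        self.n = n_actions
        self.records = []
        self._in = False
        self._best = 0.0
        self._act = 0

    def __call__(self, t, x):
        td = x[0]
        if td > 0.5:
            if not self._in:
                self._in = True
                self._best = 0.0
                self._act = int(np.argmax(x[1:1 + self.n]))
            d = x[1 + self.n]
            if abs(d) > abs(self._best):
                self._best = d
        elif self._in:
            self._in = False
            self.records.append((t, self._act, self._best))
        return 0.0


# ---------------------------------------------------------------------------
# Layer
# ---------------------------------------------------------------------------

@dataclass
class LayerConfig:
    n_actions: int
    action_vectors: np.ndarray          # (n_actions, d_action)
    theta: float = 0.2                  # consistency threshold (state units)
    q_neurons: int = 500
    bg_neurons: int = 100   # per selection channel
    mem_neurons: int = 80   # per channel of the stored-state memory
    relay_neurons: int = 100
    integ_neurons: int = 150
    out_pop_neurons: int = 40
    kappa_td: float = 5e-4
    kappa_cons: float = 5e-4
    gamma: float = 0.3                  # continuous discount rate (1/s)
    sigma: float = 0.05                 # exploration noise std (Q units)
    # noise correlation time: long enough that the perturbed preference is
    # stable across one selection cycle (latch window included)
    noise_tau: float = 0.25
    state_radius: float = 1.5
    # Q-population intercept range; positive-only intercepts give a sparse,
    # decorrelated code for sparse/categorical state vectors
    q_intercepts: tuple = (-1.0, 1.0)
    acc_radius: float = 1.5
    d_acc_radius: float = 1.0
    delta_radius: float = 2.5
    bg_input_bias: float = 0.5
    bg_input_scale: float = 0.5
    bias_scale: float = 1.0             # scale on Q-population bias currents
    out_pop_zero_aligned: bool = False  # for non-negative action vectors
    timing: Timing = field(default_factory=Timing)
    precision: str = "neural"           # "neural" | "direct"


@dataclass
class Layer:
    name: str
    cfg: LayerConfig
    pace: Node
    dual: av.DualQNetwork
    sel: Optional[asel.SelectionNetwork]
    err: Optional[ec.ErrorNetwork]
    out_pop: nef.ChannelGroup           # population representing the action vector
    action_signal: object               # decoded action vector (= out_pop)
    held_one_hot: object                # latched selection signal
    recorder: Optional[_Recorder]
    direct: Optional["DirectController"] = None

    @property
    def decisions(self):
        if self.direct is not None:
            return self.direct.records
        return self.recorder.records


def build_layer(net: Network, name: str, cfg: LayerConfig, state_source,
                d_state: int, reward_source, term_source, term_transform,
                encoder_samples=None, initial_prev=None,
                initial_cur=None) -> Layer:
    """Assemble one SMDP layer and wire its internal components.

    ``term_source``/``term_transform`` select the two-dimensional
    ``[termination_pulse, terminal_flag]`` signal driving the cycle timer.
    """
    A = cfg.n_actions
    if cfg.precision == "direct":
        return _build_layer_direct(net, name, cfg, state_source, d_state,
                                   reward_source, term_source, term_transform,
                                   encoder_samples, initial_prev, initial_cur)

    pace = net.node(f"{name}.pace", Pacemaker(cfg.timing), size_in=2,
                    size_out=3)
    net.connect(term_source, pace, transform=term_transform, synapse=None)

    dual = av.build_dual_q(net, name, state_source, d_state, A,
                           e_td_source=None, gate_node=pace, theta=cfg.theta,
                           q_neurons=cfg.q_neurons,
                           mem_neurons=cfg.mem_neurons,
                           kappa_td=cfg.kappa_td, kappa_cons=cfg.kappa_cons,
                           state_radius=cfg.state_radius,
                           encoder_samples=encoder_samples,
                           initial_prev=initial_prev, initial_cur=initial_cur,
                           bias_scale=cfg.bias_scale,
                           intercepts=cfg.q_intercepts)

    sel = asel.build_basal_ganglia(net, f"{name}.bg", dual.cur_out, A,
                                   n_neurons=cfg.bg_neurons,
                                   input_bias=cfg.bg_input_bias,
                                   input_scale=cfg.bg_input_scale,
                                   noise_sigma=cfg.sigma,
                                   noise_tau=cfg.noise_tau)
    asel.add_latch(net, f"{name}.latch", sel, cfg.action_vectors)
    net.connect(pace, sel.latch_load, transform=[[0, 1.0, 0]], synapse=None)

    err = ec.build_error_network(net, f"{name}.err", dual.prev_out,
                                 dual.cur_out, reward_source,
                                 held_one_hot=sel.latch,
                                 current_one_hot=sel.thalamus,
                                 gate_node=pace, n_actions=A,
                                 gamma=cfg.gamma,
                                 relay_neurons=cfg.relay_neurons,
                                 integ_neurons=cfg.integ_neurons,
                                 acc_radius=cfg.acc_radius,
                                 d_acc_radius=cfg.d_acc_radius,
                                 delta_radius=cfg.delta_radius)
    dual.prev_out.error = err.e_td  # close the learning loop

    out_pop = _make_out_pop(net, name, cfg)
    net.connect(sel.action_node, out_pop, transform=1.0, synapse=nef.TAU_FAST)

    rec = _Recorder(A)
    rnode = net.node(f"{name}.recorder", rec, size_in=A + 2, size_out=1)
    T = np.zeros((A + 2, 3))
    T[0, 0] = 1.0
    net.connect(pace, rnode, transform=T, synapse=None)
    T = np.zeros((A + 2, A))
    T[1:1 + A] = np.eye(A)
    net.connect(sel.latch, rnode, transform=T, synapse=nef.TAU_FAST)
    T = np.zeros((A + 2, 1))
    T[A + 1, 0] = 1.0
    net.connect(err.delta, rnode, transform=T, synapse=nef.TAU_FAST)

    return Layer(name, cfg, pace, dual, sel, err, out_pop, out_pop,
                 sel.latch, rec)


def _make_out_pop(net: Network, name: str, cfg: LayerConfig):
    """Population representing the layer's output action vector.

    When the action vectors are non-negative (context one-hots, gating
    masks), the firing intercepts are aligned away from zero so the null
    action is represented by silence — giving clean downstream inhibition and
    making the population's firing rate track the action magnitude.
    """
    d = np.asarray(cfg.action_vectors).shape[1]
    if cfg.out_pop_zero_aligned:
        return net.channels(f"{name}.action_out", d, cfg.out_pop_neurons,
                            intercepts=(0.02, 0.95), encoders="positive",
                            radius=1.0)
    return net.channels(f"{name}.action_out", d, cfg.out_pop_neurons,
                        radius=1.2)


# ---------------------------------------------------------------------------
# Perfect-precision (direct) layer
# ---------------------------------------------------------------------------

class DirectController:
    """Exact action selection and error calculation over a neural Q function.

    The Q populations and their PES-trained decoders stay neural; selection
    (argmax over noise-perturbed decoded Q values), the reward/discount
    integrals, the consistency gate and the TD error are computed in exact
    arithmetic.  Output layout: ``[E_td | E_cons | one_hot | s_prev]``.
    """

    def __init__(self, cfg: LayerConfig, d_state: int, seed: int, dt: float):
        self.cfg = cfg
        self.d = d_state
        self.dt = dt
        self.rng = np.random.default_rng(seed)
        A = cfg.n_actions
        self.s_prev = np.zeros(d_state)
        self.held = 0
        self.have_held = False
        self.R = 0.0
        self.D = 0.0
        self.prev_pulse = 0.0
        self.edge_t = None
        self.pending = None
        self.records = []
        self.out = np.zeros(2 * A + A + d_state)

    def __call__(self, t, x):
        cfg, A, d = self.cfg, self.cfg.n_actions, self.d
        state = x[:d]
        reward = x[d]
        pulse, terminal = x[d + 1], x[d + 2]
        cur_q = x[d + 3: d + 3 + A]
        prev_q = x[d + 3 + A: d + 3 + 2 * A]
        tm = cfg.timing

        if pulse > 0.5 and self.prev_pulse <= 0.5:
            a_new = int(np.argmax(cur_q + cfg.sigma * self.rng.standard_normal(A)))
            if self.have_held:
                boot = 0.0 if terminal > 0.5 else cur_q[a_new]
                delta = self.R + boot - prev_q[self.held] - self.D
                self.records.append((t, self.held, delta))
            else:
                delta = None
            self.pending = (t, a_new, delta, state.copy())
            self.edge_t = t
            if terminal > 0.5:
                self.have_held = False  # post-reset transition is not real
        self.prev_pulse = pulse

        e_td = np.zeros(A)
        in_td = False
        if self.pending is not None:
            t0, a_new, delta, s_at = self.pending
            dt_e = t - t0
            if delta is not None and tm.td_start <= dt_e < tm.td_start + tm.td_width:
                e_td[self.held] = delta
                in_td = True
            if dt_e >= tm.load_start:
                self.held = a_new
                self.have_held = True
                self.s_prev = s_at
                self.R = 0.0
                self.D = 0.0
                self.pending = None

        if self.have_held:
            self.R += reward * self.dt
            self.D += cfg.gamma * prev_q[self.held] * self.dt

        e_cons = np.zeros(A)
        if not in_td and np.linalg.norm(state - self.s_prev) < cfg.theta:
            e_cons = prev_q - cur_q

        one_hot = np.zeros(A)
        one_hot[self.held] = 1.0 if self.have_held else 0.0
        self.out[:A] = e_td
        self.out[A: 2 * A] = e_cons
        self.out[2 * A: 3 * A] = one_hot
        self.out[3 * A:] = self.s_prev
        return self.out


def _build_layer_direct(net, name, cfg, state_source, d_state, reward_source,
                        term_source, term_transform, encoder_samples,
                        initial_prev, initial_cur) -> Layer:
    A = cfg.n_actions
    ctrl = DirectController(cfg, d_state,
                            _stable_seed(net.seed, name, "direct"), net.dt)
    size_in = d_state + 3 + 2 * A
    node = net.node(f"{name}.direct", ctrl, size_in=size_in,
                    size_out=3 * A + d_state)

    prev_q = net.ensemble(f"{name}.prev_q", cfg.q_neurons, d_state,
                          radius=cfg.state_radius,
                          encoder_samples=encoder_samples,
                          intercepts=cfg.q_intercepts)
    cur_q = net.ensemble(f"{name}.cur_q", cfg.q_neurons, d_state,
                         radius=cfg.state_radius,
                         encoder_samples=encoder_samples,
                         intercepts=cfg.q_intercepts)
    prev_out = net.learned_connection(prev_q, A, error=node,
                                      kappa=cfg.kappa_td,
                                      name=f"{name}.q_prev",
                                      initial=initial_prev)
    prev_out.error_offset = 0
    cur_out = net.learned_connection(cur_q, A, error=node,
                                     kappa=cfg.kappa_cons,
                                     name=f"{name}.q_cur",
                                     initial=initial_cur)
    cur_out.error_offset = A

    def sel_cols(n_total, sl):
        T = np.zeros((sl.stop - sl.start, n_total))
        T[np.arange(sl.stop - sl.start), np.arange(sl.start, sl.stop)] = 1.0
        return T

    # ensemble inputs
    net.connect(state_source, cur_q, transform=1.0, synapse=nef.TAU_FAST)
    net.connect(node, prev_q,
                transform=sel_cols(3 * A + d_state, slice(3 * A, 3 * A + d_state)),
                synapse=None)

    # controller inputs
    Z = np.zeros
    T = np.zeros((size_in, d_state))
    T[:d_state] = np.eye(d_state)
    net.connect(state_source, node, transform=T, synapse=nef.TAU_FAST)
    T = np.zeros((size_in, reward_source.size_out))
    T[d_state, :] = 1.0
    net.connect(reward_source, node, transform=T, synapse=nef.TAU_FAST)
    tt = np.asarray(term_transform, float)
    T = np.zeros((size_in, tt.shape[1]))
    T[d_state + 1: d_state + 3] = tt
    net.connect(term_source, node, transform=T, synapse=None)
    T = np.zeros((size_in, A))
    T[d_state + 3: d_state + 3 + A] = np.eye(A)
    net.connect(cur_out, node, transform=T, synapse=nef.TAU_FAST)
    T = np.zeros((size_in, A))
    T[d_state + 3 + A:] = np.eye(A)
    net.connect(prev_out, node, transform=T, synapse=nef.TAU_FAST)

    def map_fn(t, x):
        return np.asarray(cfg.action_vectors, float).T @ x

    action_node = net.node(f"{name}.action", map_fn, size_in=A,
                           size_out=np.asarray(cfg.action_vectors).shape[1])
    net.connect(node, action_node,
                transform=sel_cols(3 * A + d_state, slice(2 * A, 3 * A)),
                synapse=None)
    out_pop = _make_out_pop(net, name, cfg)
    net.connect(action_node, out_pop, transform=1.0, synapse=nef.TAU_FAST)

    dual = av.DualQNetwork(d_state, A, None, None, prev_q, cur_q, prev_out,
                           cur_out, None, None, None, cfg.theta)

    # the held one-hot lives at offset 2A within the controller output
    layer = Layer(name, cfg, None, dual, None, None, out_pop, out_pop,
                  node, None, direct=ctrl)
    layer._held_transform = sel_cols(3 * A + d_state, slice(2 * A, 3 * A))
    return layer


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------

@dataclass
class SubgoalSpec:
    """One-to-one mapping from upper actions to target states.

    ``targets`` has one row per upper action (the state vector s0 to reach);
    ``dims`` optionally restricts the distance computation to a subset of
    state dimensions (e.g. the position-coding part).  Reaching within
    ``theta_r`` pays ``r_plus``, anywhere else pays ``r_minus``.
    """

    targets: np.ndarray
    theta_r: float
    r_plus: float = 1.0
    r_minus: float = 0.0
    dims: Optional[np.ndarray] = None
    timeout: float = 30.0


@dataclass
class InteractionSpec:
    kind: str                      # "context" | "state" | "reward"
    mask: Optional[np.ndarray] = None          # state: (d_env, d_action_up)
    subgoal: Optional[SubgoalSpec] = None      # reward: subgoal pseudoreward
    reward_fn: Optional[Callable] = None       # reward: custom factory


def pseudoreward_value(s, s0, theta_r, r_plus=1.0, r_minus=0.0,
                       dims=None) -> float:
    """Closed-form pseudoreward: r+ within ``theta_r`` of the target, r- else."""
    s = np.asarray(s, float)
    s0 = np.asarray(s0, float)
    if dims is not None:
        s, s0 = s[dims], s0[dims]
    return r_plus if np.linalg.norm(s - s0) < theta_r else r_minus


def make_pseudoreward_node(net: Network, name: str, upper: Layer,
                           state_source, d_state: int,
                           spec: SubgoalSpec) -> Node:
    """Reward-interaction node: pays the lower layer for reaching the subgoal
    commanded by the upper layer's held action."""
    A_up = upper.cfg.n_actions
    targets = np.asarray(spec.targets, float)

    def fn(t, x):
        oh = x[:A_up]
        s = x[A_up:]
        k = int(np.argmax(oh))
        if oh[k] < 0.4:
            return spec.r_minus
        return pseudoreward_value(s, targets[k], spec.theta_r, spec.r_plus,
                                  spec.r_minus, spec.dims)

    node = net.node(name, fn, size_in=A_up + d_state, size_out=1)
    _connect_held(net, upper, node, rows=slice(0, A_up), size_in=A_up + d_state)
    T = np.zeros((A_up + d_state, d_state))
    T[A_up:] = np.eye(d_state)
    net.connect(state_source, node, transform=T, synapse=nef.TAU_FAST)
    return node


def _connect_held(net, upper: Layer, node, rows, size_in):
    """Route the upper layer's held one-hot into rows of a node input."""
    A_up = upper.cfg.n_actions
    T = np.zeros((size_in, upper.held_one_hot.size_out))
    if hasattr(upper, "_held_transform"):
        T[rows] = upper._held_transform
        net.connect(upper.held_one_hot, node, transform=T, synapse=None)
    else:
        T[rows, :A_up] = np.eye(A_up)
        net.connect(upper.held_one_hot, node, transform=T,
                    synapse=nef.TAU_FAST)


def make_abstract_termination(net: Network, name: str, state_source,
                              d_state: int, spec: SubgoalSpec,
                              env_term_source, env_term_transform) -> Node:
    """Termination detector for abstract actions.

    Emits a ``[pulse, terminal]`` pair for the upper layer when the commanded
    subgoal is reached, when the timeout elapses, or when the environment
    itself ends an episode (which is forwarded as a terminal termination).
    The upper one-hot input is wired afterwards by :func:`compose`.
    """
    targets = np.asarray(spec.targets, float)
    A_up = targets.shape[0]
    state = {"last": None, "prev_near": False, "out": np.zeros(2)}

    def fn(t, x):
        env_pulse, env_terminal = x[0], x[1]
        s = x[2: 2 + d_state]
        oh = x[2 + d_state:]
        out = state["out"]
        out[:] = 0.0
        if state["last"] is None:
            # kick-off pulse so the layer makes its first selection
            if t >= 0.3:
                out[0] = 1.0
                state["last"] = t
            return out
        if env_terminal > 0.5 and env_pulse > 0.5:
            out[:] = (1.0, 1.0)
            state["last"] = t
            return out
        k = int(np.argmax(oh))
        near = False
        if oh[k] >= 0.4:
            sv, tv = s, targets[k]
            if spec.dims is not None:
                sv, tv = s[spec.dims], tv[spec.dims]
            near = bool(np.linalg.norm(sv - tv) < spec.theta_r)
        if (near and not state["prev_near"]) or (t - state["last"] > spec.timeout):
            out[0] = 1.0
            state["last"] = t
        state["prev_near"] = near
        return out

    node = net.node(name, fn, size_in=2 + d_state + A_up, size_out=2)
    tt = np.asarray(env_term_transform, float)
    T = np.zeros((2 + d_state + A_up, tt.shape[1]))
    T[:2] = tt
    net.connect(env_term_source, node, transform=T, synapse=None)
    T = np.zeros((2 + d_state + A_up, d_state))
    T[2: 2 + d_state] = np.eye(d_state)
    net.connect(state_source, node, transform=T, synapse=nef.TAU_FAST)
    node._oh_rows = slice(2 + d_state, 2 + d_state + A_up)
    return node


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

@dataclass
class LayerSpec:
    cfg: LayerConfig
    termination: str = "env"            # "env" | "subgoal"
    subgoal: Optional[SubgoalSpec] = None
    reward_transform: Optional[Callable] = None  # factory(net, layer_below...)


@dataclass
class HierarchicalAgent:
    layers: list            # index 0 = bottom
    env_node: Node
    interactions: list


def compose(net: Network, env_node: Node, d_env: int, layer_specs,
            interactions=None, encoder_samples=None,
            reward_overrides=None, initial_decoders=None) -> HierarchicalAgent:
    """Build a hierarchy of layers on top of an environment node.

    ``layer_specs`` is ordered bottom-up (index 0 acts on the environment).
    ``interactions[i]`` is the :class:`InteractionSpec` list applied between
    layer ``i+1`` (upper) and layer ``i`` (lower).  The environment node must
    output ``[state(d_env), reward, termination_pulse, terminal_flag]``.

    A single-element ``layer_specs`` yields the flat agent.
    """
    n = len(layer_specs)
    interactions = interactions or [[] for _ in range(max(n - 1, 0))]
    if len(interactions) != max(n - 1, 0):
        raise ValueError("need one interaction list per adjacent layer pair")
    for i, specs in enumerate(interactions):
        for sp in specs:
            if sp.kind not in ("context", "state", "reward"):
                raise ValueError(f"unknown interaction kind {sp.kind!r}")

    env_state_T = np.hstack([np.eye(d_env), np.zeros((d_env, 3))])
    env_term_T = np.zeros((2, d_env + 3))
    env_term_T[0, d_env + 1] = 1.0
    env_term_T[1, d_env + 2] = 1.0
    env_reward_T = np.zeros((1, d_env + 3))
    env_reward_T[0, d_env] = 1.0

    def env_state_node(name):
        nd = net.node(name, lambda t, x: x, size_in=d_env, size_out=d_env)
        net.connect(env_node, nd, transform=env_state_T, synapse=None)
        return nd

    def env_reward_node(name):
        nd = net.node(name, lambda t, x: x, size_in=1, size_out=1)
        net.connect(env_node, nd, transform=env_reward_T, synapse=None)
        return nd

    layers = [None] * n
    # build top-down so lower layers can read upper action outputs
    for i in reversed(range(n)):
        spec = layer_specs[i]
        upper = layers[i + 1] if i + 1 < n else None
        up_specs = interactions[i] if i < n - 1 else []

        state_source = None
        d_state = d_env
        reward_source = None
        for sp in up_specs:
            if sp.kind == "state":
                gate = net.channels(f"L{i}.state_gate", d_env, 40,
                                    intercepts=(0.02, 0.95),
                                    encoders="positive", radius=1.2)
                net.connect(env_node, gate, transform=env_state_T,
                            synapse=nef.TAU_FAST)
                mask = np.asarray(sp.mask, float)
                net.connect(upper.action_signal, gate, transform=mask,
                            synapse=nef.TAU_FAST, inhibitory=True)
                state_source, d_state = gate, d_env
            elif sp.kind == "context":
                d_c = upper.cfg.action_vectors.shape[1]
                d_state = d_env + d_c

                def concat(t, x):
                    return x

                nd = net.node(f"L{i}.context", concat, size_in=d_state,
                              size_out=d_state)
                T = np.zeros((d_state, d_env + 3))
                T[:d_env] = env_state_T
                net.connect(env_node, nd, transform=T, synapse=None)
                T = np.zeros((d_state, d_c))
                T[d_env:] = np.eye(d_c)
                net.connect(upper.action_signal, nd, transform=T,
                            synapse=nef.TAU_FAST)
                state_source = nd
            elif sp.kind == "reward":
                pass  # handled after state_source is known
        if state_source is None:
            state_source = env_state_node(f"L{i}.state")

        for sp in up_specs:
            if sp.kind == "reward":
                if sp.reward_fn is not None:
                    reward_source = sp.reward_fn(net, upper=upper, lower_idx=i)
                else:
                    src = state_source if sp.subgoal.targets.shape[1] == d_state \
                        else env_state_node(f"L{i}.pr_state")
                    reward_source = make_pseudoreward_node(
                        net, f"L{i}.pseudoreward", upper, src,
                        sp.subgoal.targets.shape[1], sp.subgoal)
        if reward_source is None:
            if spec.reward_transform is not None:
                reward_source = spec.reward_transform(net, env_node=env_node,
                                                      env_reward_T=env_reward_T)
            else:
                reward_source = env_reward_node(f"L{i}.reward")

        if spec.termination == "env":
            term_source, term_T = env_node, env_term_T
        elif spec.termination == "subgoal":
            if spec.subgoal is None:
                raise ValueError("subgoal termination needs a SubgoalSpec")
            det = make_abstract_termination(
                net, f"L{i}.term", env_state_node(f"L{i}.term_state"),
                d_env, spec.subgoal, env_node, env_term_T)
            term_source, term_T = det, np.eye(2)
        else:
            raise ValueError(f"unknown termination mode {spec.termination!r}")

        enc = encoder_samples[i] if isinstance(encoder_samples, (list, tuple)) \
            else encoder_samples
        init = (initial_decoders or {}).get(i, (None, None))
        layers[i] = build_layer(net, f"L{i}", spec.cfg, state_source, d_state,
                                reward_source, term_source, term_T,
                                encoder_samples=enc, initial_prev=init[0],
                                initial_cur=init[1])
        lay = layers[i]
        if spec.termination == "subgoal":
            _connect_held(net, lay, term_source, rows=term_source._oh_rows,
                          size_in=term_source.size_in)
        # factories that need the just-built layer's own signals
        rows = getattr(reward_source, "_needs_self_held", None)
        if rows is not None:
            _connect_held(net, lay, reward_source, rows=rows,
                          size_in=reward_source.size_in)
        rows = getattr(reward_source, "_needs_lower_action", None)
        if rows is not None:
            T = np.zeros((reward_source.size_in, lay.action_signal.size_out))
            T[rows] = np.eye(lay.action_signal.size_out)
            net.connect(lay.action_signal, reward_source, transform=T,
                        synapse=nef.TAU_FAST)

    # the bottom layer's action drives the environment
    bottom = layers[0]
    d_act = bottom.cfg.action_vectors.shape[1]
    T = np.zeros((env_node.size_in, d_act))
    T[:d_act] = np.eye(d_act)
    net.connect(bottom.action_signal, env_node, transform=T,
                synapse=nef.TAU_FAST)

    return HierarchicalAgent(layers, env_node, interactions)
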