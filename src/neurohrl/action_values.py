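"""Dual-training Q-value representation.

Learning action values with a local, activity-dependent rule poses a timing
problem in semi-Markov environments: the TD error for the action chosen in
state ``s`` only becomes available when that action terminates, by which time
the network's activity encodes the successor state ``s'``.  Instead of
eligibility traces — which impose a fixed usable time window and blur credit
across hierarchy levels — this module uses a *dual training system*:

* a **previous-state population** receives the state stored at the last
  selection event (held in a gated line-attractor memory), so at update time
  its activity still encodes ``s``; its decoders receive the TD error and
  represent the authoritative Q function;
* a **current-state population** receives the live state and provides the
  Q values used for action selection and for the ``Q(s', a')`` term; its
  decoders are trained toward the previous-state population's output through
  a *consistency error* ``E = Q(s) - Q(s')`` that is gated open only when the
  stored and live states are close (``||s - s'|| < theta``), because only then
  should the two populations agree.

The distance gate is a small population thresholding the decoded distance
through its firing intercepts; consistency learning is additionally gated off
during the TD pulse so the two update pathways never fight.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from . import nef_core as nef
from .nef_core import (Network, ChannelGroup, Ensemble, LearnedConnection,
                       Node)


@dataclass
class DualQNetwork:
    """Handles for the action-values component of one layer."""

    d_state: int
    n_actions: int
    memory: ChannelGroup          # stored previous state (line attractor)
    memory_load: Node             # load port (pulse = selection event)
    prev_q: Ensemble              # population encoding the stored state
    cur_q: Ensemble               # population encoding the live state
    prev_out: LearnedConnection   # decoded Q(s); TD-trained
    cur_out: LearnedConnection    # decoded Q(s'); consistency-trained
    consistency_error: ChannelGroup
    distance: Node                # decoded ||s - s'||
    blocker: ChannelGroup         # active when distance exceeds theta
    theta: float


def build_dual_q(net: Network, name: str, state_source, d_state: int,
                 n_actions: int, e_td_source, gate_node: Node,
                 theta: float, q_neurons: int = 500, mem_neurons: int = 80,
                 kappa_td: float = 5e-4, kappa_cons: float = 5e-4,
                 state_radius: float = 1.5,
                 encoder_samples: Optional[Callable] = None,
                 distance_scale: Optional[float] = None,
                 initial_prev=None, initial_cur=None,
                 bias_scale: float = 1.0,
                 intercepts: tuple = (-1.0, 1.0)) -> DualQNetwork:
    """Build the dual Q network for one layer.

    ``state_source`` is the live state signal (environment, concatenation or
    gating output); ``e_td_source`` the per-action TD error vector;
    ``gate_node`` the layer's cycle timer ``[td_gate, load_gate, ...]``.
    ``theta`` is the consistency threshold in state-space distance units.
    """
    A = n_actions

    mem, mem_diff, mem_load = nef.make_gated_memory(
        net, f"{name}.state_mem", d_state, mem_neurons, radius=state_radius)
    net.connect(state_source, mem_diff, transform=1.0, synapse=nef.TAU_FAST)
    net.connect(gate_node, mem_load, transform=[[0, 1.0, 0]], synapse=None)

    prev_q = net.ensemble(f"{name}.prev_q", q_neurons, d_state,
                          radius=state_radius,
                          encoder_samples=encoder_samples,
                          bias_scale=bias_scale, intercepts=intercepts)
    net.connect(mem, prev_q, transform=1.0, synapse=nef.TAU_FAST)
    cur_q = net.ensemble(f"{name}.cur_q", q_neurons, d_state,
                         radius=state_radius,
                         encoder_samples=encoder_samples,
                         bias_scale=bias_scale, intercepts=intercepts)
    net.connect(state_source, cur_q, transform=1.0, synapse=nef.TAU_FAST)

    prev_out = net.learned_connection(prev_q, A, error=e_td_source,
                                      kappa=kappa_td,
                                      name=f"{name}.q_prev",
                                      initial=initial_prev)

    # consistency pathway ------------------------------------------------
    def dist_fn(t, x):
        return float(np.linalg.norm(x[:d_state] - x[d_state:]))

    dist = net.node(f"{name}.distance", dist_fn, size_in=2 * d_state,
                    size_out=1)
    eye = np.eye(d_state)
    net.connect(state_source, dist,
                transform=np.vstack([eye, np.zeros((d_state, d_state))]),
                synapse=nef.TAU_FAST)
    net.connect(mem, dist,
                transform=np.vstack([np.zeros((d_state, d_state)), eye]),
                synapse=nef.TAU_FAST)

    if distance_scale is None:
        distance_scale = 1.0 / max(2.0 * theta, 1e-6)
    blocker = nef.make_threshold_detector(net, f"{name}.far", dist,
                                          threshold=theta,
                                          scale=distance_scale)

    # zero-aligned intercepts: a zero consistency error is silence, so the
    # current-state decoders do not drift on representation noise
    cons = net.channels(f"{name}.consistency_e", A, 60, radius=1.5,
                        intercepts=(0.005, 0.95))
    net.connect(blocker, cons, transform=np.ones((A, 1)), synapse=nef.TAU_FAST,
                inhibitory=True)
    # consistency learning pauses while the TD pulse is applied
    net.connect(gate_node, cons, transform=np.ones((A, 1)) @ [[1.0, 0, 0]],
                synapse=None, inhibitory=True)

    cur_out = net.learned_connection(cur_q, A, error=cons, kappa=kappa_cons,
                                     name=f"{name}.q_cur",
                                     initial=initial_cur)
    net.connect(prev_out, cons, transform=1.0, synapse=nef.TAU_FAST)
    net.connect(cur_out, cons, transform=-1.0, synapse=nef.TAU_FAST)

    return DualQNetwork(d_state, A, mem, mem_load, prev_q, cur_q,
                        prev_out, cur_out, cons, dist, blocker, theta)


def consistency_error(q_prev, q_cur, s, s_prev, theta: float) -> np.ndarray:
    """Closed-form consistency error: ``Q(s) - Q(s')`` inside the threshold.

    Reference semantics for the neural gate: the error is zero whenever the
    live and stored states differ by at least ``theta``.
    """
    q_prev = np.asarray(q_prev, float)
    q_cur = np.asarray(q_cur, float)
    if np.linalg.norm(np.asarray(s, float) - np.asarray(s_prev, float)) < theta:
        return q_prev - q_cur
    return np.zeros_like(q_prev)
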