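"""SMDP temporal-difference error with the integrative discount.

The error network receives the decoded Q vectors for the stored previous
state and the current state, masks out everything but the selected actions
with inhibition driven by the selection circuit, accumulates reward and the
discount term over the (unknown, variable) delay period with neural
integrators, and combines them into the prediction error

    delta = R_acc + Q(s', a') - Q(s, a) - D_acc

where ``R_acc`` integrates the reward signal since the last selection and
``D_acc`` integrates ``gamma * Q(s, a)``, so the discount is *subtracted*
rather than applied multiplicatively.  The integrative form keeps the two
essential properties of discounting — it scales with the delay length and
with the Q magnitude — while avoiding neural multiplication of signals with
very different magnitudes.  The error output is inhibited except during a
brief termination-triggered pulse, which is when the update reaches the
Q decoders; learning-rate x pulse-width is therefore the effective TD step
size.

A closed-form multiplicative-discount error (the classical exponentially
discounted form) is provided as a non-neural reference for comparison tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import nef_core as nef
from .nef_core import Network, ChannelGroup, Node

# how strongly a one-hot entry must rise to release its relay channel; the
# latched winner sits near 0.5-1.0 (spiking decode is conservative), so the
# release threshold is ~0.4 while near-zero losers stay fully inhibited
MASK_GAIN = 2.5


@dataclass
class ErrorNetwork:
    n_actions: int
    q_prev_sel: ChannelGroup   # relay passing only Q(s, a)
    q_cur_sel: ChannelGroup    # relay passing only Q(s', a')
    r_acc: ChannelGroup        # reward integrator
    d_acc: ChannelGroup        # discount integrator
    delta: ChannelGroup        # gated TD error (scalar)
    e_td: ChannelGroup         # per-action error vector for the Q decoders
    gamma: float


def add_selection_mask(net: Network, relay: ChannelGroup, one_hot_source,
                       gain: float = MASK_GAIN):
    """Inhibit every relay channel whose one-hot entry is low.

    The summed inhibitory drive per channel is ``1 - gain * one_hot[k]``
    (clipped at zero), so the selected channel passes and the rest are
    silenced.
    """
    A = relay.n_channels
    net.connect(net.constant, relay, transform=np.ones((A, 1)), synapse=None,
                inhibitory=True)
    net.connect(one_hot_source, relay, transform=-gain * np.eye(A),
                synapse=nef.TAU_FAST, inhibitory=True)


def build_error_network(net: Network, name: str, q_prev_source, q_cur_source,
                        reward_source, held_one_hot, current_one_hot,
                        gate_node: Node, n_actions: int, gamma: float = 0.3,
                        relay_neurons: int = 100, integ_neurons: int = 150,
                        acc_radius: float = 1.5, d_acc_radius: float = 1.0,
                        delta_radius: float = 1.5,
                        reward_transform=None) -> ErrorNetwork:
    """Assemble the full neural error-calculation network.

    ``gate_node`` is the layer's cycle timer; its outputs are
    ``[td_gate, load_gate, qcur_suppress]``.  ``held_one_hot`` masks
    Q(s, a) (the latched previous selection); ``current_one_hot`` masks
    Q(s', a') (the instantaneous winner for the new state).
    """
    A = n_actions
    ones_row = np.ones((1, A))

    # relay decoding bias enters the TD error as a spurious per-action
    # reward, so the relays get enough neurons and weak regularisation to
    # keep that bias well below the task's value gradients
    qps = net.channels(f"{name}.q_prev_sel", A, relay_neurons, radius=1.5,
                       regularization=0.02)
    net.connect(q_prev_source, qps, transform=1.0, synapse=nef.TAU_FAST)
    add_selection_mask(net, qps, held_one_hot)

    qcs = net.channels(f"{name}.q_cur_sel", A, relay_neurons, radius=1.5,
                       regularization=0.02)
    net.connect(q_cur_source, qcs, transform=1.0, synapse=nef.TAU_FAST)
    add_selection_mask(net, qcs, current_one_hot)
    # terminal transitions: the next-state value is suppressed entirely
    net.connect(gate_node, qcs, transform=np.ones((A, 1)) @ [[0, 0, 1.0]],
                synapse=None, inhibitory=True)

    # accumulators: line-attractor integrators with an event-driven reset
    r_acc = nef.make_integrator(net, f"{name}.r_acc", 1, n_neurons=integ_neurons,
                                radius=acc_radius)
    if reward_transform is None:
        reward_transform = np.ones((1, reward_source.size_out))
    net.connect(reward_source, r_acc,
                transform=np.asarray(reward_transform) * r_acc.input_transform,
                synapse=nef.TAU_FAST)
    d_acc = nef.make_integrator(net, f"{name}.d_acc", 1, n_neurons=integ_neurons,
                                radius=d_acc_radius)
    net.connect(qps, d_acc, transform=gamma * d_acc.input_transform * ones_row,
                synapse=nef.TAU_FAST)
    for acc in (r_acc, d_acc):
        _add_reset(net, acc, gate_node)

    # gated TD error:  delta = R + Q(s',a') - Q(s,a) - D
    # Error populations have firing intercepts aligned away from zero so a
    # zero error is represented by silence — an exact zero.  Without this the
    # per-channel decoding bias acts as a spurious constant reward and locks
    # selection onto whichever action has the most positive bias.
    delta = net.channels(f"{name}.delta", 1, 80, radius=delta_radius,
                         intercepts=(0.005, 0.95))
    net.connect(r_acc, delta, transform=1.0, synapse=nef.TAU_FAST)
    net.connect(qcs, delta, transform=ones_row, synapse=nef.TAU_FAST)
    net.connect(qps, delta, transform=-ones_row, synapse=nef.TAU_FAST)
    net.connect(d_acc, delta, transform=-1.0, synapse=nef.TAU_FAST)
    # inhibited except during the termination pulse
    net.connect(net.constant, delta, transform=[[1.0]], synapse=None,
                inhibitory=True)
    net.connect(gate_node, delta, transform=[[-1.0, 0.0, 0.0]], synapse=None,
                inhibitory=True)

    # per-action error: the selected channel carries delta, the others zero
    e_td = net.channels(f"{name}.e_td", A, relay_neurons, radius=delta_radius,
                        intercepts=(0.005, 0.95))
    net.connect(delta, e_td, transform=np.ones((A, 1)), synapse=nef.TAU_FAST)
    add_selection_mask(net, e_td, held_one_hot)
    net.connect(net.constant, e_td, transform=np.ones((A, 1)), synapse=None,
                inhibitory=True)
    net.connect(gate_node, e_td, transform=np.ones((A, 1)) @ [[-1.0, 0, 0]],
                synapse=None, inhibitory=True)

    return ErrorNetwork(A, qps, qcs, r_acc, d_acc, delta, e_td, gamma)


def _add_reset(net: Network, acc: ChannelGroup, gate_node: Node,
               gain: float = 8.0):
    """Drive an integrator back to zero during the load/reset window.

    A difference population representing ``-value`` feeds back strongly into
    the integrator; it is inhibited except while the reset gate (the second
    output of the cycle timer) is high.
    """
    rd = net.channels(acc.name + ".reset", acc.n_channels, 40,
                      radius=acc.radius)
    net.connect(acc, rd, transform=-1.0, synapse=nef.TAU_FAST)
    net.connect(rd, acc, transform=nef.TAU_SLOW * gain, synapse=nef.TAU_FAST)
    C = acc.n_channels
    net.connect(net.constant, rd, transform=np.ones((C, 1)), synapse=None,
                inhibitory=True)
    net.connect(gate_node, rd, transform=np.ones((C, 1)) @ [[0, -1.0, 0]],
                synapse=None, inhibitory=True)


# ---------------------------------------------------------------------------
# Closed-form references
# ---------------------------------------------------------------------------

def td_error_integrative(r_acc: float, q_sa: float, q_spap: float,
                         d_acc: float, terminal: bool = False) -> float:
    """Integrative-discount SMDP TD error (closed form).

    ``delta = R_acc + Q(s',a') - Q(s,a) - D_acc``; on terminal transitions the
    next-state value is dropped (episodic convention).
    """
    return r_acc + (0.0 if terminal else q_spap) - q_sa - d_acc


def td_error_multiplicative(rewards, q_sa: float, q_spap: float,
                            gamma: float, dt: float,
                            terminal: bool = False) -> float:
    """Classical multiplicative-discount SMDP TD error (reference mode).

    ``rewards`` is the sampled reward trace over the delay (one value per
    ``dt``); the continuous discount ``gamma`` (1/s) enters as
    ``exp(-gamma * t)``.
    """
    r = np.asarray(rewards, float)
    t = np.arange(r.size) * dt
    disc_r = float(np.sum(r * np.exp(-gamma * t) * dt))
    tau = r.size * dt
    boot = 0.0 if terminal else float(np.exp(-gamma * tau) * q_spap)
    return disc_r + boot - q_sa


def accumulate(signal, dt: float, scale: float = 1.0) -> float:
    """Exact running integral of a sampled signal (reference for integrators)."""
    return float(np.sum(np.asarray(signal, float)) * dt * scale)
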