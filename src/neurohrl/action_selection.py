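"""Basal-ganglia action selection: winner-take-all over noisy Q values.

The selection circuit is the standard rate-model basal-ganglia/thalamus
architecture (striatum D1/D2, subthalamic nucleus, globus pallidus external
and internal segments) translated into NEF populations, computing an
approximate argmax: the thalamus channel of the highest-valued action goes to
~1 and the others to ~0, provided the winning margin exceeds the circuit's
resolution.  Below that resolution the output is ambiguous — a modelled
feature of neural decision making, not a defect.

Exploration is additive low-pass-filtered Gaussian noise on the Q values,
which induces a soft-max-like selection law: the probability of choosing an
action depends on how close its value is to the maximum, relative to the
noise scale.

A latch (gated line-attractor memory) stores the winning one-hot vector
across the semi-Markov delay period, and a linear map converts it into the
action vector defined by the environment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from . import nef_core as nef
from .nef_core import Network, ChannelGroup, Node, _stable_seed

# Gain constants of the basal-ganglia rate model (the standard published
# parameterisation of the striatum/STN/GP selection circuit).
BG_PARAMS = dict(
    mm=1.0, mp=1.0, me=1.0, mg=1.0,
    ws=1.0, wt=1.0, wm=1.0, wg=1.0, wp=0.9, we=0.3,
    e=0.2, ep=-0.25, ee=-0.2, eg=-0.2,
    le=0.2, lg=0.2,
)
TAU_AMPA = 0.002
TAU_GABA = 0.008
BG_OUTPUT_WEIGHT = -3.0


@dataclass
class SelectionNetwork:
    """Handles to the pieces of one action-selection network."""

    n_actions: int
    strD1: ChannelGroup
    strD2: ChannelGroup
    stn: ChannelGroup
    gpe: ChannelGroup
    gpi: ChannelGroup
    thalamus: ChannelGroup  # instantaneous one-hot output BG(s)
    latch: ChannelGroup     # one-hot held across the SMDP delay
    latch_load: Node
    noise: Optional[Node]
    action_map: np.ndarray
    action_node: Optional[Node] = None  # mapped action vector


def _thresh_fn(offset, slope=1.0):
    def fn(x):
        return slope * np.maximum(np.asarray(x) - offset, 0.0)
    return fn


def build_basal_ganglia(net: Network, name: str, q_source, n_actions: int,
                        n_neurons: int = 100, input_bias: float = 0.5,
                        input_scale: float = 0.5,
                        noise_sigma: float = 0.0,
                        noise_tau: float = 0.05) -> SelectionNetwork:
    """Build the BG/thalamus argmax circuit reading Q values from ``q_source``.

    Q values are mapped affinely into the circuit's operating range
    (``input_bias + input_scale * Q``), so zero-initialised Q functions sit
    mid-range where the circuit discriminates well.
    """
    p = BG_PARAMS
    A = n_actions

    radius = 1.2

    def grp(gname, icept, func):
        return net.channels(f"{name}.{gname}", A, n_neurons,
                            intercepts=(icept / radius, 0.95),
                            encoders="positive", radius=radius, function=func,
                            regularization=0.03)

    strD1 = grp("strD1", p["e"], _thresh_fn(p["e"], p["mm"]))
    strD2 = grp("strD2", p["e"], _thresh_fn(p["e"], p["mm"]))
    stn = grp("stn", p["ep"], _thresh_fn(p["ep"], p["mp"]))
    gpe = grp("gpe", p["ee"], _thresh_fn(p["ee"], p["me"]))
    gpi = grp("gpi", p["eg"], _thresh_fn(p["eg"], p["mg"]))

    # noisy, affinely shifted Q input
    noise = None
    if noise_sigma > 0:
        noise = make_exploration_noise(net, f"{name}.noise", A,
                                       noise_sigma, noise_tau)
    ones = np.ones((A, 1))
    for (tgt, w) in ((strD1, p["ws"] * (1 + p["lg"])),
                     (strD2, p["ws"] * (1 - p["le"])),
                     (stn, p["wt"])):
        net.connect(q_source, tgt, transform=w * input_scale, synapse=TAU_AMPA)
        net.connect(net.constant, tgt, transform=ones * w * input_bias,
                    synapse=None)
        if noise is not None:
            net.connect(noise, tgt, transform=w * input_scale, synapse=None)

    allall = np.ones((A, A))
    net.connect(strD1, gpi, transform=-p["wm"], synapse=TAU_GABA)
    net.connect(strD2, gpe, transform=-p["wm"], synapse=TAU_GABA)
    net.connect(stn, gpi, transform=p["wp"] * allall, synapse=TAU_AMPA)
    net.connect(stn, gpe, transform=p["wp"] * allall, synapse=TAU_AMPA)
    net.connect(gpe, gpi, transform=-p["we"], synapse=TAU_GABA)
    net.connect(gpe, stn, transform=-p["wg"], synapse=TAU_GABA)

    # the thalamus decodes a sharpened (cleanup) output so that partial
    # winners latch as a crisp one-hot instead of a cancelling blend
    def thal_sharpen(x):
        return np.clip((np.asarray(x) - 0.3) / 0.25, 0.0, 1.0)

    thalamus = net.channels(f"{name}.thalamus", A, n_neurons,
                            intercepts=(0.1, 0.95), encoders="positive",
                            radius=1.0, function=thal_sharpen)
    net.connect(net.constant, thalamus, transform=np.ones((A, 1)),
                synapse=None)
    net.connect(gpi, thalamus, transform=BG_OUTPUT_WEIGHT, synapse=TAU_GABA)
    # mutual inhibition: winner-take-all cleanup so one channel commits even
    # when the pallidal margin is slim
    net.connect(thalamus, thalamus,
                transform=-0.7 * (allall - np.eye(A)), synapse=TAU_GABA)

    return SelectionNetwork(A, strD1, strD2, stn, gpe, gpi, thalamus,
                            latch=None, latch_load=None, noise=noise,
                            action_map=None)


def make_exploration_noise(net: Network, name: str, d: int, sigma: float,
                           tau: float = 0.05) -> Node:
    """Low-pass-filtered Gaussian noise with stationary std ``sigma``.

    Filtering keeps the perturbation stable within a decision window so the
    winner-take-all circuit can settle on the perturbed winner.
    """
    rng = np.random.default_rng(_stable_seed(net.seed, name))
    alpha = 1.0 - np.exp(-net.dt / tau)
    gain = sigma * np.sqrt((2.0 - alpha) / alpha) if sigma > 0 else 0.0
    state = np.zeros(d)

    def fn(t):
        state[:] += alpha * (gain * rng.standard_normal(d) - state)
        return state

    return net.node(name, fn, size_in=0, size_out=d)


def add_latch(net: Network, name: str, sel: SelectionNetwork,
              action_map: np.ndarray, n_neurons: int = 100):
    """Store the winning one-hot across the delay and map it to an action.

    The latch loads the thalamus output whenever the load port is pulsed
    (the selection event) and holds it otherwise.  The action node computes
    the linear readout ``sum_k one_hot[k] * action_map[k]``.
    """
    A = sel.n_actions
    action_map = np.asarray(action_map, float)
    if action_map.shape[0] != A:
        raise ValueError("action map must have one vector per action")

    mem, diff, load = nef.make_gated_memory(net, name, A, n_neurons,
                                            radius=1.2)
    net.connect(sel.thalamus, diff, transform=1.0, synapse=nef.TAU_FAST)

    def map_fn(t, x):
        return action_map.T @ x

    action_node = net.node(name + ".action", map_fn, size_in=A,
                           size_out=action_map.shape[1])
    net.connect(mem, action_node, transform=1.0, synapse=nef.TAU_FAST)
    sel.latch = mem
    sel.latch_load = load
    sel.action_map = action_map
    sel.action_node = action_node
    return sel


def map_action(one_hot, action_map) -> np.ndarray:
    """Linear readout of the action vector for a (possibly noisy) one-hot."""
    return np.asarray(action_map, float).T @ np.asarray(one_hot, float)


def softmax_law(Q, sigma: float, normalize: bool = True) -> np.ndarray:
    """Selection probabilities induced by additive Gaussian value noise.

    For each action the probability is the chance that its noise-perturbed
    value exceeds the perturbed maximum — a pairwise Gaussian comparison
    ``P = 1 - Phi((max Q - Q_a) / (sigma*sqrt2))`` against the best action.
    For two actions this pre-normalisation value is the exact selection
    probability; with more actions the pairwise values only approximate the
    true probabilities and are normalised to sum to one (the soft-max-like
    policy).  With ``sigma = 0`` this is the greedy policy.
    """
    Q = np.asarray(Q, float)
    if sigma <= 0:
        p = (Q == Q.max()).astype(float)
        return p / p.sum()
    z = (Q.max() - Q) / (sigma * np.sqrt(2.0))
    p = 1.0 - norm.cdf(z)
    return p / p.sum() if normalize else p
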