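"""Minimal Neural Engineering Framework (NEF) substrate.

This module provides the neural building blocks used by every other part of
the package: leaky integrate-and-fire (LIF) neurons in rate or spiking mode,
heterogeneous populations encoding real vectors through randomly sampled
tuning curves, regularised least-squares decoding, the prescribed-error
sensitivity (PES) learning rule for online decoder learning, neural
integrator memories (line attractors), and inhibitory gating.

The public surface is deliberately nengo-like: a :class:`Network` is populated
with channel groups (batches of one-dimensional populations), multi-dimensional
:class:`Ensemble` objects, and :class:`Node` objects (arbitrary time-domain
callables such as environments), wired with :meth:`Network.connect`.  A
:class:`Simulator` compiles the network into flat numpy arrays — all scalar
channels share a single neuron pool, and all decoded/node signals live in one
signal vector with per-time-constant low-pass filtered copies — so that a
simulation step is a short sequence of vectorised operations.  This is what
makes hour-scale simulated experiments tractable on a single CPU.

Weights are always kept in factorised encoder/decoder form (standard NEF
practice); full synaptic weight matrices are never materialised.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

__all__ = [
    "lif_rate",
    "gain_bias",
    "tuning_curves",
    "solve_decoders",
    "pes_delta",
    "Network",
    "Simulator",
    "ChannelGroup",
    "Ensemble",
    "Node",
    "LearnedConnection",
    "Probe",
    "make_integrator",
    "make_gated_memory",
    "make_threshold_detector",
]

# Default synaptic time constants (s): fast sensory/decoding synapses and the
# slow recurrent synapse used by integrator memories.
TAU_FAST = 0.005
TAU_SLOW = 0.1

# Current added per unit of inhibitory gate signal.  Chosen to exceed the
# largest drive current produced by the default tuning-curve ranges, so a unit
# gate silences any population it projects to.
INHIBITION_STRENGTH = 20.0


# ---------------------------------------------------------------------------
# LIF neuron model
# ---------------------------------------------------------------------------

def lif_rate(J, tau_rc: float = 0.02, tau_ref: float = 0.002):
    """Steady-state LIF firing rate (Hz) for input current ``J``.

    The rate is ``1 / (tau_ref - tau_rc * ln(1 - 1/J))`` above the threshold
    current ``J = 1`` and zero at or below it.  ``J`` may be a scalar or array.

    Raises
    ------
    ValueError
        If ``J`` contains non-finite values, or time constants are invalid.
    """
    if tau_rc <= 0:
        raise ValueError("tau_rc must be positive")
    if tau_ref < 0:
        raise ValueError("tau_ref must be non-negative")
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("input current must be finite")
    out = np.zeros_like(J)
    above = J > 1.0 + 1e-12
    if J.ndim:
        out[above] = 1.0 / (tau_ref - tau_rc * np.log1p(-1.0 / J[above]))
        return out
    if above:
        return float(1.0 / (tau_ref - tau_rc * np.log1p(-1.0 / J)))
    return 0.0


def _stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary labels (process-independent)."""
    return zlib.crc32(repr(parts).encode()) & 0x7FFFFFFF


def _current_for_rate(rate, tau_rc, tau_ref):
    """Inverse of :func:`lif_rate`: current producing the requested rate."""
    rate = np.asarray(rate, dtype=float)
    return 1.0 / (1.0 - np.exp((tau_ref - 1.0 / rate) / tau_rc))


def gain_bias(max_rates, intercepts, tau_rc: float = 0.02, tau_ref: float = 0.002):
    """Per-neuron gain and bias current from desired tuning-curve shape.

    ``max_rates`` is the firing rate when the encoded projection equals the
    population radius; ``intercepts`` is the normalised projection at which the
    neuron starts firing.  Both are arrays of equal length.
    """
    max_rates = np.asarray(max_rates, float)
    intercepts = np.asarray(intercepts, float)
    j_max = _current_for_rate(max_rates, tau_rc, tau_ref)
    gain = (j_max - 1.0) / (1.0 - intercepts)
    bias = 1.0 - gain * intercepts
    return gain, bias


def _lif_spike_step(v, ref, J, dt, tau_rc, tau_ref, out):
    """One step of the spiking LIF model (in place).

    Uses exact membrane decay over the non-refractory part of the step and
    sub-step spike-time interpolation, so the long-run spike rate matches the
    closed-form rate equation without timestep quantisation bias.
    """
    delta = np.clip(dt - ref, 0.0, dt)
    np.subtract(ref, dt, out=ref)
    np.maximum(ref, 0.0, out=ref)
    v[...] = J + (v - J) * np.exp(-delta / tau_rc)
    np.maximum(v, 0.0, out=v)
    spiked = v > 1.0
    out[...] = 0.0
    if np.any(spiked):
        out[spiked] = 1.0 / dt
        # time already elapsed since the threshold crossing (within this
        # step); the refractory period starts at the crossing, not at the
        # step boundary
        elapsed = -tau_rc * np.log1p(-(v[spiked] - 1.0) / (J[spiked] - 1.0))
        ref[spiked] = tau_ref - elapsed
        v[spiked] = 0.0
    return out


# ---------------------------------------------------------------------------
# Decoder solving
# ---------------------------------------------------------------------------

def tuning_curves(gain, bias, encoders, eval_points, radius=1.0,
                  tau_rc=0.02, tau_ref=0.002):
    """Rate responses of a population over a set of evaluation points.

    Returns an ``(n_points, n_neurons)`` activity matrix for ``encoders`` of
    shape ``(n_neurons, d)`` and ``eval_points`` of shape ``(n_points, d)``.
    """
    eval_points = np.atleast_2d(np.asarray(eval_points, float))
    encoders = np.atleast_2d(np.asarray(encoders, float))
    J = ((eval_points / radius) @ encoders.T) * gain + bias
    return lif_rate(J, tau_rc, tau_ref)


def solve_decoders(activities, targets, regularization: float = 0.1):
    """Regularised least-squares decoders for a population.

    Parameters
    ----------
    activities : (n_points, n_neurons) array
        Tuning-curve responses at the evaluation points.
    targets : (n_points, d_out) array
        Function values to approximate.
    regularization : float
        Ridge term expressed as a fraction of the maximum activity (the
        standard NEF convention).

    Returns
    -------
    (n_neurons, d_out) decoder array.
    """
    A = np.asarray(activities, float)
    Y = np.atleast_2d(np.asarray(targets, float))
    if Y.shape[0] != A.shape[0]:
        Y = Y.T
    amax = A.max()
    if amax <= 0:
        raise ValueError("cannot solve decoders for an all-silent population")
    sigma = regularization * amax
    n = A.shape[0]
    G = A.T @ A / n + np.eye(A.shape[1]) * sigma ** 2
    U = A.T @ Y / n
    return np.linalg.solve(G, U)


def pes_delta(error, activities, kappa: float, dt: float, n_neurons: Optional[int] = None):
    """PES decoder increment for one simulation step.

    The update is local: row ``i`` of the returned ``(n_neurons, d_out)``
    increment depends only on presynaptic activity ``a_i`` and the modulatory
    error vector.  ``kappa`` is scaled by ``1/n_neurons`` so the effective rate
    of change of the decoded value is roughly independent of population size.
    """
    a = np.asarray(activities, float)
    e = np.asarray(error, float)
    if n_neurons is None:
        n_neurons = a.shape[-1]
    return (kappa * dt / n_neurons) * np.outer(a, e)


# ---------------------------------------------------------------------------
# Model-description objects
# ---------------------------------------------------------------------------

class _Signal:
    """Anything that owns a slice of the global signal vector ``z``."""

    size_out: int
    _z_slice: Optional[slice] = None


@dataclass
class ChannelGroup(_Signal):
    """A batch of independent one-dimensional LIF populations.

    Each of the ``n_channels`` channels represents one scalar with
    ``n_neurons`` neurons; the decoded output (after the optional channelwise
    ``function``) is a vector of length ``n_channels``.  Used for everything
    scalar in the model: basal-ganglia channels, integrators, memories, gates
    and error populations.
    """

    name: str
    n_channels: int
    n_neurons: int
    radius: float = 1.0
    intercepts: tuple = (-1.0, 1.0)
    max_rates: tuple = (50.0, 200.0)
    encoders: str = "both"  # "both" | "positive"
    function: Optional[Callable] = None
    regularization: float = 0.1
    seed_offset: int = 0

    def __post_init__(self):
        if self.n_channels < 1 or self.n_neurons < 1:
            raise ValueError("channel group needs at least one channel and neuron")
        self.size_out = self.n_channels
        self.size_in = self.n_channels


@dataclass
class Ensemble(_Signal):
    """A multi-dimensional NEF population (e.g. a Q-function population).

    Has no decoded output of its own; outputs are created by attaching
    :class:`LearnedConnection` objects (online-learned decoders) or fixed
    decoders via :meth:`Network.decoded`.
    """

    name: str
    n_neurons: int
    dimensions: int
    radius: float = 1.0
    intercepts: tuple = (-1.0, 1.0)
    max_rates: tuple = (50.0, 200.0)
    encoder_samples: Optional[Callable] = None  # fn(n, rng) -> (n, d) array
    bias_scale: float = 1.0

    def __post_init__(self):
        if self.n_neurons < 1 or self.dimensions < 1:
            raise ValueError("ensemble needs at least one neuron and dimension")
        self.size_out = 0
        self.size_in = self.dimensions


@dataclass
class Node(_Signal):
    """Direct (non-neural) computation: environments, pulse timing, probes.

    ``func(t, x)`` receives the summed, filtered input vector and returns the
    output vector (or a scalar for ``size_out == 1``).
    """

    name: str
    func: Callable
    size_in: int = 0
    size_out: int = 1


@dataclass
class LearnedConnection(_Signal):
    """Decoded output of an :class:`Ensemble` with PES-trained decoders.

    ``error`` is the modulatory error signal (a signal source of dimension
    ``size_out``); with ``kappa = 0`` the decoders stay constant.
    """

    name: str
    source: Ensemble
    size_out: int
    error: Optional[_Signal]
    kappa: float
    initial: Optional[np.ndarray] = None
    error_offset: int = 0  # offset into the error signal's output vector


@dataclass
class _Decoded(_Signal):
    """Fixed-function decoded output of an :class:`Ensemble`."""

    name: str
    source: Ensemble
    function: Callable
    size_out: int


@dataclass
class Connection:
    source: _Signal
    target: object
    transform: np.ndarray  # (target_size, source_size)
    synapse: Optional[float]
    inhibitory: bool = False


@dataclass
class Probe:
    target: object  # signal source, or ("rates", group/ensemble)
    every: float
    synapse: Optional[float]


class _Constant(_Signal):
    """The always-1.0 entry of the signal vector; used for bias inputs."""

    size_out = 1
    _z_slice = slice(0, 1)


class Network:
    """Container for model description; compiled by :class:`Simulator`."""

    def __init__(self, dt: float = 0.001, seed: int = 0, mode: str = "rate",
                 tau_rc: float = 0.02, tau_ref: float = 0.002):
        if mode not in ("rate", "spiking"):
            raise ValueError("mode must be 'rate' or 'spiking'")
        self.dt = float(dt)
        self.seed = int(seed)
        self.mode = mode
        self.tau_rc = tau_rc
        self.tau_ref = tau_ref
        self.groups: list[ChannelGroup] = []
        self.ensembles: list[Ensemble] = []
        self.nodes: list[Node] = []
        self.learned: list[LearnedConnection] = []
        self.decoded_outputs: list[_Decoded] = []
        self.connections: list[Connection] = []
        self.probes: list[Probe] = []
        self.constant = _Constant()
        self.rng = np.random.default_rng(seed)

    # -- construction ------------------------------------------------------
    def channels(self, name, n_channels, n_neurons=40, **kw) -> ChannelGroup:
        g = ChannelGroup(name, n_channels, n_neurons, **kw)
        self.groups.append(g)
        return g

    def ensemble(self, name, n_neurons, dimensions, **kw) -> Ensemble:
        e = Ensemble(name, n_neurons, dimensions, **kw)
        self.ensembles.append(e)
        return e

    def node(self, name, func, size_in=0, size_out=1) -> Node:
        n = Node(name, func, size_in, size_out)
        self.nodes.append(n)
        return n

    def learned_connection(self, source: Ensemble, size_out: int,
                           error: Optional[_Signal], kappa: float,
                           name: str = "", initial=None) -> LearnedConnection:
        lc = LearnedConnection(name or f"{source.name}.learned", source,
                               size_out, error, kappa, initial)
        self.learned.append(lc)
        return lc

    def decoded(self, source: Ensemble, function: Callable, size_out: int,
                name: str = "") -> _Decoded:
        d = _Decoded(name or f"{source.name}.decoded", source, function, size_out)
        self.decoded_outputs.append(d)
        return d

    def connect(self, source: _Signal, target, transform=1.0,
                synapse: Optional[float] = TAU_FAST, inhibitory: bool = False):
        tsize = target.size_in if not inhibitory else (
            target.n_channels if isinstance(target, ChannelGroup) else 1)
        T = _as_matrix(transform, tsize, source.size_out)
        c = Connection(source, target, T, synapse, inhibitory)
        self.connections.append(c)
        return c

    def probe(self, target, every: float = 0.01,
              synapse: Optional[float] = TAU_FAST) -> Probe:
        p = Probe(target, every, synapse)
        self.probes.append(p)
        return p


def _as_matrix(transform, rows, cols):
    T = np.asarray(transform, dtype=float)
    if T.ndim == 0:
        if rows == cols:
            return np.eye(rows) * T
        if cols == 1:
            return np.full((rows, 1), T)
        raise ValueError(f"scalar transform needs square shape, got {rows}x{cols}")
    if T.ndim == 1:
        if T.size == cols == rows:
            return np.diag(T)
        if rows == 1:
            return T.reshape(1, -1)
        if cols == 1:
            return T.reshape(-1, 1)
        raise ValueError("ambiguous 1-D transform")
    if T.shape != (rows, cols):
        raise ValueError(f"transform shape {T.shape} != ({rows},{cols})")
    return T


# ---------------------------------------------------------------------------
# Simulator
# ---------------------------------------------------------------------------

class _PoolState:
    """Flattened neuron arrays for all channel groups."""

    __slots__ = ("gain_enc", "bias", "chan", "offsets", "dflat", "n", "C",
                 "v", "ref", "out", "rates")


class _EnsState:
    __slots__ = ("gain", "bias", "enc_scaled", "n", "d", "x_slice", "inh_idx",
                 "v", "ref", "out", "afilt", "learned", "decoded")


class Simulator:
    """Compiles a :class:`Network` and advances it in fixed steps of ``dt``."""

    def __init__(self, network: Network):
        self.net = network
        self.dt = network.dt
        self.t = 0.0
        self._build()

    # -- building ----------------------------------------------------------
    def _build(self):
        net = self.net
        rng = np.random.default_rng(net.seed)

        # --- allocate the global signal vector z ---
        # layout: [constant 1.0 | group outputs | decoded outputs | learned
        #          outputs | node outputs]
        pos = 1
        for sig in net.groups + net.decoded_outputs + net.learned + net.nodes:
            sig._z_slice = slice(pos, pos + sig.size_out)
            pos += sig.size_out
        self.zsize = pos

        # --- synapse buckets ---
        # ZBUF row 0 is the raw signal vector; row k the tau_k-filtered copy.
        taus = sorted({c.synapse for c in net.connections if c.synapse} |
                      {p.synapse for p in net.probes if p.synapse} | {TAU_FAST})
        self.taus = taus
        self._tau_row = {None: 0}
        self._tau_row.update({tau: i + 1 for i, tau in enumerate(taus)})
        self.ZBUF = np.zeros((1 + len(taus), pos))
        self.ZBUF[:, 0] = 1.0
        self.z = self.ZBUF[0]
        self._alpha_col = np.array([1.0 - math.exp(-self.dt / tau)
                                    for tau in taus])[:, None]
        self._ftmp = np.zeros((len(taus), pos))
        self.alphas = {tau: float(a) for tau, a in
                       zip(taus, self._alpha_col[:, 0])}

        # --- build the channel pool ---
        pool = _PoolState()
        gains, biases, chans, dflat, offs = [], [], [], [], []
        self._group_chan = {}
        self._group_neuron = {}
        cpos = 0
        npos = 0
        for g in net.groups:
            gr = np.random.default_rng(_stable_seed(net.seed, g.name, g.seed_offset))
            self._group_chan[id(g)] = slice(cpos, cpos + g.n_channels)
            self._group_neuron[id(g)] = slice(npos, npos + g.n_channels * g.n_neurons)
            mr = gr.uniform(g.max_rates[0], g.max_rates[1],
                            size=(g.n_channels, g.n_neurons))
            ic = gr.uniform(g.intercepts[0], g.intercepts[1],
                            size=(g.n_channels, g.n_neurons))
            if g.encoders == "both":
                enc = gr.choice([-1.0, 1.0], size=(g.n_channels, g.n_neurons))
            else:
                enc = np.ones((g.n_channels, g.n_neurons))
            gain, bias = gain_bias(mr, ic, net.tau_rc, net.tau_ref)
            # decoders per channel (over the normalised domain)
            xs = np.linspace(-1.0, 1.0, 128)
            f = g.function or (lambda v: v)
            targets = np.asarray(f(xs * g.radius), float).reshape(-1, 1)
            for c in range(g.n_channels):
                A = lif_rate(np.outer(xs, gain[c] * enc[c]) + bias[c],
                             net.tau_rc, net.tau_ref)
                try:
                    D = solve_decoders(A, targets, g.regularization)
                except ValueError:
                    D = np.zeros((g.n_neurons, 1))
                dflat.append(D[:, 0])
                offs.append(npos + c * g.n_neurons)
            gains.append((gain * enc / g.radius).ravel())
            biases.append(bias.ravel())
            chans.append(np.repeat(np.arange(cpos, cpos + g.n_channels),
                                   g.n_neurons))
            cpos += g.n_channels
            npos += g.n_channels * g.n_neurons
        pool.C = cpos
        pool.n = npos
        pool.gain_enc = np.concatenate(gains) if gains else np.zeros(0)
        pool.bias = np.concatenate(biases) if biases else np.zeros(0)
        pool.chan = np.concatenate(chans).astype(np.intp) if chans else np.zeros(0, np.intp)
        pool.dflat = np.concatenate(dflat) if dflat else np.zeros(0)
        pool.offsets = np.asarray(offs, np.intp) if offs else np.zeros(1, np.intp)
        pool.v = np.zeros(pool.n)
        pool.ref = np.zeros(pool.n)
        pool.out = np.zeros(pool.n)
        pool.rates = np.zeros(pool.n)
        self.pool = pool
        self._pool_afilt = np.zeros(pool.n)
        self._pool_ymax = np.zeros(max(pool.C, 1))

        # --- ensembles ---
        self._ens = {}
        xpos = pool.C  # ensemble input dims appended after channel inputs
        inh_pos = pool.C
        for e in net.ensembles:
            er = np.random.default_rng(_stable_seed(net.seed, e.name))
            st = _EnsState()
            st.n, st.d = e.n_neurons, e.dimensions
            mr = er.uniform(e.max_rates[0], e.max_rates[1], e.n_neurons)
            ic = er.uniform(e.intercepts[0], e.intercepts[1], e.n_neurons)
            if e.encoder_samples is not None:
                enc = np.asarray(e.encoder_samples(e.n_neurons, er), float)
            else:
                enc = er.standard_normal((e.n_neurons, e.dimensions))
            norms = np.linalg.norm(enc, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            enc = enc / norms
            st.gain, st.bias = gain_bias(mr, ic, net.tau_rc, net.tau_ref)
            st.bias = st.bias * e.bias_scale
            st.enc_scaled = enc * (st.gain[:, None] / e.radius)
            st.x_slice = slice(xpos, xpos + e.dimensions)
            st.inh_idx = inh_pos
            xpos += e.dimensions
            inh_pos += 1
            st.v = np.zeros(st.n)
            st.ref = np.zeros(st.n)
            st.out = np.zeros(st.n)
            st.afilt = np.zeros(st.n)
            st.learned = []
            st.decoded = []
            self._ens[id(e)] = st
        self.xsize = xpos
        self.X = np.zeros(xpos)
        self.INH = np.zeros(inh_pos)

        # learned connections
        self._lc_state = {}
        for lc in net.learned:
            st = self._ens[id(lc.source)]
            if lc.initial is not None:
                D = np.array(lc.initial, float, copy=True)
                if D.shape != (lc.source.n_neurons, lc.size_out):
                    raise ValueError("initial decoders have wrong shape")
            else:
                D = np.zeros((lc.source.n_neurons, lc.size_out))
            if lc.error is not None:
                z0 = lc.error._z_slice.start + lc.error_offset
                err_slice = slice(z0, z0 + lc.size_out)
            else:
                err_slice = None
            rec = {"D": D, "err": err_slice, "lc": lc,
                   "coef": lc.kappa * self.dt / lc.source.n_neurons}
            st.learned.append(rec)
            self._lc_state[id(lc)] = rec

        # fixed decoded outputs of ensembles
        for dec in net.decoded_outputs:
            e = dec.source
            st = self._ens[id(e)]
            er = np.random.default_rng(_stable_seed(net.seed, e.name, "eval"))
            pts = er.uniform(-e.radius, e.radius, size=(500, e.dimensions))
            enc = st.enc_scaled * e.radius / st.gain[:, None]
            A = tuning_curves(st.gain, st.bias, enc, pts, e.radius,
                              net.tau_rc, net.tau_ref)
            targets = np.asarray([np.atleast_1d(dec.function(p)) for p in pts])
            D = solve_decoders(A, targets)
            st.decoded.append({"D": D, "dec": dec})

        # --- compile connections into three stacked matrices over ZBUF ---
        # columns are blocks of zsize, one per ZBUF row (raw + each tau)
        Z = self.zsize
        ncols = (1 + len(taus)) * Z
        nin_total = sum(n.size_in for n in net.nodes)
        self.WXb = np.zeros((self.xsize, ncols))
        self.WIb = np.zeros((self.INH.size, ncols))
        self.WNb = np.zeros((max(nin_total, 1), ncols))
        node_rows = {}
        npos_in = 0
        for n in net.nodes:
            node_rows[id(n)] = slice(npos_in, npos_in + n.size_in)
            npos_in += n.size_in

        def cols(synapse, sl):
            off = self._tau_row[synapse] * Z
            return slice(off + sl.start, off + sl.stop)

        for c in net.connections:
            src_sl = c.source._z_slice
            if src_sl is None:
                raise ValueError(f"unconnected source {c.source}")
            if isinstance(c.target, Node):
                self.WNb[node_rows[id(c.target)],
                         cols(c.synapse, src_sl)] += c.transform
                continue
            if c.inhibitory:
                if isinstance(c.target, ChannelGroup):
                    rows = self._group_chan[id(c.target)]
                else:
                    st = self._ens[id(c.target)]
                    rows = slice(st.inh_idx, st.inh_idx + 1)
                self.WIb[rows, cols(c.synapse, src_sl)] += c.transform
            else:
                if isinstance(c.target, ChannelGroup):
                    rows = self._group_chan[id(c.target)]
                elif isinstance(c.target, Ensemble):
                    rows = self._ens[id(c.target)].x_slice
                else:
                    raise TypeError(f"bad connection target {c.target}")
                self.WXb[rows, cols(c.synapse, src_sl)] += c.transform
        # sparse routing pays off once signal vectors get large (hierarchies
        # with place-cell states); keep dense for small models
        from scipy import sparse as _sp
        total = sum(getattr(self, a).size for a in ("WXb", "WIb", "WNb"))
        nnz = sum(np.count_nonzero(getattr(self, a))
                  for a in ("WXb", "WIb", "WNb"))
        self._sparse = total > 100_000 and nnz < 0.2 * total
        if self._sparse:
            for attr in ("WXb", "WIb", "WNb"):
                setattr(self, attr, _sp.csr_matrix(getattr(self, attr)))
        self._node_buf = np.zeros(max(nin_total, 1))
        self._node_list = [(n, node_rows[id(n)], n._z_slice)
                           for n in net.nodes]
        self._ens_list = [(e, self._ens[id(e)]) for e in net.ensembles]
        for _, st in self._ens_list:
            for rec in st.learned:
                rec["buf"] = np.zeros_like(rec["D"])
        self._is_rate = net.mode == "rate"

        # probes
        self._probe_data = {}
        for p in net.probes:
            self._probe_data[id(p)] = {"t": [], "v": [],
                                       "stride": max(1, round(p.every / self.dt))}
        self._step_count = 0

    # -- running -----------------------------------------------------------
    def step(self):
        """Advance one timestep.

        Routing reads the previous step's signal buffer, so every connection
        carries a uniform one-step delay on top of its synaptic filter; event
        pulses are therefore several steps wide (see environments).
        """
        net, dt = self.net, self.dt
        z = self.z
        t = self.t
        Zflat = self.ZBUF.reshape(-1)
        zfast = self.ZBUF[self._tau_row[TAU_FAST]]

        # 1. route inputs (from the previous step's signals)
        if not self._sparse:
            np.dot(self.WNb, Zflat, out=self._node_buf)
            X = np.dot(self.WXb, Zflat, out=self.X)
            INH = np.dot(self.WIb, Zflat, out=self.INH)
        else:
            self._node_buf[:] = self.WNb @ Zflat
            X = self.X
            X[:] = self.WXb @ Zflat
            INH = self.INH
            INH[:] = self.WIb @ Zflat
        np.clip(INH, 0.0, None, out=INH)

        # 2. nodes (in creation order)
        for n, in_sl, z_sl in self._node_list:
            out = n.func(t, self._node_buf[in_sl]) if n.size_in else n.func(t)
            z[z_sl] = out

        # 3. channel pool
        p = self.pool
        afilt_alpha = self.alphas[TAU_FAST]
        if p.n:
            J = p.gain_enc * X[: p.C][p.chan] + p.bias
            J -= INHIBITION_STRENGTH * INH[: p.C][p.chan]
            if self._is_rate:
                Jc = np.maximum(J, 1.0 + 1e-9)
                a = 1.0 / (net.tau_ref - net.tau_rc * np.log1p(-1.0 / Jc))
                a[J <= 1.0] = 0.0
                p.rates = a
            else:
                a = _lif_spike_step(p.v, p.ref, J, dt, net.tau_rc, net.tau_ref,
                                    p.out)
            self._pool_afilt += afilt_alpha * (a - self._pool_afilt)
            y = np.add.reduceat(p.dflat * a, p.offsets)
            z[1: 1 + p.C] = y  # group outputs follow the constant in z
            np.maximum(self._pool_ymax, np.abs(zfast[1: 1 + p.C]),
                       out=self._pool_ymax)

        # 4. ensembles + learned decoders + PES
        for e, st in self._ens_list:
            J = st.enc_scaled @ X[st.x_slice]
            J += st.bias
            J -= INHIBITION_STRENGTH * INH[st.inh_idx]
            if self._is_rate:
                Jc = np.maximum(J, 1.0 + 1e-9)
                a = 1.0 / (net.tau_ref - net.tau_rc * np.log1p(-1.0 / Jc))
                a[J <= 1.0] = 0.0
            else:
                a = _lif_spike_step(st.v, st.ref, J, dt, net.tau_rc,
                                    net.tau_ref, st.out)
            st.afilt += afilt_alpha * (a - st.afilt)
            for rec in st.learned:
                z[rec["lc"]._z_slice] = rec["D"].T @ st.afilt
                if rec["err"] is not None and rec["coef"] != 0.0:
                    E = zfast[rec["err"]]
                    np.multiply(st.afilt[:, None], E, out=rec["buf"])
                    rec["buf"] *= rec["coef"]
                    rec["D"] += rec["buf"]
            for drec in st.decoded:
                z[drec["dec"]._z_slice] = drec["D"].T @ st.afilt

        # 5. synapse filters (all taus at once)
        ZF = self.ZBUF[1:]
        np.subtract(z, ZF, out=self._ftmp)
        self._ftmp *= self._alpha_col
        ZF += self._ftmp

        # 6. probes
        self._step_count += 1
        for p_ in net.probes:
            rec = self._probe_data[id(p_)]
            if self._step_count % rec["stride"] == 0:
                rec["t"].append(t)
                rec["v"].append(self._probe_value(p_))

        self.t = t + dt

    def _probe_value(self, p: Probe):
        if isinstance(p.target, tuple) and p.target[0] == "rates":
            obj = p.target[1]
            if isinstance(obj, ChannelGroup):
                sl = self._group_neuron[id(obj)]
                return float(np.mean(self._pool_afilt[sl]))
            st = self._ens[id(obj)]
            return st.afilt.copy()
        sl = p.target._z_slice
        return self.ZBUF[self._tau_row.get(p.synapse, 0)][sl].copy()

    def run(self, duration: float):
        for _ in range(int(round(duration / self.dt))):
            self.step()

    # -- results -----------------------------------------------------------
    def time(self, probe: Probe):
        return np.asarray(self._probe_data[id(probe)]["t"])

    def data(self, probe: Probe):
        return np.asarray(self._probe_data[id(probe)]["v"])

    def value(self, signal: _Signal, synapse: Optional[float] = TAU_FAST):
        """Current (optionally filtered) value of any signal source."""
        src = self.ZBUF[self._tau_row[synapse]]
        return src[signal._z_slice].copy()

    def decoders(self, lc: LearnedConnection):
        return self._lc_state[id(lc)]["D"]

    def saturation(self, group: ChannelGroup):
        """Peak decoded magnitude of each channel as a fraction of radius."""
        sl = self._group_chan[id(group)]
        return self._pool_ymax[sl] / group.radius

    def save_probes(self, probes: dict, path, hdf5: bool = False):
        """Write probe data to CSV files (or one HDF5 container).

        ``probes`` maps names to :class:`Probe` objects.  CSV columns are
        ``time_s, value...``; with ``hdf5=True`` a single ``.h5`` file holds
        one dataset per probe (preferred for long runs).
        """
        from pathlib import Path
        path = Path(path)
        if hdf5:
            import h5py
            with h5py.File(path, "w") as f:
                for name, p in probes.items():
                    g = f.create_group(name)
                    g.create_dataset("time_s", data=self.time(p))
                    g.create_dataset("value", data=self.data(p))
            return path
        path.mkdir(parents=True, exist_ok=True)
        for name, p in probes.items():
            t = self.time(p)
            v = np.atleast_2d(np.asarray(self.data(p), float))
            if v.shape[0] != t.size:
                v = v.T
            cols = np.column_stack([t, v])
            header = "time_s," + ",".join(
                f"value_{i}" for i in range(v.shape[1]))
            np.savetxt(path / f"{name}.csv", cols, delimiter=",",
                       header=header, comments="")
        return path


# ---------------------------------------------------------------------------
# Standard subnetworks
# ---------------------------------------------------------------------------

def make_integrator(net: Network, name: str, d: int = 1, input_scale: float = 1.0,
                    feedback: float = 1.0, n_neurons: int = 150,
                    radius: float = 1.0, tau: float = TAU_SLOW) -> ChannelGroup:
    """A neural integrator: ``d`` line-attractor channels.

    A constant input ``c`` changes the decoded value at ``c * input_scale``
    per second; with zero input the value holds (drift bounded by the
    recurrent decoding error, hence the low decoder regularisation and the
    relatively large neuron count).  Values saturate at ``radius`` (inspect
    :meth:`Simulator.saturation`).
    """
    g = net.channels(name, d, n_neurons, radius=radius, regularization=0.02)
    net.connect(g, g, transform=feedback, synapse=tau)
    g.input_transform = tau * input_scale  # callers scale their input with this
    return g


def make_gated_memory(net: Network, name: str, d: int, n_neurons: int = 100,
                      radius: float = 1.0, gain: float = 30.0,
                      tau: float = TAU_SLOW, function=None):
    """A load/hold memory (line attractor with a gated difference input).

    Returns ``(mem, diff, load_port)``.  The memory holds its decoded value
    while the scalar load signal is 0 and converges to the input routed into
    ``diff`` while the load signal is 1.  Implemented in the standard NEF way:
    a difference population drives the memory and is inhibited whenever the
    memory should hold, so holding is the default state.
    """
    mem = net.channels(name, d, n_neurons, radius=radius,
                       regularization=0.02, function=function)
    diff = net.channels(name + ".diff", d, max(40, int(0.6 * n_neurons)),
                        radius=2.0 * radius)
    net.connect(mem, mem, transform=1.0, synapse=tau)
    net.connect(mem, diff, transform=-1.0, synapse=TAU_FAST)
    net.connect(diff, mem, transform=tau * gain, synapse=tau)
    # the load port: an inverting node so that load=1 -> diff uninhibited
    inv = net.node(name + ".hold", lambda t, x: max(0.0, 1.0 - x[0]),
                   size_in=1, size_out=1)
    net.connect(inv, diff, transform=np.ones((d, 1)), synapse=None,
                inhibitory=True)
    return mem, diff, inv


def make_threshold_detector(net: Network, name: str, source: _Signal,
                            threshold: float, scale: float = 1.0,
                            n_neurons: int = 40, invert: bool = False,
                            source_transform=None) -> ChannelGroup:
    """A population decoding a step function of a scalar signal.

    The output approximates ``1`` when the (transformed) source exceeds
    ``threshold`` and ``0`` otherwise (swapped when ``invert``).  All firing
    intercepts are aligned on the active side so the population is silent —
    an exact zero — in the "off" region; this is the mechanism used throughout
    the model for clean inhibitory gating.  ``scale`` maps the expected input
    range onto the unit radius.
    """
    sgn = -1.0 if invert else 1.0

    def step_fn(x):
        return (np.asarray(x) > 0).astype(float)

    g = net.channels(name, 1, n_neurons, radius=1.0, intercepts=(0.02, 0.95),
                     encoders="positive", function=step_fn)
    if source_transform is None:
        source_transform = np.ones((1, source.size_out))
    net.connect(source, g, transform=np.asarray(source_transform) * scale * sgn,
                synapse=TAU_FAST)
    net.connect(net.constant, g,
                transform=np.array([[-threshold * scale * sgn]]), synapse=None)
    return g
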