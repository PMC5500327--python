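import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def run_channel(value, n_neurons=80, seed=0, mode="rate", duration=0.5,
                probe_synapse=0.02, **channel_kw):
    """Decode a constant scalar through one population (test helper)."""
    from neurohrl import nef_core as nc
    net = nc.Network(seed=seed, mode=mode)
    src = net.node("in", lambda t: float(value), size_out=1)
    g = net.channels("chan", 1, n_neurons, **channel_kw)
    net.connect(src, g)
    p = net.probe(g, every=0.001, synapse=probe_synapse)
    sim = nc.Simulator(net)
    sim.run(duration)
    return sim.data(p)[:, 0], sim.time(p), sim
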