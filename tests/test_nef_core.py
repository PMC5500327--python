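"""Unit and property tests for the NEF substrate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neurohrl import nef_core as nc
from conftest import run_channel


# ---------------------------------------------------------------------------
# LIF rate model
# ---------------------------------------------------------------------------

class TestLifRate:
    def test_at_and_below_threshold_is_silent(self):
        assert nc.lif_rate(1.0) == 0.0
        assert nc.lif_rate(0.3) == 0.0
        assert nc.lif_rate(-5.0) == 0.0

    def test_closed_form_value(self):
        # 1 / (tau_ref - tau_rc * ln(1 - 1/J)) at J=2
        expected = 1.0 / (0.002 - 0.02 * np.log(0.5))
        assert nc.lif_rate(2.0, 0.02, 0.002) == pytest.approx(expected)
        assert expected == pytest.approx(63.04, abs=0.01)

    def test_refractory_asymptote(self):
        assert nc.lif_rate(1e12, 0.02, 0.002) == pytest.approx(500.0, rel=1e-3)

    @given(st.floats(1.0, 50.0), st.floats(1.0, 50.0))
    @settings(deadline=None, max_examples=50)
    def test_monotone_in_current(self, j1, j2):
        lo, hi = sorted((j1, j2))
        assert nc.lif_rate(lo) <= nc.lif_rate(hi)

    def test_rejects_non_finite_current(self):
        with pytest.raises(ValueError):
            nc.lif_rate(np.nan)
        with pytest.raises(ValueError):
            nc.lif_rate(np.array([1.0, np.inf]))

    def test_rejects_bad_time_constants(self):
        with pytest.raises(ValueError):
            nc.lif_rate(2.0, tau_rc=0.0)
        with pytest.raises(ValueError):
            nc.lif_rate(2.0, tau_ref=-1e-3)


class TestEncoding:
    def test_gain_bias_pin_intercept_and_max_rate(self):
        gain, bias = nc.gain_bias([100.0], [0.2])
        # silent at the intercept, max rate at the radius
        assert nc.lif_rate(gain[0] * 0.2 + bias[0]) == pytest.approx(0.0, abs=1e-6)
        assert nc.lif_rate(gain[0] * 1.0 + bias[0]) == pytest.approx(100.0, rel=1e-6)

    def test_zero_input_drives_bias_current_only(self):
        gain, bias = nc.gain_bias([80.0, 150.0], [-0.5, 0.3])
        enc = np.array([[1.0], [-1.0]])
        a = nc.tuning_curves(gain, bias, enc, [[0.0]])
        expected = [nc.lif_rate(b) for b in bias]
        assert np.allclose(a[0], expected)

    def test_encoder_contribution_is_linear_in_input(self):
        gain, bias = nc.gain_bias([120.0], [-0.9])
        enc = np.array([[0.6, 0.8]])
        x1 = np.array([[0.1, 0.2]])
        x2 = 2.0 * x1
        j = lambda x: gain * (x @ enc.T) + bias
        assert np.allclose(j(x2) - bias, 2.0 * (j(x1) - bias))


# ---------------------------------------------------------------------------
# Decoder solving
# ---------------------------------------------------------------------------

class TestSolveDecoders:
    def _population(self, n, rng, d=1):
        gain, bias = nc.gain_bias(rng.uniform(50, 200, n),
                                  rng.uniform(-0.95, 0.95, n))
        enc = rng.choice([-1.0, 1.0], size=(n, d))
        return gain, bias, enc

    def test_zero_target_gives_zero_decoders(self, rng):
        gain, bias, enc = self._population(30, rng)
        pts = np.linspace(-1, 1, 100)[:, None]
        A = nc.tuning_curves(gain, bias, enc, pts)
        D = nc.solve_decoders(A, np.zeros((100, 1)))
        assert np.allclose(D, 0.0)

    def test_identity_decode_rmse_under_5_percent(self, rng):
        gain, bias, enc = self._population(100, rng)
        pts = np.linspace(-1, 1, 200)[:, None]
        A = nc.tuning_curves(gain, bias, enc, pts)
        D = nc.solve_decoders(A, pts)
        rmse = np.sqrt(np.mean((A @ D - pts) ** 2))
        assert rmse < 0.05

    def test_matches_dense_normal_equation_oracle(self, rng):
        # brute-force ridge solution on a 5-neuron instance
        gain, bias, enc = self._population(5, rng)
        pts = np.linspace(-1, 1, 40)[:, None]
        A = nc.tuning_curves(gain, bias, enc, pts)
        reg = 0.1
        D = nc.solve_decoders(A, pts, reg)
        n = A.shape[0]
        sigma = reg * A.max()
        oracle = np.linalg.inv(A.T @ A / n + sigma ** 2 * np.eye(5)) @ (A.T @ pts / n)
        assert np.allclose(D, oracle, atol=1e-10)

    def test_all_silent_population_rejected(self):
        with pytest.raises(ValueError):
            nc.solve_decoders(np.zeros((50, 10)), np.ones((50, 1)))

    def test_local_optimality_against_perturbations(self, rng):
        gain, bias, enc = self._population(40, rng)
        pts = np.linspace(-1, 1, 100)[:, None]
        A = nc.tuning_curves(gain, bias, enc, pts)
        D = nc.solve_decoders(A, pts)
        n = A.shape[0]
        sigma = 0.1 * A.max()

        def loss(Dx):
            return (np.mean((A @ Dx - pts) ** 2) +
                    sigma ** 2 * np.sum(Dx ** 2))

        base = loss(D)
        for _ in range(20):
            assert loss(D + 1e-4 * rng.standard_normal(D.shape)) >= base


# ---------------------------------------------------------------------------
# PES learning rule
# ---------------------------------------------------------------------------

class TestPes:
    def test_zero_error_is_fixed_point(self, rng):
        a = rng.uniform(0, 200, 30)
        d = nc.pes_delta(np.zeros(2), a, kappa=1e-3, dt=1e-3)
        assert np.allclose(d, 0.0)

    def test_silent_neurons_do_not_update(self, rng):
        a = rng.uniform(0, 200, 30)
        a[7] = 0.0
        d = nc.pes_delta(np.array([0.5, -0.2]), a, kappa=1e-3, dt=1e-3)
        assert np.allclose(d[7], 0.0)
        assert not np.allclose(d, 0.0)

    def test_update_is_local(self, rng):
        # row i depends only on a_i and the error
        a = rng.uniform(0, 200, 30)
        e = np.array([0.3])
        d1 = nc.pes_delta(e, a, 1e-3, 1e-3)
        a2 = a.copy()
        a2[np.arange(30) != 5] = rng.uniform(0, 200, 29)
        d2 = nc.pes_delta(e, a2, 1e-3, 1e-3)
        assert d1[5] == pytest.approx(d2[5])

    def test_closed_loop_error_descends(self):
        # learn a constant target from a constant input
        net = nc.Network(seed=7)
        ens = net.ensemble("e", 60, 1)
        src = net.node("x", lambda t: 0.4, size_out=1)
        net.connect(src, ens)
        lc = net.learned_connection(ens, 1, error=None, kappa=2e-3)
        err = net.node("err", lambda t, x: 0.7 - x[0], size_in=1, size_out=1)
        net.connect(lc, err)
        lc.error = err
        p = net.probe(lc, every=0.01)
        sim = nc.Simulator(net)
        sim.run(1.0)
        d = sim.data(p)[:, 0]
        early = abs(d[:10] - 0.7).mean()
        late = abs(d[-10:] - 0.7).mean()
        assert late < 0.1 * early

    def test_stationary_when_output_matches_target(self):
        # decoders that already hit the target barely move under PES
        net = nc.Network(seed=8)
        ens = net.ensemble("e", 60, 1)
        src = net.node("x", lambda t: 0.4, size_out=1)
        net.connect(src, ens)
        lc = net.learned_connection(ens, 1, error=None, kappa=2e-3)
        err = net.node("err", lambda t, x: 0.7 - x[0], size_in=1, size_out=1)
        net.connect(lc, err)
        lc.error = err
        sim = nc.Simulator(net)
        sim.run(2.0)  # converge
        D0 = sim.decoders(lc).copy()
        sim.run(0.5)
        drift = np.abs(sim.decoders(lc) - D0).max()
        assert drift < 0.02 * max(np.abs(D0).max(), 1e-9)


# ---------------------------------------------------------------------------
# Integrators, memories, gating
# ---------------------------------------------------------------------------

class TestIntegrator:
    def _integrator_net(self, input_fn, seed=2):
        net = nc.Network(seed=seed)
        src = net.node("c", input_fn, size_out=1)
        integ = nc.make_integrator(net, "int", 1)
        net.connect(src, integ, transform=integ.input_transform,
                    synapse=nc.TAU_SLOW)
        p = net.probe(integ, every=0.01)
        return net, p

    def test_holds_value_within_5pct_over_1s(self):
        net, p = self._integrator_net(lambda t: 1.0 if t < 0.5 else 0.0)
        sim = nc.Simulator(net)
        sim.run(1.6)
        d, tt = sim.data(p)[:, 0], sim.time(p)
        v0 = d[np.searchsorted(tt, 0.6)]
        v1 = d[np.searchsorted(tt, 1.6) - 1]
        assert abs(v1 - v0) < 0.05

    def test_ramp_matches_analytic_integral(self):
        net, p = self._integrator_net(lambda t: 1.0 if t < 0.5 else 0.0)
        sim = nc.Simulator(net)
        sim.run(0.6)
        d, tt = sim.data(p)[:, 0], sim.time(p)
        assert d[np.searchsorted(tt, 0.58)] == pytest.approx(0.5, abs=0.08)

    def test_saturation_is_reported(self):
        net = nc.Network(seed=3)
        src = net.node("c", lambda t: 1.0, size_out=1)
        integ = nc.make_integrator(net, "int", 1, radius=0.5)
        net.connect(src, integ, transform=integ.input_transform,
                    synapse=nc.TAU_SLOW)
        sim = nc.Simulator(net)
        sim.run(2.0)
        assert sim.saturation(integ)[0] > 0.9


class TestGatedMemory:
    def test_load_hold_overwrite(self):
        net = nc.Network(seed=4)
        u = net.node("u", lambda t: 0.7 if t < 1.0 else -0.4, size_out=1)
        load = net.node("load", lambda t: 1.0 if (0.2 < t < 0.3 or
                                                  1.2 < t < 1.3) else 0.0,
                        size_out=1)
        mem, diff, hold = nc.make_gated_memory(net, "mem", 1)
        net.connect(u, diff, transform=1.0, synapse=nc.TAU_FAST)
        net.connect(load, hold, synapse=None)
        p = net.probe(mem, every=0.01)
        sim = nc.Simulator(net)
        sim.run(1.8)
        d, tt = sim.data(p)[:, 0], sim.time(p)
        at = lambda x: d[np.searchsorted(tt, x)]
        assert abs(at(0.15)) < 0.1                      # empty before load
        assert at(0.6) == pytest.approx(0.7, abs=0.1)   # loaded
        assert at(1.15) == pytest.approx(0.7, abs=0.12)  # held against new input
        assert at(1.75) == pytest.approx(-0.4, abs=0.1)  # overwritten


class TestInhibitoryGating:
    def _gated(self, gate_value, seed=5):
        net = nc.Network(seed=seed)
        src = net.node("x", lambda t: 0.8, size_out=1)
        gate = net.node("g", lambda t: float(gate_value), size_out=1)
        g = net.channels("sig", 1, 80)
        net.connect(src, g)
        net.connect(gate, g, transform=[[1.0]], synapse=nc.TAU_FAST,
                    inhibitory=True)
        p = net.probe(g, every=0.01)
        sim = nc.Simulator(net)
        sim.run(0.4)
        return abs(sim.data(p)[-5:, 0].mean())

    def test_full_gate_silences_output(self):
        assert self._gated(1.0) < 0.02

    def test_open_gate_passes_signal(self):
        assert self._gated(0.0) == pytest.approx(0.8, abs=0.06)

    def test_attenuation_monotone_in_gate_strength(self):
        outs = [self._gated(v) for v in (0.0, 0.1, 0.2, 0.3, 0.5, 1.0)]
        for a, b in zip(outs, outs[1:]):
            assert b <= a + 0.03


class TestThresholdDetector:
    def test_step_response(self):
        net = nc.Network(seed=6)
        x = net.node("x", lambda t: t, size_out=1)  # ramp 0..1
        det = nc.make_threshold_detector(net, "det", x, threshold=0.5,
                                         scale=2.0)
        p = net.probe(det, every=0.01)
        sim = nc.Simulator(net)
        sim.run(1.0)
        d, tt = sim.data(p)[:, 0], sim.time(p)
        assert abs(d[np.searchsorted(tt, 0.40)]) < 0.05
        assert d[np.searchsorted(tt, 0.75)] > 0.8


# ---------------------------------------------------------------------------
# Rate/spiking equivalence and determinism
# ---------------------------------------------------------------------------

class TestModes:
    def test_spiking_matches_rate_on_communication_channel(self):
        vals = {}
        for mode in ("rate", "spiking"):
            d, tt, _ = run_channel(0.5, mode=mode, duration=1.0, seed=11)
            vals[mode] = d[np.searchsorted(tt, 0.3):].mean()
        assert vals["spiking"] == pytest.approx(vals["rate"], abs=0.05)

    def test_mode_switch_preserves_population_parameters(self):
        sims = {}
        for mode in ("rate", "spiking"):
            _, _, sim = run_channel(0.5, mode=mode, duration=0.01, seed=12)
            sims[mode] = sim
        assert np.array_equal(sims["rate"].pool.gain_enc,
                              sims["spiking"].pool.gain_enc)
        assert np.array_equal(sims["rate"].pool.bias,
                              sims["spiking"].pool.bias)

    @pytest.mark.parametrize("mode", ["rate", "spiking"])
    def test_identical_seeds_give_identical_runs(self, mode):
        d1, _, _ = run_channel(0.3, mode=mode, duration=0.2, seed=13)
        d2, _, _ = run_channel(0.3, mode=mode, duration=0.2, seed=13)
        assert np.array_equal(d1, d2)
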