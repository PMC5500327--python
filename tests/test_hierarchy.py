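"""Tests for hierarchical composition and layer interactions."""

import numpy as np
import pytest

from neurohrl import nef_core as nc
from neurohrl import hierarchy as hi
from neurohrl.environments import CARDINAL_VECTORS, StimuliEnv
from neurohrl.hierarchy import (InteractionSpec, LayerConfig, LayerSpec,
                                SubgoalSpec, compose, pseudoreward_value)


def small_cfg(**kw):
    base = dict(n_actions=4, action_vectors=CARDINAL_VECTORS, theta=0.2,
                q_neurons=80, bg_neurons=30, mem_neurons=40, relay_neurons=30,
                integ_neurons=60, out_pop_neurons=20)
    base.update(kw)
    return LayerConfig(**base)


def dummy_env_node(net, d_env=2, reward=0.0):
    """A minimal environment port: constant state, periodic terminations."""
    def fn(t, x):
        out = np.zeros(d_env + 3)
        out[0] = 0.3
        out[d_env] = reward
        out[d_env + 1] = 1.0 if (t % 0.8) < 0.01 else 0.0
        return out
    return net.node("env", fn, size_in=2, size_out=d_env + 3)


class TestPseudoreward:
    def test_paper_magnitudes_for_delivery_schedule(self):
        s0 = np.array([0.25, 0.75])
        at_goal = pseudoreward_value([0.26, 0.74], s0, theta_r=0.15,
                                     r_plus=1.5, r_minus=-0.05)
        away = pseudoreward_value([0.8, 0.2], s0, theta_r=0.15,
                                  r_plus=1.5, r_minus=-0.05)
        assert at_goal == 1.5
        assert away == -0.05

    def test_default_binary_form(self):
        s0 = np.zeros(3)
        assert pseudoreward_value([0.05, 0, 0], s0, theta_r=0.1) == 1.0
        assert pseudoreward_value([0.5, 0, 0], s0, theta_r=0.1) == 0.0

    def test_dims_mask_restricts_distance(self):
        s0 = np.array([0.0, 9.0])
        r = pseudoreward_value([0.01, -3.0], s0, theta_r=0.1,
                               dims=np.array([0]))
        assert r == 1.0


class TestContextConcat:
    def test_dimensions_add(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net, d_env=3)
        upper = LayerSpec(small_cfg(n_actions=2, action_vectors=np.eye(2),
                                    out_pop_zero_aligned=True))
        lower = LayerSpec(small_cfg())
        agent = compose(net, env_node, 3, [lower, upper],
                        [[InteractionSpec("context")]])
        assert agent.layers[0].dual.d_state == 5
        assert agent.layers[1].dual.d_state == 3

    def test_context_separates_q_values(self):
        # alternate two contexts with opposite-signed targets; the decoded
        # values at the same environmental state must end up separated
        net = nc.Network(seed=1)
        ctx = {"v": np.array([1.0, 0.0])}
        src = net.node("s", lambda t: np.concatenate([[0.4, -0.2], ctx["v"]]),
                       size_out=4)
        # reload the stored state at each phase boundary so the training
        # error always matches the context held in memory
        gate = net.node("gate", lambda t: np.array(
            [0.0, 1.0 if (t % 0.5) < 0.12 else 0.0, 0.0]), size_out=3)
        err = net.node("e", lambda t: (np.array([0.5, 0.0])
                                       if ctx["v"][0] > 0.5
                                       else np.array([-0.5, 0.0]))
                       if (t % 0.5) > 0.15 else np.zeros(2),
                       size_out=2)
        from neurohrl import action_values as av
        dual = av.build_dual_q(net, "L", src, 4, 2, e_td_source=err,
                               gate_node=gate, theta=0.3, q_neurons=300)
        sim = nc.Simulator(net)
        for phase in range(8):
            ctx["v"] = np.array([1.0, 0.0]) if phase % 2 == 0 else \
                np.array([0.0, 1.0])
            sim.run(0.5)
        st = sim._ens[id(dual.prev_q)]
        D = sim.decoders(dual.prev_out)

        def qat(c):
            s = np.concatenate([[0.4, -0.2], c])
            a = nc.lif_rate(np.maximum(st.enc_scaled @ s + st.bias, 0.0))
            return (D.T @ a)[0]

        q1, q2 = qat([1.0, 0.0]), qat([0.0, 1.0])
        assert q1 - q2 > 0.2
        assert q1 > 0.0 and q2 < 0.0


class TestStateAbstraction:
    def _gated_state(self, upper_action, state, seed=0):
        env = StimuliEnv(seed=0)
        net = nc.Network(seed=seed)
        s = net.node("s", lambda t: np.asarray(state, float), size_out=8)
        up = net.node("up", lambda t: np.asarray(upper_action, float),
                      size_out=2)
        gate = net.channels("gate", 8, 40, intercepts=(0.02, 0.95),
                            encoders="positive", radius=1.2)
        net.connect(s, gate, transform=1.0)
        net.connect(up, gate, transform=env.state_mask, synapse=nc.TAU_FAST,
                    inhibitory=True)
        p = net.probe(gate, every=0.01)
        sim = nc.Simulator(net)
        sim.run(0.3)
        return sim.data(p)[-3:].mean(axis=0)

    def test_shape_rule_passes_only_shape_block(self):
        state = [1, 0, 0, 1, 0, 0, 0, 1]
        out = self._gated_state([1.0, 0.0], state)
        assert np.all(np.abs(out[[0, 1, 5, 6, 7]]) < 0.05)
        assert out[3] > 0.8

    def test_orientation_rule_passes_only_orientation_block(self):
        state = [1, 0, 0, 1, 0, 0, 0, 1]
        out = self._gated_state([0.0, 1.0], state)
        assert np.all(np.abs(out[[0, 1, 2, 3, 4]]) < 0.05)
        assert out[7] > 0.8

    def test_null_action_passes_everything(self):
        state = [1, 0, 0, 1, 0, 0, 0, 1]
        out = self._gated_state([0.0, 0.0], state)
        assert np.all(out[[0, 3, 7]] > 0.8)


class TestAbstractTermination:
    def _detector(self, state_fn, oh_fn, timeout=5.0, T=3.0):
        net = nc.Network(seed=0)
        s = net.node("s", state_fn, size_out=2)
        env_term = net.node("et", lambda t: np.zeros(2), size_out=2)
        spec = SubgoalSpec(targets=np.array([[0.8, 0.8], [-0.8, -0.8]]),
                           theta_r=0.2, timeout=timeout)
        det = hi.make_abstract_termination(net, "det", s, 2, spec, env_term,
                                           np.eye(2))
        oh = net.node("oh", oh_fn, size_out=2)
        T_in = np.zeros((det.size_in, 2))
        T_in[det._oh_rows] = np.eye(2)
        net.connect(oh, det, transform=T_in, synapse=None)
        p = net.probe(det, every=0.001, synapse=None)
        sim = nc.Simulator(net)
        sim.run(T)
        return sim.data(p), sim.time(p)

    # the first pulse (~0.3 s) is the detector's kick-off that starts the
    # upper layer's first cycle; the assertions below skip it

    def test_pulse_on_subgoal_arrival(self):
        d, tt = self._detector(
            lambda t: np.array([0.8, 0.8]) if t > 1.0 else np.zeros(2),
            lambda t: np.array([1.0, 0.0]))
        pulses = tt[(d[:, 0] > 0.5) & (tt > 0.4)]
        assert len(pulses) >= 1
        assert pulses[0] == pytest.approx(1.0, abs=0.1)

    def test_timeout_closes_cycle_without_subgoal(self):
        d, tt = self._detector(lambda t: np.zeros(2),
                               lambda t: np.array([1.0, 0.0]), timeout=1.5)
        pulses = tt[(d[:, 0] > 0.5) & (tt > 0.4)]
        assert len(pulses) >= 1
        assert pulses[0] == pytest.approx(0.3 + 1.5, abs=0.1)

    def test_wrong_subgoal_does_not_terminate(self):
        d, tt = self._detector(
            lambda t: np.array([0.8, 0.8]) if t > 1.0 else np.zeros(2),
            lambda t: np.array([0.0, 1.0]), timeout=50.0)
        assert not np.any(d[tt > 0.4, 0] > 0.5)


class TestCompose:
    def test_single_layer_is_flat_agent(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net)
        agent = compose(net, env_node, 2, [LayerSpec(small_cfg())])
        assert len(agent.layers) == 1
        assert agent.layers[0].dual.d_state == 2

    def test_unknown_interaction_rejected(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net)
        with pytest.raises(ValueError):
            compose(net, env_node, 2,
                    [LayerSpec(small_cfg()), LayerSpec(small_cfg())],
                    [[InteractionSpec("telepathy")]])

    def test_missing_interaction_list_rejected(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net)
        with pytest.raises(ValueError):
            compose(net, env_node, 2,
                    [LayerSpec(small_cfg()), LayerSpec(small_cfg())],
                    interactions=[[], []])

    def test_subgoal_termination_requires_spec(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net)
        with pytest.raises(ValueError):
            compose(net, env_node, 2,
                    [LayerSpec(small_cfg()),
                     LayerSpec(small_cfg(), termination="subgoal")],
                    [[InteractionSpec("context")]])

    def test_three_layer_chain_builds_and_runs(self):
        net = nc.Network(seed=0)
        env_node = dummy_env_node(net, d_env=2)
        sub = SubgoalSpec(targets=np.array([[0.3, 0.0], [0.0, 0.3]]),
                          theta_r=0.2, timeout=2.0)
        specs = [LayerSpec(small_cfg()),
                 LayerSpec(small_cfg(n_actions=2, action_vectors=np.eye(2),
                                     out_pop_zero_aligned=True),
                           termination="subgoal", subgoal=sub),
                 LayerSpec(small_cfg(n_actions=2, action_vectors=np.eye(2),
                                     out_pop_zero_aligned=True),
                           termination="subgoal", subgoal=sub)]
        inter = [[InteractionSpec("context")], [InteractionSpec("context")]]
        agent = compose(net, env_node, 2, specs, inter)
        sim = nc.Simulator(net)
        sim.run(2.0)  # smoke: three concurrent SMDP cycles
        assert len(agent.layers) == 3
        assert agent.layers[0].dual.d_state == 4

    def test_both_layers_learn_during_joint_run(self):
        net = nc.Network(seed=2)

        def fn(t, x):  # environment paying reward every cycle
            out = np.zeros(5)
            out[0] = np.sin(t)
            out[2] = 0.8
            out[3] = 1.0 if (t % 0.7) < 0.01 else 0.0
            return out

        env_node = net.node("env", fn, size_in=2, size_out=5)
        sub = SubgoalSpec(targets=np.array([[0.9, 0.0], [-0.9, 0.0]]),
                          theta_r=0.5, timeout=1.5)
        specs = [LayerSpec(small_cfg()),
                 LayerSpec(small_cfg(n_actions=2, action_vectors=np.eye(2),
                                     out_pop_zero_aligned=True),
                           termination="subgoal", subgoal=sub)]
        agent = compose(net, env_node, 2, specs,
                        [[InteractionSpec("context")]])
        sim = nc.Simulator(net)
        sim.run(8.0)
        for lay in agent.layers:
            d = sim.decoders(lay.dual.prev_out)
            assert np.abs(d).max() > 0.0


class TestModularity:
    def test_scripted_upper_replaces_neural_upper(self):
        # a lower layer driven by a scripted context emitter runs exactly as
        # in the hierarchical wiring: its ports are all it sees
        net = nc.Network(seed=3)
        env_node = dummy_env_node(net, d_env=2)
        script = net.node("upper", lambda t: np.array([1.0, 0.0]) if t < 1.0
                          else np.array([0.0, 1.0]), size_out=2)
        concat = net.node("ctx", lambda t, x: x, size_in=4, size_out=4)
        T = np.zeros((4, 5))
        T[:2, :2] = np.eye(2)
        net.connect(env_node, concat, transform=T, synapse=None)
        T = np.zeros((4, 2))
        T[2:] = np.eye(2)
        net.connect(script, concat, transform=T, synapse=None)
        reward = net.node("r", lambda t, x: x, size_in=1, size_out=1)
        net.connect(env_node, reward, transform=np.array([[0, 0, 1.0, 0, 0]]),
                    synapse=None)
        term_T = np.array([[0, 0, 0, 1.0, 0], [0, 0, 0, 0, 1.0]])
        lay = hi.build_layer(net, "L0", small_cfg(), concat, 4, reward,
                             env_node, term_T)
        sim = nc.Simulator(net)
        sim.run(3.0)
        assert len(lay.decisions) >= 2  # full SMDP cycles ran
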