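"""Experiment runners, metrics and multi-run statistics.

Each ``run_*`` function builds an environment and agent from a seed plus a
handful of size parameters, simulates it, and returns a plain-dict record
(config snapshot, event logs, metric series).  Records are fully reproducible
from ``(parameters, seed)``.

The default problem sizes here are desk-scale: they are chosen so a run
completes in minutes on a single CPU while preserving the qualitative
behaviour of interest (learning curves, hierarchical-versus-flat ordering,
activity patterns).  Durations, neuron counts, timestep and exploration
noise are all exposed as arguments for larger-scale runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from . import nef_core as nef
from . import environments as envs
from . import hierarchy as hier
from . import reference_rl as ref
from .environments import (CARDINAL_VECTORS, DeliveryConfig, DeliveryEnv,
                           ContextNavEnv, GridNavEnv, StimuliEnv,
                           scripted_delivery_run)
from .hierarchy import (InteractionSpec, LayerConfig, LayerSpec, SubgoalSpec,
                        compose)
from .nef_core import Network, Simulator, _stable_seed


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def latency(trial) -> int:
    """Steps taken minus the Manhattan-optimal number of steps."""
    return trial.steps - trial.optimal


def block_means(values, block: int) -> np.ndarray:
    """Mean of consecutive blocks (the trailing partial block included)."""
    v = np.asarray(values, float)
    return np.array([v[i:i + block].mean() for i in range(0, len(v), block)])


def adjusted_cumreward(times, cum, baseline_rate: float) -> np.ndarray:
    """Cumulative reward minus the random-policy accumulation rate."""
    return np.asarray(cum, float) - baseline_rate * np.asarray(times, float)


def terminal_slope(times, cum, fraction: float = 0.25) -> float:
    """Reward-accumulation rate over the last ``fraction`` of the run."""
    times = np.asarray(times, float)
    cum = np.asarray(cum, float)
    t0 = times[-1] * (1 - fraction)
    m = times >= t0
    if m.sum() < 2:
        return 0.0
    return float(np.polyfit(times[m], cum[m], 1)[0])


def reward_rate(cfg: DeliveryConfig, policy: str, duration: float = 20000.0,
                seed: int = 0) -> float:
    """Long-run reward rate of a scripted policy (event-level simulation)."""
    t, c = scripted_delivery_run(cfg, policy, duration, seed)
    return float(c[-1] / t[-1])


def accuracy_blocks(trials, block: int = 60) -> np.ndarray:
    """Fraction of correct responses per block of trials."""
    return block_means([t.correct for t in trials], block)


def activity_blocks(times, activity, trial_ends, blocks=(0, 120, 240, 360),
                    normalize: bool = True) -> np.ndarray:
    """Mean population activity per trial block, normalised to the first.

    ``trial_ends`` are the trial completion times; block ``i`` covers trials
    ``blocks[i]..blocks[i+1]``.
    """
    times = np.asarray(times, float)
    activity = np.asarray(activity, float).ravel()
    trial_ends = np.asarray(trial_ends, float)
    out = []
    for b0, b1 in zip(blocks[:-1], blocks[1:]):
        t0 = 0.0 if b0 == 0 else trial_ends[min(b0, len(trial_ends)) - 1]
        t1 = trial_ends[min(b1, len(trial_ends)) - 1]
        m = (times >= t0) & (times < t1)
        out.append(activity[m].mean() if m.any() else np.nan)
    out = np.asarray(out)
    if normalize and out[0]:
        out = out / out[0]
    return out


def aggregate_runs(series: Sequence[np.ndarray], confidence: float = 0.95):
    """Pointwise mean and t-based confidence half-width over runs.

    Series must share a common x grid.  With a single run the half-width is
    zero-length (mean only) and a warning field is set.
    """
    arr = np.asarray(series, float)
    mean = arr.mean(axis=0)
    n = arr.shape[0]
    if n < 2:
        return {"mean": mean, "ci": None, "n": n,
                "warning": "single run: confidence interval omitted"}
    sem = arr.std(axis=0, ddof=1) / np.sqrt(n)
    half = sem * stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
    return {"mean": mean, "ci": half, "n": n, "warning": None}


# ---------------------------------------------------------------------------
# Grid task
# ---------------------------------------------------------------------------

def grid_layer_config(q_neurons=500, sigma=0.1, gamma=0.3, kappa=1.5e-3,
                      **kw) -> LayerConfig:
    return LayerConfig(
        n_actions=4, action_vectors=CARDINAL_VECTORS, theta=0.2,
        q_neurons=q_neurons, sigma=sigma, gamma=gamma,
        kappa_td=kappa, kappa_cons=kappa, state_radius=1.5,
        bg_input_bias=0.2, bg_input_scale=0.8, **kw)


def run_grid(seed: int = 0, n_trials: int = 100, dt: float = 0.001,
             mode: str = "rate", max_time: float = 2500.0,
             precision: str = "neural", **cfg_kw) -> dict:
    """Flat agent on the 5x5 variable-delay navigation task."""
    net = Network(dt=dt, seed=seed, mode=mode)
    env = GridNavEnv(seed=seed)
    env_node = net.node("env", env, size_in=2, size_out=2 + 3)
    cfg = grid_layer_config(precision=precision, **cfg_kw)
    agent = compose(net, env_node, 2, [LayerSpec(cfg)])
    sim = Simulator(net)
    while len(env.trials) < n_trials and sim.t < max_time:
        sim.run(5.0)
    lat = np.array([t.latency for t in env.trials])
    return {"kind": "grid", "seed": seed, "dt": dt, "mode": mode,
            "trials": env.trials, "latencies": lat, "sim_time": sim.t,
            "decisions": agent.layers[0].decisions,
            "sim": sim, "layer": agent.layers[0],
            "config": asdict(cfg) | {"n_trials": n_trials}}


def run_grid_tabular(seed: int = 0, n_trials: int = 100, **kw) -> dict:
    agent, trials = ref.run_tabular_grid(n_trials=n_trials, seed=seed, **kw)
    return {"kind": "grid_tabular", "seed": seed, "trials": trials,
            "latencies": np.array([t.latency for t in trials]),
            "Q": agent.Q, "agent": agent}


# ---------------------------------------------------------------------------
# Delivery task
# ---------------------------------------------------------------------------

def place_threshold(env: DeliveryEnv, offset: Optional[float] = None,
                    n: int = 64) -> float:
    """Place-vector distance corresponding to an arena offset.

    Used to express the subgoal radius in the state space the agent actually
    sees (mean over sampled directions around the two target locations).
    """
    offset = offset if offset is not None else env.cfg.region_radius
    rng = np.random.default_rng(_stable_seed(0, "place-threshold"))
    ds = []
    for centre in (env.cfg.pickup, env.cfg.dropoff):
        c = np.asarray(centre, float)
        for _ in range(n):
            u = rng.standard_normal(2)
            u /= np.linalg.norm(u)
            p = np.clip(c + offset * u, 0, 1)
            ds.append(np.linalg.norm(env.encode_position(p) -
                                     env.encode_position(c)))
    return float(np.mean(ds))


def delivery_layer_configs(q_neurons=500, sigma=0.15, gamma=0.3, kappa=1.5e-3,
                           precision="neural", state_radius=2.0,
                           upper_timeout=30.0):
    # relay decode bias is amplified ~1/(gamma*tau) on this continual task,
    # so the relays get extra neurons; exploration noise is sized to dominate
    # the residual bias
    lower = LayerConfig(
        n_actions=4, action_vectors=CARDINAL_VECTORS, theta=0.0,  # set later
        q_neurons=q_neurons, relay_neurons=150, mem_neurons=50,
        sigma=sigma, gamma=gamma,
        kappa_td=kappa, kappa_cons=kappa, state_radius=state_radius,
        bg_input_bias=0.2, bg_input_scale=0.8, precision=precision)
    upper = LayerConfig(
        n_actions=2, action_vectors=np.eye(2), theta=0.0,
        q_neurons=q_neurons, relay_neurons=150, mem_neurons=50,
        sigma=sigma, gamma=gamma,
        kappa_td=kappa, kappa_cons=kappa, state_radius=state_radius,
        bg_input_bias=0.2, bg_input_scale=0.8,
        acc_radius=2.0, d_acc_radius=2.0, out_pop_zero_aligned=True,
        precision=precision)
    return lower, upper, upper_timeout


def run_delivery(seed: int = 0, condition: str = "flat",
                 duration: float = 1500.0, dt: float = 0.002,
                 mode: str = "rate", q_neurons: int = 500,
                 sigma: float = 0.15, gamma: float = 0.3, kappa: float = 1.5e-3,
                 pretrain_duration: float = 2000.0,
                 upper_timeout: float = 30.0,
                 config: Optional[DeliveryConfig] = None,
                 initial_decoders=None) -> dict:
    """Delivery task under one of four conditions.

    ``condition``: "flat" (single layer), "hier" (two layers, context +
    pseudoreward interactions), "direct" (hierarchical with perfect-precision
    selection/error), or "transfer" (hierarchical with the lower layer's
    decoders pretrained on randomised-context navigation).
    """
    cfg = config or DeliveryConfig()
    if condition == "transfer" and initial_decoders is None:
        pre = run_pretrain_context(seed=seed, duration=pretrain_duration,
                                   dt=dt, mode=mode, q_neurons=q_neurons,
                                   sigma=sigma, gamma=gamma, kappa=kappa,
                                   config=cfg)
        initial_decoders = {0: pre["decoders"]}

    precision = "direct" if condition == "direct" else "neural"
    net = Network(dt=dt, seed=seed, mode=mode)
    env = DeliveryEnv(cfg, seed=seed, dt=dt)
    d_env = env.state_dim
    env_node = net.node("env", env, size_in=2, size_out=d_env + 3)
    lower, upper, timeout = delivery_layer_configs(
        q_neurons=q_neurons, sigma=sigma, gamma=gamma, kappa=kappa,
        precision=precision, upper_timeout=upper_timeout)
    theta_r = place_threshold(env)
    # consistency threshold: a modest fraction of the place-vector diameter,
    # above the 38-dimensional memory decode noise but far below one step
    diam = 2.0 * np.sqrt(2.0)
    lower.theta = upper.theta = 0.15 * diam

    targets = np.stack([np.concatenate([env.encode_position(cfg.pickup),
                                        np.zeros(2)]),
                        np.concatenate([env.encode_position(cfg.dropoff),
                                        np.zeros(2)])])
    place_dims = np.arange(cfg.n_cells)
    subgoal = SubgoalSpec(targets=targets, theta_r=theta_r, r_plus=1.5,
                          r_minus=-0.05, dims=place_dims, timeout=timeout)

    if condition == "flat":
        specs = [LayerSpec(lower)]
        inter = []
        enc = [lambda n, rng: env.sample_states(n, rng)]
    else:
        specs = [LayerSpec(lower),
                 LayerSpec(upper, termination="subgoal", subgoal=subgoal)]
        inter = [[InteractionSpec("context"),
                  InteractionSpec("reward", subgoal=subgoal)]]
        enc = [lambda n, rng: env.sample_states(n, rng, extra_dims=2),
               lambda n, rng: env.sample_states(n, rng)]

    agent = compose(net, env_node, d_env, specs, inter, encoder_samples=enc,
                    initial_decoders=initial_decoders)
    sim = Simulator(net)
    sim.run(duration)
    times = np.array([p[0] for p in env.reward_series])
    cum = np.array([p[1] for p in env.reward_series])
    return {"kind": "delivery", "condition": condition, "seed": seed,
            "dt": dt, "mode": mode, "duration": duration,
            "times": times, "cum_reward": cum,
            "deliveries": list(env.deliveries), "pickups": list(env.pickups),
            "decisions": [l.decisions for l in agent.layers],
            "env_config": asdict(cfg),
            "config": {"q_neurons": q_neurons, "sigma": sigma,
                       "gamma": gamma, "kappa": kappa,
                       "condition": condition}}


def run_pretrain_context(seed: int = 0, duration: float = 2000.0,
                         dt: float = 0.002, mode: str = "rate",
                         q_neurons: int = 500, sigma: float = 0.15,
                         gamma: float = 0.3, kappa: float = 1.5e-3,
                         config: Optional[DeliveryConfig] = None) -> dict:
    """Pretraining phase for transfer: randomised-context navigation.

    Trains a flat layer over the delivery state space extended with the
    context one-hot (the same 40-dimensional space as the hierarchical lower
    layer), with the environment choosing the target context.  Returns the
    learned decoders for injection into a fresh hierarchical agent.
    """
    cfg = config or DeliveryConfig()
    net = Network(dt=dt, seed=seed, mode=mode)
    env = ContextNavEnv(cfg, seed=_stable_seed(seed, "pre"), dt=dt)
    d_env = env.state_dim
    env_node = net.node("env", env, size_in=2, size_out=d_env + 3)
    lower, _, _ = delivery_layer_configs(q_neurons=q_neurons, sigma=sigma,
                                         gamma=gamma, kappa=kappa)
    lower.theta = 0.15 * 2.0 * np.sqrt(2.0)
    enc = [lambda n, rng: env.sample_states(n, rng)]
    agent = compose(net, env_node, d_env, [LayerSpec(lower)],
                    encoder_samples=enc)
    sim = Simulator(net)
    sim.run(duration)
    layer = agent.layers[0]
    decs = (sim.decoders(layer.dual.prev_out).copy(),
            sim.decoders(layer.dual.cur_out).copy())
    return {"kind": "pretrain_context", "seed": seed,
            "arrivals": list(env.arrivals), "decoders": decs,
            "duration": duration}


# ---------------------------------------------------------------------------
# Stimuli task
# ---------------------------------------------------------------------------

def stimuli_layer_configs(q_neurons=300, sigma=0.05, gamma=0.3,
                          kappa=8e-3):
    lower = LayerConfig(
        n_actions=3, action_vectors=np.eye(3), theta=0.6,
        q_neurons=q_neurons, sigma=sigma, gamma=gamma, kappa_td=kappa,
        kappa_cons=kappa, state_radius=1.2, q_intercepts=(0.05, 0.9),
        bg_input_bias=0.5, bg_input_scale=2.0)
    upper = LayerConfig(
        n_actions=3, action_vectors=StimuliEnv.RULE_VECTORS, theta=0.6,
        q_neurons=q_neurons, sigma=sigma, gamma=gamma, kappa_td=kappa,
        kappa_cons=kappa, state_radius=1.8, q_intercepts=(0.05, 0.9),
        out_pop_zero_aligned=True, bg_input_bias=0.5, bg_input_scale=2.0)
    return lower, upper


def stimuli_encoder_samples(env: StimuliEnv):
    """Encoder distributions for the stimulus-task Q populations.

    The stimulus code is sparse (concatenated one-hots), so Q-population
    encoders are drawn from the states the populations will actually see —
    masked states under each rule for the lower layer, full stimulus vectors
    for the upper layer — giving selective tuning instead of the weak drive
    random-direction encoders produce on categorical inputs.
    """
    stims = env._all_stimuli()
    mask = env.state_mask

    def lower(n, rng):
        # stratified over (stimulus, rule) so every masked state gets an
        # even share of selective neurons
        pool = [(s, rule) for s in stims for rule in range(3)]
        rng.shuffle(pool)
        out = np.zeros((n, 8))
        for i in range(n):
            stim, rule = pool[i % len(pool)]
            v = env.encode(stim).copy()
            if rule < 2:
                v[mask[:, rule] > 0] = 0.0
            out[i] = v
        return out

    def upper(n, rng):
        order = list(rng.permutation(len(stims)))
        return np.stack([env.encode(stims[order[i % len(stims)]])
                         for i in range(n)])

    return [lower, upper]


def run_stimuli(seed: int = 0, mapping: str = "hier", n_trials: int = 360,
                dt: float = 0.001, mode: str = "spiking",
                q_neurons: int = 300, sigma: float = 0.05,
                gamma: float = 0.3, kappa: float = 8e-3,
                rule_bias: float = 0.15, probe_every: float = 0.05) -> dict:
    """Two-layer agent on the 18-stimulus rule task.

    The model is identical in both conditions; only the environment's
    response mapping changes.  The upper layer chooses among the shape rule,
    the orientation rule and no rule (state abstraction + rule-consistent
    pseudoreward); its reward carries a small positive bias whenever a rule —
    right or wrong — was chosen.
    """
    net = Network(dt=dt, seed=seed, mode=mode)
    env = StimuliEnv(mapping=mapping, seed=seed)
    env_node = net.node("env", env, size_in=3, size_out=8 + 3)
    lower, upper = stimuli_layer_configs(q_neurons=q_neurons, sigma=sigma,
                                         gamma=gamma, kappa=kappa)

    def rule_reward_factory(net, upper, lower_idx):
        A = 3

        def fn(t, x):
            if not env.in_feedback or not env.trials:
                return 0.0
            tr = env.trials[-1]
            k = int(np.argmax(x))
            if x[k] < 0.4 or k == StimuliEnv.RULE_NONE:
                return env.REWARD if tr.correct else -env.REWARD
            tgt = env.rule_button(k, tr.stimulus)
            return env.REWARD if tr.action == tgt else -env.REWARD

        node = net.node(f"L{lower_idx}.rule_reward", fn, size_in=A, size_out=1)
        hier._connect_held(net, upper, node, rows=slice(0, A), size_in=A)
        return node

    def upper_bias_factory(net, env_node, env_reward_T):
        def fn(t, x):
            if not env.in_feedback or not env.trials:
                return 0.0
            base = env.REWARD if env.trials[-1].correct else -env.REWARD
            k = int(np.argmax(x))
            if x[k] >= 0.4 and k != StimuliEnv.RULE_NONE:
                base += rule_bias
            return base

        node = net.node("L1.biased_reward", fn, size_in=3, size_out=1)
        node._needs_self_held = slice(0, 3)
        return node

    specs = [LayerSpec(lower),
             LayerSpec(upper, reward_transform=upper_bias_factory)]
    inter = [[InteractionSpec("state", mask=env.state_mask),
              InteractionSpec("reward", reward_fn=rule_reward_factory)]]
    agent = compose(net, env_node, 8, specs, inter,
                    encoder_samples=stimuli_encoder_samples(env))
    act_probe = net.probe(("rates", agent.layers[1].out_pop),
                          every=probe_every)
    sim = Simulator(net)
    trial_len = env.PRESENT + env.FEEDBACK
    sim.run(n_trials * trial_len + trial_len)
    trials = env.trials[:n_trials]
    acc = accuracy_blocks(trials)
    t_ends = [t.t_end for t in trials]
    act = activity_blocks(sim.time(act_probe), sim.data(act_probe), t_ends)
    return {"kind": "stimuli", "mapping": mapping, "seed": seed, "dt": dt,
            "mode": mode, "trials": trials, "accuracy_blocks": acc,
            "activity_blocks": act,
            "activity_raw": (sim.time(act_probe), sim.data(act_probe)),
            "config": {"q_neurons": q_neurons, "sigma": sigma,
                       "gamma": gamma, "kappa": kappa,
                       "rule_bias": rule_bias, "n_trials": n_trials}}


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_summary(record: dict) -> dict:
    """JSON-safe summary of a run record (drops bulky raw arrays)."""
    out = {}
    for k, v in record.items():
        if k in ("trials", "decisions", "agent", "Q", "activity_raw",
                 "decoders", "sim", "layer"):
            continue
        out[k] = _jsonable(v)
    if "trials" in record and record["trials"]:
        t0 = record["trials"][0]
        if hasattr(t0, "latency"):
            out["n_trials"] = len(record["trials"])
            out["final_block_latency"] = float(
                np.mean([t.latency for t in record["trials"][-20:]]))
        elif hasattr(t0, "correct"):
            out["n_trials"] = len(record["trials"])
            out["peak_block_accuracy"] = float(
                np.max(block_means([t.correct for t in record["trials"]], 60)))
    return out


def save_record(record: dict, outdir) -> Path:
    """Write the JSON summary and CSV series of a run to ``outdir``."""
    import pandas as pd
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "summary.json").write_text(
        json.dumps(run_summary(record), indent=2))
    if "latencies" in record:
        pd.DataFrame({"trial": np.arange(len(record["latencies"])),
                      "latency": record["latencies"]}
                     ).to_csv(outdir / "latency.csv", index=False)
    if "cum_reward" in record:
        pd.DataFrame({"time_s": record["times"],
                      "cum_reward": record["cum_reward"]}
                     ).to_csv(outdir / "cum_reward.csv", index=False)
    if "accuracy_blocks" in record:
        pd.DataFrame({"block": np.arange(len(record["accuracy_blocks"])),
                      "accuracy": record["accuracy_blocks"]}
                     ).to_csv(outdir / "accuracy.csv", index=False)
    if "decisions" in record:
        layers = record["decisions"]
        if layers and not isinstance(layers[0], list):
            layers = [layers]
        with open(outdir / "decisions.jsonl", "w") as fh:
            for li, decs in enumerate(layers):
                for (t, action, delta) in decs:
                    fh.write(json.dumps({"layer": li, "time_s": round(t, 4),
                                         "action": int(action),
                                         "delta": round(float(delta), 5)})
                             + "\n")
    return outdir
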