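# Methods

`neurohrl` simulates a semi-Markov (SMDP) reinforcement-learning agent built
entirely from populations of leaky integrate-and-fire (LIF) neurons, and
composes such agents into hierarchies. This note describes the model, its
parameters, the numerical choices behind the simulator, what the synthetic
tasks do and do not capture, and the known limitations.

## The model

### Representation and learning substrate

Vectors are represented by heterogeneous LIF populations in the standard
population-coding scheme: neuron *i* fires at
`G[alpha_i (e_i . x) + J_bias_i]`, where `G` is the LIF response (closed-form
rate, or spikes; the two modes are interchangeable and differ only in the
neuron-update step), `e_i` is the neuron's preferred-direction encoder, and
gain/bias are sampled so maximum rates fall in 50–200 Hz at the population
radius. Fixed transformations are realised by regularised least-squares
decoders; connection weights are always kept in factorised encoder/decoder
form. Unknown transformations — the Q functions — are learned online with the
prescribed-error-sensitivity (PES) rule: the decoder update for neuron *i* is
`kappa/n * a_i * E` per unit time, local in presynaptic activity `a_i` and
the modulatory error vector `E`.

Two representational conventions matter throughout:

* **Clean zeros.** Populations whose output gates or modulates others (error
  populations, gating populations, the action-output population for
  non-negative action vectors) have firing intercepts aligned away from
  zero, so that a zero value is represented by silence — an exact zero.
  Without this, per-channel decoding bias acts as a small constant error
  that is integrated by learning and manifests as action lock-in.
* **Task-matched encoders.** Q-population encoders are sampled from the
  distribution of states the population will see. For sparse categorical
  codes (concatenated one-hots) the intercepts are additionally positive,
  giving a sparse, decorrelated code; with generic random encoders the
  activity patterns of distinct one-hot states correlate at ~0.8 through
  bias-driven firing, and PES interference then swamps state
  differentiation. A mixed intercept range (partly negative, giving broadly
  tuned neurons) was evaluated for the rule-selecting upper layer — it
  speeds rule-value generalisation across stimuli but also keeps the flat
  condition's rule exploration active longer, washing out the flat/
  hierarchical activity difference, and does not change the five-seed mean
  peak accuracy; the sparse code is therefore the default.

### One SMDP layer

A layer contains three components wired in a loop:

* **Action values** — the dual training system. Two populations encode the
  same Q function: the *previous-state* population reads a gated
  line-attractor memory that stores the state at the last selection event,
  the *current-state* population reads the live state. The TD error trains
  only the previous-state decoders (whose activity still encodes the state
  where the action was chosen), while a consistency error
  `E = Q(s) − Q(s')`, gated open only when `||s − s'|| < theta`, trains the
  current-state decoders toward the previous-state output. This replaces
  eligibility traces: no fixed decay window limits the action duration.
  The distance gate is a small population thresholding the decoded distance
  through its intercepts; consistency learning pauses during the TD pulse so
  the two pathways cannot conflict.

* **Action selection** — a basal-ganglia/thalamus circuit (striatum D1/D2,
  STN, GPe, GPi with the published gain constants of the standard selection
  model) computing an approximate argmax over the Q vector, plus additive
  low-pass-filtered Gaussian exploration noise on the Q values. The thalamus
  adds mutual inhibition and a sharpening decode (winner-take-all cleanup)
  so that slim margins still latch as a crisp one-hot. A gated memory
  latches the winner across the delay; a linear readout maps the one-hot to
  the environment's action vector. The circuit has a finite resolution:
  margins below roughly 0.05–0.1 (in units of the circuit input) are not
  reliably resolved — a modelled feature that limits how flat a value
  gradient can be and still drive behaviour.

* **Error calculation** — the integrative-discount TD error
  `delta = R_acc + Q(s',a') − Q(s,a) − D_acc`, with `R_acc` a neural
  integrator of the reward since the last selection and `D_acc` an
  integrator of `gamma * Q(s,a)`. Subtracting the accumulated discount
  preserves the two essential properties of discounting (scaling with delay
  length and with Q magnitude) without multiplying neural signals of very
  different scales. Selected-action values are read out through relay
  populations inhibited on all non-selected channels. The error output is
  inhibited except during a termination-triggered pulse; on terminal
  transitions the next-state value is suppressed (episodic convention). The
  classical multiplicative form (`sum gamma^t r_t + gamma^tau Q(s',a') −
  Q(s,a)`) is provided in closed form as a reference; the two agree to first
  order for short delays and small values.

A cycle timer sequences each termination event: the TD window opens 130 ms
after the event (after the selection circuit has settled on the new state's
winner) for 50 ms, while the state memory still holds the pre-transition
state; then latch, state memory and accumulator resets run in a 100 ms load
window. Learning-rate × TD-window width is the effective TD step size. The
first event after start-up or an episode reset latches a selection without
applying a TD update, since the stored state/selection pair does not
describe a real transition then.

### Hierarchy

Layers interact only through their ordinary ports. Context interactions
append the upper layer's action vector to the lower layer's state; state
interactions inhibit (mask) irrelevant state dimensions; reward interactions
replace the lower layer's reward with a pseudoreward paying `r+` within a
threshold of the commanded target state and `r−` elsewhere. Abstract actions
terminate when the commanded subgoal is reached or a configured timeout
elapses; environment episode resets are forwarded to upper layers as
terminal terminations. A single-layer composition is exactly the flat agent.

### Perfect-precision (direct) mode

For the precision comparison, a layer can swap its selection and
error-calculation circuits for exact arithmetic (sampled Gaussian noise +
true argmax; exact reward/discount integrals and TD error; perfect state
memory) while the Q populations and PES learning stay neural. This isolates
the cost of neural imprecision in selection and error computation.

## Parameters

| Parameter | Default | Notes |
| --- | --- | --- |
| timestep `dt` | 1 ms | 2 ms in desk-scale presets (behaviour verified equivalent at both) |
| synapses | 5 ms feedforward, 100 ms recurrent, 2/8 ms AMPA/GABA in the selection circuit | first-order low-pass |
| max rates / intercepts | U(50, 200) Hz, U(−1, 1) | positive intercepts for sparse state codes and gating populations |
| `gamma` (continuous discount) | 0.3 /s | one grid step (~0.75 s) discounts ~0.22 of a unit Q |
| `theta` (consistency gate) | exact-match scale for discrete tasks (less than half the minimum state separation); 10% of state-space diameter for continuous tasks | Euclidean distance over the full (context-extended) state |
| PES rate `kappa` | task presets: grid/delivery 1.5e-3, stimuli 8e-3 | chosen so the effective TD step (`kappa * mean-square activity / n * 50 ms`) is ~0.1–0.3, comparable to the tabular baseline's alpha = 0.2; the stimuli preset is larger because its sparse state code has ~7x lower population activity |
| exploration noise `sigma` | 0.05–0.1 (task presets), 250 ms correlation time | the correlation time keeps the perturbed preference stable across one selection cycle |
| TD pulse / load window | 50 ms at +130 ms / 100 ms at +190 ms | |
| neuron counts | Q populations 300–500, BG 100/channel, integrators 150, relays 100, memories/gates 40–60 | relays and integrators are sized to keep decoding bias well below task value gradients, since relay bias enters the TD error as a spurious per-action reward |
| abstract-action timeout | 30 s (delivery default); scaled with run length in desk presets | |

## Tasks

* **Grid navigation**: 5×5 grid, fixed goal, random start, 600–900 ms
  transition delays, reward 1 in the goal state. The goal state persists for
  one further cycle (with reward on) before the episode terminates and
  restarts, so the final action's credit is carried by an ordinary SMDP
  cycle. Latency = steps − Manhattan distance, excluding the goal dwell.
  A uniform random walk on this grid needs ~89 steps per trial in
  expectation, which sets the scale of the early learning curve.
* **Delivery**: continuous unit arena, cardinal steps of 0.25, pickup at
  (0.25, 0.75) and dropoff at (0.75, 0.25) with radius 0.15 — geometry
  calibrated so an optimal pickup-to-dropoff leg takes 4 decisions ≈ 3 s.
  State = 36 Gaussian place cells (width 0.15, seeded uniform centres) plus
  a two-dimensional package flag. The hierarchical agent adds an upper layer
  with two abstract actions (go-to-pickup / go-to-dropoff) interacting via
  context concatenation and pseudoreward (+1.5 in the commanded region,
  −0.05 elsewhere); subgoal thresholds are expressed in place-vector
  distance corresponding to the region radius. Transfer pretrains the flat
  context-extended layer on randomised-context navigation (the same subgoal
  structure with environment-chosen contexts) and injects its decoders into
  a fresh hierarchical agent.
* **Stimulus–response**: 18 stimuli (2 colours × 3 shapes × 3 orientations)
  as concatenated one-hots, 500 ms presentations, ±1.5 feedback for 100 ms.
  Flat condition: an arbitrary seeded button per stimulus. Hierarchical
  condition: one colour's correct button follows the shape index, the
  other's the orientation index. The two-layer model (identical in both
  conditions) selects among shape-rule / orientation-rule / no-rule actions;
  rules mask irrelevant state dimensions and pay the lower layer for
  rule-consistent responses, while the upper layer's own reward carries a
  +0.15 bias whenever a rule — right or wrong — was chosen (a preference for
  rule-based explanations). With no rule the lower layer receives the raw
  environmental reward.

## What the synthetic tasks do and do not show

The environments are the study conditions themselves, not approximations of
richer data, but the desk-scale presets shrink durations, seed counts and
neuron counts relative to cluster-scale runs. Consequences to keep in mind:

* Learning-curve shapes, condition orderings (hierarchical > flat,
  perfect-precision ≥ neural, transfer > naive) and activity patterns are
  preserved at desk scale; absolute terminal performance percentages on the
  delivery task are not expected to match multi-hour runs.
* The upper layer's activity in the stimulus task starts near its
  exploration baseline and rises as the rule bias takes hold, rather than
  starting at its maximum; the flat/hierarchical *difference* by the end
  block — lower output activity when no rule is worth representing — is the
  pattern the model reproduces.
* Decoding noise scales like 1/sqrt(neurons); at desk-scale counts the
  selection resolution floor is correspondingly higher than at large scale.

## Numerical choices

* The simulator advances all signals with a uniform one-step delay: routing
  matrices read the previous step's signal buffer, nodes and neurons then
  update. Event pulses are therefore several timesteps wide.
* Spiking LIF neurons use exact membrane decay over the non-refractory part
  of the step and sub-step spike-time interpolation, so long-run spike rates
  match the closed-form rate equation without timestep quantisation bias
  (naive resets leak integrators badly: a 1 ms step otherwise caps a 197 Hz
  neuron at ~164 Hz).
* Integrator and memory populations use weak decoder regularisation (0.02)
  and larger neuron counts, because recurrent decode bias converts directly
  into drift (error/tau per second).
* Accumulator resets are implemented as a gated difference population
  driving the integrator toward zero during the load window (about 8 /s
  feedback), not as raw inhibition, which would not clear the recurrent
  filter state.
* Inhibitory connections add a fixed negative current (20 per unit gate) to
  every neuron of the target; gates are clipped non-negative before
  application.
* Relay masks release a channel when its one-hot entry exceeds ~0.4
  (release gain 2.5): latched winners sit between 0.5 and 1.0, conservative
  in spiking mode, while losers stay near zero.
* Ties in selection are broken by the noise process; there is no
  deterministic tie rule.

## Design choices where the design was open

* The environment emits reward during the delay that follows the rewarded
  event (a one-cycle dwell in the grid/delivery goal states), so terminal
  credit flows through an ordinary SMDP cycle instead of a special-cased
  terminal reward.
* The upper delivery layer receives the environmental reward only; the
  pseudoreward channel belongs to the lower layer.
* Consistency learning is gated off during the TD pulse (simultaneous
  updates on the two pathways could conflict).
* Exploration noise is constant within a run; a schedule hook exists but is
  unused.
* Hierarchy geometry (place-cell centres, pickup/dropoff locations) is held
  fixed across seeds; seeds vary neuron parameters, noise and environment
  event sampling.

## Known limitations

* The basal-ganglia model's resolution floor, decode noise in ~40–100-neuron
  populations, and the ±0.01 relay bias bound all scale with neuron counts;
  behaviour at much larger counts was not characterised.
* The integrative discount saturates with very long abstract actions (the
  discount integrator radius caps `gamma * Q * tau`), under-discounting
  delays beyond ~7 s at default settings.
* Encoders are fixed at construction; only decoders learn.
* The stimulus task's upper layer partially generalises across stimuli of
  the same colour; full per-colour rule separation is not always reached
  within 360 trials, which is consistent with the accuracy plateau near 70%
  rather than human-level performance.
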