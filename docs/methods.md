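# Methods

## Model

The network holds N_E excitatory LIF point neurons (membrane time constant
τ_m,E = 10 ms, capacitance C_m = 250 pF, reset V_r = 0 mV, refractory
τ_ref,E = 20 ms) split into M disjoint subpopulations of n_E = N_E/M neurons,
one subpopulation per stimulus symbol, plus a single inhibitory LIF neuron
(τ_m,I = 5 ms, τ_ref,I = 2 ms, threshold θ_I = 15 mV). Each excitatory neuron
receives exactly K_EE excitatory inputs drawn uniformly without replacement
from the other excitatory neurons (no autapses or multapses); excitatory and
inhibitory populations are connected all-to-all in both directions with fixed
weights J_IE = 532.76 pA and J_EI = −12915.49 pA; there are no I→I
connections.

The total somatic current of an excitatory neuron is
I = I_ED + I_EI + I_S + I_B:

* **I_ED (dendrite)**: each delayed (d_EE = 2 ms) presynaptic spike adds an
  alpha kernel with amplitude J_ij and time constant τ_EE = 30 ms (the
  kernel peaks at exactly J_ij one time constant after delivery). When I_ED
  reaches θ_dAP = 59 pA, and no plateau is active and the neuron is not
  refractory, a dendritic action potential starts: I_ED is clamped to
  I_dAP = 200 pA for τ_dAP = 60 ms and then reset to 0. Synaptic input
  arriving during a plateau or during somatic refractoriness is discarded
  (the dendrite restarts from zero afterwards). A somatic spike clears the
  dendrite for the refractory period. The plateau's somatic drive is
  R_m·I_dAP = 8 mV, which exceeds the replay threshold (7 mV) but not the
  training threshold (20 mV) — this single inequality is what turns replay
  on and off.
* **I_EI (inhibition)**: exponential PSC, τ_EI = 1 ms. Because the single
  inhibitory neuron projects identically to every excitatory neuron, I_EI is
  one shared scalar. Whenever I_EI < I_θ = −1000 pA ("strong inhibition"),
  ongoing plateaus are terminated and new ones vetoed; see *Design
  decisions*.
* **I_S (stimulus)**: exponential PSC, τ_EX = 2 ms, weight J_EX = 4112.2 pA;
  a single stimulus spike per sequence element drives all neurons of the
  matching subpopulation (peak EPSP 22 mV, i.e. suprathreshold in both
  modes).
* **I_B (background)**: replay-phase noise, either pooled Poisson input or a
  subpopulation-coherent sinusoid (below).

The inhibitory neuron integrates excitatory spikes through an exponential
PSC (τ_IE = 0.5 ms). With the default weights, about ρ = 20 coincident
excitatory spikes are needed to drive it across threshold; its feedback IPSP
(trough −40 mV on every excitatory neuron) silences the network for tens of
milliseconds, implementing the winner-take-all competition.

## Numerical scheme

States advance synchronously on a fixed grid (Δt = 0.1 ms; all delays are
validated as grid multiples). Every linear subsystem — membrane potentials,
exponential PSCs, and the two-state canonical form of the alpha kernel — is
propagated with matrix exponentials computed once at setup, so subthreshold
trajectories are exact for impulsive/piecewise-constant inputs regardless of
step size (verified against brute-force Euler at Δt/1000 to 1e-5 relative
error). The update order within a step is: (1) deliver delayed spikes and
noise increments to synaptic state, (2) exact propagation, refractory clamp,
trace decay, (3) dendritic nonlinearity (plateau expiry, strong-inhibition
reset, new onsets; threshold tests use ≥), (4) somatic thresholds for all
neurons simultaneously (ties fire together), resets, spike enqueueing,
(5) scheduled plasticity updates. Sinusoidal background currents are treated
as constant within a step. A non-finite membrane potential aborts the run
with the neuron id and time.

One master seed feeds named substreams (connectivity, initial weights,
background-source assignment, Poisson drawing, oscillation phases, inter-cue
intervals) through `numpy` SeedSequence spawning, so each component is
individually reproducible.

## Plasticity

Only EE synapses are plastic, and only in training mode. Per edge j→i:

* every presynaptic spike depresses by J_max·λ₋·y_i (defaults:
  35 pA · 1.4e-5 · 1);
* every *eligible* postsynaptic somatic spike at tᵢ*, applied one dendritic
  delay later (tᵢ* + d_EE), potentiates by J_max·λ₊·x_j(tᵢ* + d_EE) and adds
  the homeostatic term J_max·λ_h·(z* − z_i(tᵢ*)), where x_j jumps by 1 at
  each presynaptic spike and decays with τ₊ = 20 ms, and z_i jumps by 1 at
  each dAP onset and decays with τ_h.

Eligibility uses the lag τ = tᵢ* − t_j⁺ + d_EE against the nearest
presynaptic spike t_j⁺ known by the application step: the update fires iff
Δt_min < τ < Δt_max (4–50 ms). This one test implements both the pairing
window and the "no presynaptic spike closer than Δt_min" filter, because a
later presynaptic spike only shrinks τ. In particular synchronously firing
neurons (τ = d_EE = 2 ms) never potentiate each other, which prevents
runaway self-prediction within a subpopulation. The filter is evaluated
causally over spikes known at the application time; a literal quantifier
over all future presynaptic spikes would be non-causal. Weights are clipped
to [J_min, J_max] = [0, 35] pA after every increment. Traces decay eagerly
every grid step (exact exponential factors), and trace jumps are
right-continuous: an event at t is included in the trace value at t.

The homeostatic set point deserves a note: z* /τ_h (10.35/2200 ms for two
sequences, 21/4620 ms for five) equals ≈ 4.6 dAPs/s — exactly the sequence
presentation rate of the training protocol (10 sequences per 2.2 s episode).
Homeostasis therefore pushes weights up until a neuron's dendrite predicts
at *every* presentation of its context, while the WTA feedback limits how
many such neurons fire somatically; their balance yields sparse assemblies
near ρ.

## Background noise

**Pooled Poisson input.** Each subpopulation owns private pools of n
excitatory and n inhibitory Poisson sources at rate ν = 1000/s; each neuron
draws K = 100 sources from each pool without replacement, with weights
±J_EQ and exponential filtering (τ_B = 2 ms). The weight is derived from
the requested current standard deviation via σ² = J²·K·ν·τ_B. Shared
draws give a within-subpopulation current correlation c = K/n (exact fast
paths implement c = 1, all sources shared, and c = 0, private sources);
neurons of different subpopulations are uncorrelated. Because arrivals are
locked to the grid and sampled after jump-then-decay, the sampled variance
would fall short of σ² by ≈ Δt/τ_B (5%); the applied jump amplitude carries
a half-step factor exp(Δt/(2τ_B)) that centres arrivals mid-step and makes
the sampled variance σ²·x/sinh(x) with x = Δt/τ_B — exact to 0.04%. The
noise is calibrated to be subthreshold (σ = 12–26 pA ↔ membrane
fluctuations well below 1 mV against a 7 mV threshold): it perturbs spike
*timing*, not spike counts.

**Oscillatory input.** I_B,i(t) = J_EG·a·sin(2πft + φ_k) with one phase φ_k
~ U[0, 2π) per subpopulation, shared by all its neurons. Used with
uniformly-random inter-cue intervals (U(200, 400) ms) so that each cue
samples a random oscillation phase.

Background noise exists only in replay mode; configuring it on a
training-mode simulation raises an error.

## Protocols and statistics

Training presents N_e episodes of L = 10 sequences, elements 40 ms apart,
sequences 100 ms apart, continuously (no state resets). Episode composition
follows the training frequencies through cumulative largest-remainder
quotas, so every episode holds exactly L presentations and long-run totals
are exactly proportional to the frequencies even when p_i·L is fractional;
a shuffled-order policy permutes each episode with a seeded generator.
Replay lowers θ_E to 7 mV, freezes weights, and presents the cue N_t times;
a trial spans [cue_j, cue_{j+1}) (last trial: 200 ms). A sequence counts as
replayed when more than 0.5ρ distinct neurons of its *last-element*
subpopulation fire in the trial (strict inequality: exactly 10 of 20 does
not count). Trials are tallied exclusively over the power set of the
sequence set, so the relative frequencies sum to one by construction.

Response latencies follow the population-averaged first-spike definition
over the neurons active in a trial (silent subpopulation → missing value).
The across-trial variance of the population latency decomposes as
v = v_s/ρ + ((ρ−1)/ρ)·c_s·v_s with v_s the mean single-neuron variance and
c_s the mean pairwise correlation; the implementation estimates all three
from the trials-by-neurons first-spike matrix (rows with silent neurons
dropped; the identity then holds exactly for the sample estimators).
Latencies are measured with the I→E weights set to zero so that both
competing branches express spikes. The *compound weight* w_XY between
subpopulations is the mean over target neurons (with ≥1 such edge) of their
summed incoming weights from the source subpopulation — the effective PSC
amplitude a cell receives when the source assembly fires synchronously;
assembly sizes are counted as distinct spiking neurons of a subpopulation
per trial, following the last-element convention.

## Design decisions

* **Strong-inhibition dendritic reset.** The reset of I_ED under strong
  inhibition is evaluated continuously (every grid step), but it terminates
  *plateaus* only and vetoes new onsets; subthreshold alpha-kernel
  accumulation survives. With the default weights the |I_EI| > 1000 pA
  window lasts ~2.6 ms after every inhibitory spike and always overlaps the
  2 ms EE delivery of the winning volley to the next subpopulation, so
  erasing subthreshold state would cancel the winner's own forward drive;
  plateau-only termination is the reading under which the WTA feedback
  cancels the losing branch's predictions (its already-active plateaus)
  while replay remains possible at all. Evaluating the reset only at somatic
  spike times would make it redundant with the spike-triggered dendrite
  clear.
* **Replay tempo.** With the plateau clamped at exactly I_dAP, the
  inter-element interval during autonomous replay is ~43 ms: each volley
  triggers the inhibitory neuron, whose IPSP trough is −40 mV (this value
  follows exactly from J_EI), and recovery from that trough with τ_m = 10 ms
  against a plateau drive of 8 mV and threshold of 7 mV takes
  10·ln(48) ≈ 39 ms; the dendritic delay-plus-rise adds a few ms. Without
  inhibition (the latency-measurement protocol) the chain runs at
  ~27–30 ms per element. The interval is reported as computed; no parameter
  is adjusted to change it.
* **Plateau semantics.** The plateau replaces the synaptic dendritic
  current (clamp), it does not add to it; inputs during the plateau are
  discarded rather than accumulated silently, so the post-plateau reset to
  zero is exact. A new plateau cannot start while one is active or during
  somatic refractoriness.
* **Tie-breaking.** All threshold tests use ≥. All neurons crossing
  threshold in a step fire together. A presynaptic spike landing exactly on
  a potentiation's application step participates in the trace and vetoes
  that edge's update (its lag is below Δt_min either way).
* **Trial state.** Dynamic state is not reset between cues (continuous
  protocol); the 200 ms minimum inter-cue interval comfortably exceeds the
  ~130 ms a four-element replay occupies.

## Problem sizes and runtime

The packaged experiments use the two-sequence network (900 neurons) trained
for 20 episodes (44 s biological time) with 151 replay cues, and the
five-sequence network (1800 neurons, M = 12, K_EE = 360, τ_h = 4620 ms,
z* = 21) trained for 40 episodes with 120 cues — about 90 s total on one
CPU for the acceptance script. Strategy-classification checks (max-prob,
noise averaging) use 51 trials. These sizes keep full retraining cheap;
statistics quoted from them carry the corresponding binomial error bars.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself: the stimulus is an
idealized single spike per element, background noise is stationary pooled
Poisson input or a constant-frequency sinusoid, and sequences overlap in
exactly their first two elements. Passing tests therefore demonstrate the
internal consistency of the model — learning maps frequency to weights,
correlated noise converts that mapping into probability matching, and the
implementation reproduces the closed-form physics it claims — but nothing
about messy real inputs: graded or jittered stimuli, nonstationary waves,
conductance effects, or sequences with immediate repeats (the plasticity
window deliberately blocks same-subpopulation potentiation, so {A,B,B,C}
cannot be learned). The CUBA inhibition can hyperpolarize membranes
arbitrarily far (−40 mV troughs here), a known simplification of the
current-based synapse model; a conductance-based variant would bound it and
would plausibly shorten the replay tempo noted above. Multiple inhibitory
neurons, multiple dendritic branches, and plasticity during replay (beyond
freezing) are out of scope.
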