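# seqreplay

A spiking-network simulator for **sequence learning and probabilistic
cue-triggered replay**. The model is a recurrent network of leaky
integrate-and-fire (LIF) point neurons with a nonlinear dendrite: when the
dendritic input current of a neuron crosses a threshold θ_dAP, a **dendritic
action potential (dAP)** clamps the dendritic current to a plateau I_dAP for
τ_dAP = 60 ms, depolarizing the soma for tens of milliseconds (a "predictive"
state). The N_E excitatory neurons are divided into M subpopulations, one per
stimulus symbol, and compete through a single inhibitory neuron that
implements a fast **winner-take-all (WTA)** circuit. Excitatory-to-excitatory
synapses learn with a **homeostatic spike-timing-dependent plasticity** rule

    dJ_ij/J_max = λ₊ x_j(t) · δ(t − [tᵢ* + d_EE]) · 𝕀(Δt_min < τ < Δt_max)
                − λ₋ y_i · δ(t − t_j*)
                + λ_h (z* − z_i) · δ(t − tᵢ*) · 𝕀(...)     ,  J_min ≤ J ≤ J_max

where x_j is the presynaptic spike trace (decay τ₊), z_i the postsynaptic dAP
trace (decay τ_h), and z* the target dAP activity that steers each neuron's
participation, yielding sparse assemblies of about ρ = 20 neurons per symbol.

Who is this for: computational neuroscientists studying sequence memory,
population coding and noise correlations, and anyone reproducing or extending
the replay-strategy results below.

## What the model does

Training presents ordered symbol sequences (e.g. {A,F,B,D} at relative
frequency p and {A,F,C,E} at 1 − p) as single stimulus spikes per element,
40 ms apart. Learning maps training frequency onto synaptic weights between
consecutive subpopulations. In **replay mode** (somatic threshold lowered
from 20 mV to 7 mV so a dAP plateau alone can fire a neuron; plasticity
frozen) an ambiguous cue "A" triggers autonomous recall. The recall strategy
is controlled by background noise injected into the subpopulations:

* **no noise** — max-prob: only the most frequent sequence is recalled;
* **uncorrelated noise** (private Poisson sources, c = 0) — averages out in
  the population code; recall stays effectively deterministic;
* **locally correlated noise** (shared Poisson source pools, c = K/n → 1,
  or subpopulation-coherent oscillations) — response-latency distributions
  of competing branches overlap, and recall frequencies approach the
  training frequencies (**probability matching**).

## Worked example

```python
import seqreplay as sq

params = sq.ModelParams()                      # 900 neurons, 6 subpopulations
net = sq.build_network(params, seed=1)

alphabet, sequences = sq.TWO_SEQUENCE_TASK     # {A,F,B,D} and {A,F,C,E}
task = sq.SequenceTask(alphabet, sequences, probs=[0.2, 0.8], N_e=20, L=10)
sq.train(net, params, task, seed=2)            # ~44 s of biological time

replay_params = sq.set_replay_mode(params)     # theta_E 20 -> 7 mV, weights frozen
noise = sq.NoiseConfig(kind="poisson", sigma=20.0, c=1.0)
result = sq.replay(net, replay_params, task, cue_symbol="A", N_t=151,
                   noise=noise, seed=3)

stats = result.stats()
for name, cell in [("fail", frozenset()), ("s1", frozenset([0])),
                   ("s2", frozenset([1])), ("both", frozenset([0, 1]))]:
    print(f"f_{name} = {stats.frequencies()[cell]:.3f}")
print(f"mean inter-element interval: {stats.inter_element_intervals().mean():.1f} ms")
print(f"assembly size (last element): {stats.mean_active_count(1):.1f} neurons")
w_bf = sq.compound_weight(net, 1, 2)           # F -> B
w_cf = sq.compound_weight(net, 1, 4)           # F -> C
print(f"compound weights: w_BF = {w_bf:.1f} pA, w_CF = {w_cf:.1f} pA")
```

Output (about two minutes on one CPU):

```
f_fail = 0.000
f_s1 = 0.245
f_s2 = 0.722
f_both = 0.033
mean inter-element interval: 43.3 ms
assembly size (last element): 24.8 neurons
compound weights: w_BF = 57.8 pA, w_CF = 63.2 pA
```

Reading this: the sequence trained at p = 0.2 is recalled in 24.5% of the
151 cue trials and the p = 0.8 sequence in 72.2% — probability matching.
The learned compound weight toward the more frequent branch (w_CF) exceeds
w_BF; recall recruits sparse assemblies near the target size ρ = 20; and the
autonomous replay steps through elements every ~43 ms (each WTA volley is
followed by a strong global hyperpolarization whose recovery, together with
the 8 mV plateau drive against the 7 mV threshold, sets this tempo — see
`docs/methods.md`).

A command-line interface wraps the same protocols:

```bash
seqreplay train  --config configs/two_sequence.yaml --seed 1 --out out/
seqreplay replay --config configs/two_sequence.yaml --seed 1 \
    --network out/network_trained.tsv --trials 151 --out out/
seqreplay latency --config configs/two_sequence.yaml --seed 1 \
    --network out/network_trained.tsv --out out/
```

## Layout

| module | contents |
| --- | --- |
| `params` | all model constants (ms/mV/pA/pF), mode switching, validation |
| `network` | fixed in-degree random EE connectivity, edge storage |
| `simulator` | exact-integration stepping engine, dAP nonlinearity, WTA |
| `plasticity` | homeostatic STDP traces, eligibility window, clipping |
| `inputs` | stimulus encoding, correlated Poisson pools, oscillations, cues |
| `protocols` | train / set_replay_mode / replay / measure_latencies |
| `analysis` | replay detection, power-set frequencies, latencies, Eq-style variance decomposition, compound weights |
| `config`, `io`, `fixtures`, `cli` | YAML configs, text serialization, test fixtures, CLI |
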