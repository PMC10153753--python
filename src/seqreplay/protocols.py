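"""Experiment orchestration: training, mode switching, cue-triggered replay.

Training runs the full stimulus schedule (``N_e`` episodes of ``L``
sequence presentations) through the simulator with plasticity enabled, the
high somatic threshold, and no background noise; the dynamic state is never
reset between episodes. Replay lowers the threshold so a dendritic plateau
alone drives firing, freezes the weights, optionally injects background
noise, and presents the cue symbol repeatedly; trials are the windows
between consecutive cues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .analysis import ReplayStats, first_spike_matrix, segment_trials
from .inputs import NoiseConfig, SequenceTask, StimulusSchedule, cue_schedule, encode_task
from .network import Network
from .params import ModelParams
from .record import SpikeRecord
from .simulator import Simulator

__all__ = ["train", "set_replay_mode", "replay", "measure_latencies",
           "TrainResult", "ReplayResult"]


@dataclass
class TrainResult:
    net: Network
    record: SpikeRecord
    task: SequenceTask
    weight_snapshots: list[np.ndarray] = field(default_factory=list)
    snapshot_episodes: list[int] = field(default_factory=list)


@dataclass
class ReplayResult:
    record: SpikeRecord
    cue_times: np.ndarray
    task: SequenceTask
    params: ModelParams

    def trials(self) -> list[SpikeRecord]:
        return segment_trials(self.record, self.cue_times)

    def stats(self, rho: int | None = None) -> ReplayStats:
        rho = self.params.rho if rho is None else rho
        return ReplayStats.from_record(self.record, self.task, rho, self.cue_times)


def train(
    net: Network,
    params: ModelParams,
    task: SequenceTask,
    seed: int = 0,
    snapshot_every: int | None = None,
) -> TrainResult:
    """Run the learning protocol; mutates and returns the network weights.

    ``snapshot_every`` stores a weight copy after every so-many episodes
    (for learning-curve analyses). The stimulus order within an episode
    follows the task's order policy.
    """
    if params.mode != "training":
        raise ValueError("training requires params.mode == 'training'")
    if not params.plasticity.enabled:
        raise ValueError("training requires enabled plasticity")
    ss = np.random.SeedSequence(seed)
    s_order, s_sim = ss.spawn(2)
    schedule = encode_task(task, seed=s_order)
    sim = Simulator(net, params, seed=_as_int(s_sim), stimulus=schedule)
    snapshots: list[np.ndarray] = []
    episodes_done: list[int] = []
    if task.N_e > 0:
        episode_ms = schedule.duration_ms / task.N_e
        for e in range(task.N_e):
            sim.run(episode_ms)
            if snapshot_every and ((e + 1) % snapshot_every == 0 or e + 1 == task.N_e):
                snapshots.append(net.edge_weight.copy())
                episodes_done.append(e + 1)
    return TrainResult(net, sim.spike_record(), task, snapshots, episodes_done)


def set_replay_mode(params: ModelParams) -> ModelParams:
    """Replay configuration: theta_E lowered, plasticity frozen."""
    return params.replay_mode()


def replay(
    net: Network,
    params: ModelParams,
    task: SequenceTask,
    cue_symbol: str,
    N_t: int,
    noise: NoiseConfig | None = None,
    seed: int = 0,
    cue_policy: str = "fixed",
    lead_in_ms: float = 100.0,
) -> ReplayResult:
    """Present the cue ``N_t`` times in replay mode and record everything."""
    if params.mode != "replay":
        raise ValueError("call set_replay_mode(params) first")
    cue_pop = task.subpop_of_symbol(cue_symbol)
    ss = np.random.SeedSequence(seed)
    s_cues, s_sim = ss.spawn(2)
    cues = cue_schedule(N_t, policy=cue_policy, seed=s_cues, t0=lead_in_ms)
    schedule = StimulusSchedule(
        cues, np.full(N_t, cue_pop, dtype=np.int32), cues[-1] + 200.0
    )
    sim = Simulator(net, params, seed=_as_int(s_sim), stimulus=schedule, noise=noise)
    sim.run(schedule.duration_ms)
    return ReplayResult(sim.spike_record(), cues, task, params)


def measure_latencies(
    net: Network,
    params: ModelParams,
    task: SequenceTask,
    cue_symbol: str,
    N_t: int,
    subpops: list[int],
    noise: NoiseConfig | None = None,
    seed: int = 0,
    n_neurons: int | None = None,
):
    """Per-trial, per-neuron first-spike latencies with inhibition silenced.

    All I->E synapses are set to zero weight so that every competing
    subpopulation expresses its spikes; this is the protocol for measuring
    the response-latency distributions and their variance decomposition.
    Returns ``{subpop: (neuron_ids, latency matrix trials x neurons)}``,
    with the neuron set restricted to those that fired in every trial (the
    learned sparse assembly), optionally capped at ``n_neurons``.
    """
    silent = dataclasses.replace(params, J_EI=0.0)
    result = replay(net, silent, task, cue_symbol, N_t, noise=noise, seed=seed)
    trials = result.trials()
    out = {}
    for k in subpops:
        counts: dict[int, int] = {}
        for tr in trials:
            ids = np.unique(tr.spike_ids[tr.spike_subpops() == k])
            for i in ids:
                counts[int(i)] = counts.get(int(i), 0) + 1
        always = np.array(sorted(i for i, c in counts.items() if c == len(trials)),
                          dtype=np.int64)
        if n_neurons is not None:
            always = always[:n_neurons]
        mat = first_spike_matrix(trials, result.cue_times, always)
        out[k] = (always, mat)
    return out


def _as_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, dtype=np.uint32)[0])
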