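"""Replay detection, power-set replay statistics, latencies, weights.

A sequence counts as replayed in a trial when more than ``0.5 * rho``
distinct neurons of the subpopulation representing its *last* element fire
within the trial window (strict inequality). Trials are classified
exclusively over the power set of the sequence set: a trial in which both
sequences complete contributes to the joint cell, not to the singletons, so
the relative frequencies always sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .inputs import SequenceTask
from .network import Network
from .record import SpikeRecord

__all__ = [
    "detect_replay", "replay_frequencies", "response_latency",
    "latency_variance_decomposition", "compound_weight",
    "active_neuron_count", "ReplayStats", "segment_trials",
]


def segment_trials(record: SpikeRecord, cue_times: np.ndarray,
                   tail_ms: float = 200.0) -> list[SpikeRecord]:
    """Split a replay record into per-trial windows ``[cue_j, cue_{j+1})``.

    The last trial extends ``tail_ms`` past its cue.
    """
    cues = np.asarray(cue_times, dtype=float)
    ends = np.append(cues[1:], cues[-1] + tail_ms)
    return [record.in_window(c, e) for c, e in zip(cues, ends)]


def active_neuron_count(trial: SpikeRecord, subpop: int) -> int:
    """Distinct neurons of ``subpop`` with at least one spike in the trial."""
    mask = trial.spike_subpops() == subpop
    return int(np.unique(trial.spike_ids[mask]).size)


def detect_replay(trial: SpikeRecord, task: SequenceTask, rho: int) -> frozenset[int]:
    """Indices of the sequences replayed in one trial (exclusive subset)."""
    hit = []
    for si, last in enumerate(task.last_subpops()):
        if active_neuron_count(trial, last) > 0.5 * rho:
            hit.append(si)
    return frozenset(hit)


def replay_frequencies(subsets: list[frozenset[int]], S: int) -> dict[frozenset[int], float]:
    """Relative frequency of every power-set cell over the trials.

    Cells are keyed by frozensets of sequence indices; all ``2**S`` cells
    are present (zero where never observed) and the values sum to one.
    """
    if not subsets:
        raise ValueError("need at least one trial")
    n = len(subsets)
    counts: dict[frozenset[int], int] = {}
    for r in range(S + 1):
        for cell in combinations(range(S), r):
            counts[frozenset(cell)] = 0
    for sub in subsets:
        counts[sub] = counts.get(sub, 0) + 1
    return {cell: c / n for cell, c in counts.items()}


def response_latency(trial: SpikeRecord, subpop: int, cue_time: float) -> float:
    """Population-averaged first-spike latency of ``subpop`` after the cue.

    The mean runs over the neurons that fired in the trial; returns NaN for
    a silent subpopulation (excluded from across-trial statistics).
    """
    pops = trial.spike_subpops()
    mask = pops == subpop
    if not mask.any():
        return np.nan
    ids = trial.spike_ids[mask]
    times = trial.spike_times[mask]
    order = np.lexsort((times, ids))
    ids, times = ids[order], times[order]
    first = np.concatenate([[True], ids[1:] != ids[:-1]])
    return float(np.mean(times[first]) - cue_time)


def _first_spike(trial: SpikeRecord, subpop: int, cue_time: float) -> float:
    """Earliest spike time of a subpopulation relative to the cue (NaN if silent)."""
    mask = trial.spike_subpops() == subpop
    if not mask.any():
        return np.nan
    return float(trial.spike_times[mask].min() - cue_time)


def first_spike_matrix(trials: list[SpikeRecord], cue_times: np.ndarray,
                       neuron_ids: np.ndarray) -> np.ndarray:
    """First-spike latency of each neuron (columns) in each trial (rows); NaN if silent."""
    out = np.full((len(trials), len(neuron_ids)), np.nan)
    pos = {int(n): j for j, n in enumerate(neuron_ids)}
    for i, (trial, cue) in enumerate(zip(trials, cue_times)):
        sel = np.isin(trial.spike_ids, neuron_ids)
        ids = trial.spike_ids[sel]
        times = trial.spike_times[sel] - cue
        order = np.lexsort((times, ids))
        ids, times = ids[order], times[order]
        first = np.concatenate([[True], ids[1:] != ids[:-1]]) if ids.size else np.empty(0, bool)
        for n, t in zip(ids[first], times[first]):
            out[i, pos[int(n)]] = t
    return out


def latency_variance_decomposition(first_spikes: np.ndarray):
    """Decompose the across-trial variance of the population latency.

    ``first_spikes`` is a (trials x neurons) matrix of single-neuron
    first-spike times; rows with any silent neuron are dropped so the
    population average is over a fixed ensemble. Returns ``(v, v_s, c_s)``:
    the across-trial variance ``v`` of the population-mean latency, the
    population-averaged single-neuron variance ``v_s``, and the
    population-averaged pairwise spike-time correlation ``c_s``. They are
    related by ``v = v_s / rho + (rho - 1) / rho * c_s * v_s``.
    """
    X = np.asarray(first_spikes, dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    n_trials, rho = X.shape
    if n_trials < 2 or rho < 2:
        raise ValueError("need at least two complete trials and two neurons")
    v = float(np.var(X.mean(axis=1), ddof=1))
    var_i = np.var(X, axis=0, ddof=1)
    v_s = float(var_i.mean())
    if v_s == 0.0:
        return v, v_s, np.nan
    C = np.cov(X.T)
    cov_sum = C.sum() - np.trace(C)
    c_s = float(cov_sum / (rho * (rho - 1) * v_s))
    return v, v_s, c_s


def compound_weight(net: Network, pre_subpop: int, post_subpop: int) -> float:
    """Mean summed incoming weight from one subpopulation to another (pA).

    For every neuron of the target subpopulation that receives at least one
    edge from the source subpopulation, sum those incoming weights; the
    compound weight is the mean of these sums (the effective PSC amplitude
    a target cell sees when the source population fires synchronously).
    """
    pre_mask = net.subpop_of[net.edge_pre] == pre_subpop
    post_mask = net.subpop_of[net.edge_post] == post_subpop
    sel = pre_mask & post_mask
    if not sel.any():
        return 0.0
    sums = np.bincount(net.edge_post[sel], weights=net.edge_weight[sel],
                       minlength=net.N_E)
    has = np.bincount(net.edge_post[sel], minlength=net.N_E) > 0
    return float(sums[has].mean())


@dataclass
class ReplayStats:
    """Per-trial replay outcomes and derived summary statistics."""

    task: SequenceTask
    rho: int
    cue_times: np.ndarray
    subsets: list[frozenset[int]]
    latencies: pd.DataFrame = field(repr=False)      # trial x subpop (ms), Eq-1 mean
    first_spikes: pd.DataFrame = field(repr=False)   # trial x subpop (ms), earliest
    active_counts: pd.DataFrame = field(repr=False)  # trial x subpop

    @classmethod
    def from_record(cls, record: SpikeRecord, task: SequenceTask, rho: int,
                    cue_times: np.ndarray, tail_ms: float = 200.0) -> "ReplayStats":
        trials = segment_trials(record, cue_times, tail_ms)
        subsets = [detect_replay(tr, task, rho) for tr in trials]
        M = len(task.alphabet)
        lat = np.array([[response_latency(tr, k, c) for k in range(M)]
                        for tr, c in zip(trials, cue_times)])
        fs = np.array([[_first_spike(tr, k, c) for k in range(M)]
                       for tr, c in zip(trials, cue_times)])
        act = np.array([[active_neuron_count(tr, k) for k in range(M)]
                        for tr in trials])
        cols = list(task.alphabet)
        return cls(task, rho, np.asarray(cue_times), subsets,
                   pd.DataFrame(lat, columns=cols),
                   pd.DataFrame(fs, columns=cols),
                   pd.DataFrame(act, columns=cols))

    @property
    def n_trials(self) -> int:
        return len(self.subsets)

    def frequencies(self) -> dict[frozenset[int], float]:
        return replay_frequencies(self.subsets, self.task.S)

    def frequency_of(self, seq_idx: int) -> float:
        """Exclusive replay frequency of a single sequence."""
        return self.frequencies()[frozenset([seq_idx])]

    @property
    def failure_rate(self) -> float:
        return self.frequencies()[frozenset()]

    def sequence_trials(self, seq_idx: int) -> list[int]:
        """Trials in which exactly this sequence was replayed."""
        want = frozenset([seq_idx])
        return [i for i, s in enumerate(self.subsets) if s == want]

    def mean_active_count(self, seq_idx: int, element: int = -1) -> float:
        """Mean distinct-spiking-neuron count in one element's subpopulation
        over the trials that replayed exactly this sequence."""
        rows = self.sequence_trials(seq_idx)
        if not rows:
            return np.nan
        sym = self.task.sequences[seq_idx][element]
        return float(self.active_counts.iloc[rows][sym].mean())

    def inter_element_intervals(self) -> np.ndarray:
        """Intervals between successive subpopulation activations (earliest
        spike per subpopulation) of the replayed sequence, pooled over
        single-sequence trials."""
        out = []
        for i, sub in enumerate(self.subsets):
            if len(sub) != 1:
                continue
            (si,) = sub
            fs = [self.first_spikes.iloc[i][s] for s in self.task.sequences[si]]
            difs = np.diff(fs)
            if np.all(np.isfinite(difs)):
                out.append(difs)
        return np.concatenate(out) if out else np.empty(0)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-trial summary table."""
        rows = []
        for i, sub in enumerate(self.subsets):
            rows.append({
                "trial": i,
                "cue_time_ms": self.cue_times[i],
                "replayed": "+".join(sorted(str(s) for s in sub)) or "none",
            })
        return pd.DataFrame(rows)
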