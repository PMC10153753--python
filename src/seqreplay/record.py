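"""Spike and dendritic-event records with plain-text round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SpikeRecord"]


@dataclass
class SpikeRecord:
    """Somatic spikes, dAP onsets and inhibitory spikes of one simulation.

    Times are in ms on the simulation grid; ``spike_ids``/``dap_ids`` are
    excitatory neuron indices. ``meta`` carries provenance (seed, parameter
    hash, mode) and travels with the text serialization.
    """

    spike_times: np.ndarray
    spike_ids: np.ndarray
    dap_times: np.ndarray
    dap_ids: np.ndarray
    inh_spike_times: np.ndarray
    subpop_of: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def spike_subpops(self) -> np.ndarray:
        if self.subpop_of is None:
            raise ValueError("record carries no subpopulation map")
        return self.subpop_of[self.spike_ids]

    def in_window(self, t0: float, t1: float) -> "SpikeRecord":
        """Restrict all events to ``t0 <= t < t1``."""
        sm = (self.spike_times >= t0) & (self.spike_times < t1)
        dm = (self.dap_times >= t0) & (self.dap_times < t1)
        im = (self.inh_spike_times >= t0) & (self.inh_spike_times < t1)
        return SpikeRecord(
            self.spike_times[sm], self.spike_ids[sm],
            self.dap_times[dm], self.dap_ids[dm],
            self.inh_spike_times[im], self.subpop_of, dict(self.meta),
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy event table: time_ms, neuron_id, subpopulation, event_type."""
        def pop(ids):
            if self.subpop_of is None:
                return np.full(len(ids), -1)
            return self.subpop_of[ids]

        frames = [
            pd.DataFrame({"time_ms": self.spike_times,
                          "neuron_id": self.spike_ids,
                          "subpopulation": pop(self.spike_ids),
                          "event_type": "spike"}),
            pd.DataFrame({"time_ms": self.dap_times,
                          "neuron_id": self.dap_ids,
                          "subpopulation": pop(self.dap_ids),
                          "event_type": "dap"}),
            pd.DataFrame({"time_ms": self.inh_spike_times,
                          "neuron_id": -1,
                          "subpopulation": -1,
                          "event_type": "inh_spike"}),
        ]
        df = pd.concat(frames, ignore_index=True)
        return df.sort_values(["time_ms", "event_type"], kind="stable").reset_index(drop=True)

    def save(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key}={val}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path, subpop_of: np.ndarray | None = None) -> "SpikeRecord":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    meta[key.strip()] = val
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, sep="\t")
        spikes = df[df.event_type == "spike"]
        daps = df[df.event_type == "dap"]
        inh = df[df.event_type == "inh_spike"]
        return cls(
            spikes.time_ms.to_numpy(float), spikes.neuron_id.to_numpy(int),
            daps.time_ms.to_numpy(float), daps.neuron_id.to_numpy(int),
            inh.time_ms.to_numpy(float), subpop_of, meta,
        )

    @staticmethod
    def from_event_lists(spikes, daps, inh_steps, dt, subpop_of=None, meta=None):
        """Assemble from per-step event lists of ``(step, ids)`` pairs."""
        def flatten(events):
            if not events:
                return np.empty(0), np.empty(0, dtype=np.int64)
            times = np.concatenate([np.full(len(ids), s * dt) for s, ids in events])
            ids = np.concatenate([np.asarray(ids) for _, ids in events])
            return times, ids.astype(np.int64)

        st, si = flatten(spikes)
        dtt, di = flatten(daps)
        it = np.asarray(inh_steps, dtype=float) * dt
        return SpikeRecord(st, si, dtt, di, it, subpop_of, meta or {})
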