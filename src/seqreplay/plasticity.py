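"""Event-driven homeostatic STDP on the excitatory-to-excitatory synapses.

The weight of edge ``j -> i`` changes through three event-driven terms, all
scaled by ``J_max`` and hard-clipped to ``[J_min, J_max]`` immediately after
each increment:

* at every presynaptic spike: depression ``-J_max * lambda_minus * y_i``;
* at every *eligible* postsynaptic somatic spike ``t_i``, applied one
  dendritic delay ``d_EE`` later: potentiation
  ``J_max * lambda_plus * x_j(t_i + d_EE)`` plus the homeostatic term
  ``J_max * lambda_h * (z_star - z_i(t_i))``, where ``x_j`` is the
  presynaptic spike trace (decay ``tau_plus``, +1 per presynaptic spike)
  and ``z_i`` the dAP trace (decay ``tau_h``, +1 per dAP onset).

Eligibility: with ``tau = t_i - t_j^+ + d_EE`` measured against the nearest
presynaptic spike ``t_j^+`` at or before the application step, the update
fires only when ``delta_t_min < tau < delta_t_max``. This single test
implements both the pairing-window indicator and the requirement that no
presynaptic spike falls closer than ``delta_t_min`` to the postsynaptic
spike: any later presynaptic spike only shrinks ``tau`` below the bound.
Synchronous pre/post firing (``tau = d_EE``) therefore never changes the
weight, which is what prevents runaway self-connections inside a
subpopulation.
"""

from __future__ import annotations

import numpy as np

from .network import Network
from .params import ModelParams

__all__ = ["HomeostaticSTDP"]


class HomeostaticSTDP:
    """Incremental plasticity state coupled to one network's weight array."""

    def __init__(self, net: Network, params: ModelParams) -> None:
        self.net = net
        self.p = params.plasticity
        self.dt = params.dt
        self.d_steps = params.steps(params.d_EE)
        n = net.N_E
        self.x = np.zeros(n)                     # presynaptic spike traces
        self.z = np.zeros(n)                     # dAP traces
        self.last_pre_step = np.full(n, np.iinfo(np.int64).min // 2, dtype=np.int64)
        self.decay_x = np.exp(-params.dt / self.p.tau_plus)
        self.decay_z = np.exp(-params.dt / self.p.tau_h)
        self.depression = self.p.J_max * self.p.lambda_minus * self.p.y_i
        self._pending: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    # -- per-step hooks ------------------------------------------------------

    def decay_traces(self) -> None:
        self.x *= self.decay_x
        self.z *= self.decay_z

    def on_dap_onsets(self, ids: np.ndarray) -> None:
        self.z[ids] += 1.0

    def on_somatic_spikes(self, ids: np.ndarray, t_step: int) -> None:
        """Register a synchronous volley of somatic spikes at ``t_step``.

        Applies the presynaptic depression to all outgoing edges, bumps the
        spike traces, and schedules the (potentiation + homeostasis) update
        of all incoming edges for ``t_step + d_EE`` with the dAP traces
        snapshot at the spike time.
        """
        net = self.net
        if self.depression > 0.0:
            out = _edge_ranges(net.pre_ptr, ids)
            if out.size:
                w = net.edge_weight
                w[out] = np.clip(w[out] - self.depression, self.p.J_min, self.p.J_max)
        self.x[ids] += 1.0
        self.last_pre_step[ids] = t_step
        self._pending[t_step + self.d_steps] = (np.asarray(ids), self.z[ids].copy())

    def apply_scheduled(self, t_step: int) -> None:
        """Apply potentiation/homeostasis scheduled for this grid step."""
        ev = self._pending.pop(t_step, None)
        if ev is None:
            return
        ids, z_snap = ev
        t_post = t_step - self.d_steps
        net, p = self.net, self.p
        w = net.edge_weight
        lag_offset = self.d_steps  # tau includes the dendritic delay
        for i, z_i in zip(ids, z_snap):
            idx = net.in_edge_idx(i)
            if idx.size == 0:
                continue
            pres = net.edge_pre[idx]
            tau = (t_post - self.last_pre_step[pres] + lag_offset) * self.dt
            elig = (tau > p.delta_t_min) & (tau < p.delta_t_max)
            if not np.any(elig):
                continue
            sel = idx[elig]
            dw = p.J_max * (p.lambda_plus * self.x[pres[elig]]
                            + p.lambda_h * (p.z_star - z_i))
            w[sel] = np.clip(w[sel] + dw, p.J_min, p.J_max)

    def flush(self) -> None:
        """Drop scheduled updates (end of a run)."""
        self._pending.clear()


def _edge_ranges(ptr: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(ptr[j], ptr[j+1])`` for all ``j`` in ``ids``."""
    starts = ptr[ids]
    stops = ptr[np.asarray(ids) + 1]
    lens = stops - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.repeat(starts - np.concatenate([[0], np.cumsum(lens)[:-1]]), lens)
    return out + np.arange(total)
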