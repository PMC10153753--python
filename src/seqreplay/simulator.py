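"""Time-stepped network dynamics with exact integration on a fixed grid.

All linear subsystems (membrane potentials, exponential and alpha-shaped
synaptic currents) are advanced with matrix-exponential propagators, so the
update over one grid step is exact for piecewise-constant/impulsive inputs;
spikes, dAP events and resets are handled synchronously on the grid.

Update order within one step:

1. deliver delayed spikes to the synaptic state (EE volleys into the
   dendritic alpha kernels, inhibitory feedback, stimulus spikes,
   background-noise increments);
2. propagate all linear states by ``dt`` (exact), clamp refractory
   membranes, decay plasticity traces;
3. dendritic nonlinearity: expire elapsed plateaus; while the inhibitory
   feedback current is stronger than ``I_theta``, terminate ongoing
   plateaus and veto new ones; otherwise trigger plateaus where the
   dendritic current reached ``theta_dAP``;
4. somatic thresholds for all neurons simultaneously (ties fire together);
   resets, refractoriness, spike enqueueing with per-connection delays;
5. apply plasticity updates scheduled for this step.

The dendritic current of a neuron is suspended while a plateau is active or
the neuron is refractory: incoming kernels are discarded and the state
restarts from zero afterwards, matching the plateau/reset semantics of the
dAP model (the plateau amplitude is fixed, and the dendrite is reset after
both plateau end and somatic spikes).

Strong-inhibition reset: the veto is evaluated continuously (every grid
step), but it terminates *plateaus* only - subthreshold dendritic
accumulation survives the brief hyperpolarized window. This is the only
reading under which the winner-take-all feedback (which follows every
volley within ~2 ms, exactly when the next subpopulation's synaptic input
arrives) can cancel the losing sequence's predictions without also erasing
the winning sequence's forward drive.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from .inputs import NoiseConfig, StimulusSchedule, make_background
from .network import Network
from .params import ModelParams
from .plasticity import HomeostaticSTDP
from .record import SpikeRecord

__all__ = ["Simulator", "simulate"]


def _exp_propagator(tau_s: float, tau_m: float, C_m: float, dt: float):
    """Exact one-step propagator of (I_s, V) for an exponential current."""
    A = np.array([[-1.0 / tau_s, 0.0],
                  [1.0 / C_m, -1.0 / tau_m]])
    P = expm(A * dt)
    return P[0, 0], P[1, 0]  # current decay, current->V coupling


def _alpha_propagator(tau_s: float, tau_m: float, C_m: float, dt: float):
    """Exact one-step propagator of (y1, y2, V) for an alpha current."""
    A = np.array([[-1.0 / tau_s, 0.0, 0.0],
                  [1.0, -1.0 / tau_s, 0.0],
                  [0.0, 1.0 / C_m, -1.0 / tau_m]])
    P = expm(A * dt)
    return P[0, 0], P[1, 0], P[1, 1], P[2, 0], P[2, 1]


class Simulator:
    """Stateful stepping engine for one network in one mode.

    The engine owns all dynamic state, so protocols can run it in chunks
    (e.g. snapshot weights between training episodes) without resets.
    """

    def __init__(
        self,
        net: Network,
        params: ModelParams,
        seed: int = 0,
        stimulus: StimulusSchedule | None = None,
        noise: NoiseConfig | None = None,
        record_dap: bool = True,
        probe_ids: np.ndarray | None = None,
    ) -> None:
        self.net = net
        self.params = params
        self.dt = params.dt
        n = net.N_E
        p = params

        # propagator constants (exact integration)
        self.pV = np.exp(-p.dt / p.tau_m_E)
        (self.a11, self.a21, self.a22,
         self.vy1, self.vy2) = _alpha_propagator(p.tau_EE, p.tau_m_E, p.C_m, p.dt)
        self.dEI, self.vEI = _exp_propagator(p.tau_EI, p.tau_m_E, p.C_m, p.dt)
        self.dS, self.vS = _exp_propagator(p.tau_EX, p.tau_m_E, p.C_m, p.dt)
        self.dB, self.vB = _exp_propagator(p.tau_EQ, p.tau_m_E, p.C_m, p.dt)
        self.vconst = p.R_m_E * (1.0 - self.pV)  # piecewise-constant current
        self.pVI = np.exp(-p.dt / p.tau_m_I)
        self.dIE, self.vIE = _exp_propagator(p.tau_IE, p.tau_m_I, p.C_m, p.dt)

        # alpha kernel input scaling: a unit-weight spike peaks at J at t=tau
        self.kernel_gain = np.e / p.tau_EE

        # dynamic state
        self.V = np.full(n, p.V_r)
        self.y1 = np.zeros(n)
        self.y2 = np.zeros(n)
        self.I_S = np.zeros(n)
        self.I_Bp = np.zeros(n)          # Poisson background current
        self.I_EI = 0.0                  # shared inhibitory feedback current
        self.ref_count = np.zeros(n, dtype=np.int32)
        self.dap_active = np.zeros(n, dtype=bool)
        self.dap_count = np.zeros(n, dtype=np.int32)
        self.V_I = p.V_r
        self.I_IE = 0.0
        self.ref_I = 0

        # step counts
        self.t_step = 0
        self.ref_steps = p.steps(p.tau_ref_E)
        self.ref_steps_I = p.steps(p.tau_ref_I)
        self.dap_steps = p.steps(p.tau_dAP)
        self.D = p.steps(p.d_EE)
        self.d_EX_steps = p.steps(p.d_EX)

        # delayed-event buffers
        self.ring: list[np.ndarray | None] = [None] * self.D
        self._ie_pending = 0       # E spikes reaching the inhibitory neuron next step
        self._ei_pending = 0       # inhibitory spikes reaching E next step

        # stimulus schedule -> delivery steps
        if stimulus is not None and len(stimulus):
            self._stim_steps = np.round(stimulus.times_ms / p.dt).astype(np.int64) \
                + self.d_EX_steps
            self._stim_pops = stimulus.subpops
        else:
            self._stim_steps = np.empty(0, dtype=np.int64)
            self._stim_pops = np.empty(0, dtype=np.int32)
        self._stim_ptr = 0

        ss = np.random.SeedSequence(seed)
        noise_seed, = ss.spawn(1)
        self.background = (noise if not isinstance(noise, NoiseConfig)
                           else make_background(params, noise, noise_seed))
        self._bg_poisson = getattr(self.background, "decays_in_simulator", False)

        self.plasticity: HomeostaticSTDP | None = (
            HomeostaticSTDP(net, params) if params.plasticity.enabled else None
        )

        # recording
        self.record_dap = record_dap
        self._spike_events: list[tuple[int, np.ndarray]] = []
        self._dap_events: list[tuple[int, np.ndarray]] = []
        self._inh_steps: list[int] = []
        self.probe_ids = probe_ids
        self.probe_V: list[np.ndarray] = []
        self.probe_I_ED: list[np.ndarray] = []

        self._theta_E = p.theta_E
        self._theta_I = p.theta_I
        self._J_EI = p.J_EI
        self._J_IE = p.J_IE
        self._J_EX = p.J_EX
        self._I_theta = p.I_theta
        self._V_r = p.V_r
        self._dap_any = False

    # ------------------------------------------------------------------

    @property
    def t_ms(self) -> float:
        return self.t_step * self.dt

    def run(self, duration_ms: float) -> None:
        """Advance the network by ``duration_ms``."""
        n_steps = self.params.steps(duration_ms)
        for _ in range(n_steps):
            self._step()

    def _step(self) -> None:
        net, t = self.net, self.t_step
        plast = self.plasticity

        # -- 1. deliveries -------------------------------------------------
        slot = t % self.D
        bucket = self.ring[slot]
        if bucket is not None:
            self.ring[slot] = None
            if bucket.size:
                eidx = _edge_ranges(net.pre_ptr, bucket)
                tgt = net.edge_post[eidx]
                open_mask = ~(self.dap_active[tgt] | (self.ref_count[tgt] > 0))
                if open_mask.any():
                    np.add.at(self.y1, tgt[open_mask],
                              net.edge_weight[eidx[open_mask]] * self.kernel_gain)
        if self._ei_pending:
            self.I_EI += self._J_EI * self._ei_pending
            self._ei_pending = 0
        if self._ie_pending:
            self.I_IE += self._J_IE * self._ie_pending
            self._ie_pending = 0
        sp = self._stim_ptr
        steps_arr = self._stim_steps
        while sp < steps_arr.size and steps_arr[sp] == t:
            k = self._stim_pops[sp]
            self.I_S[net.subpop_slice(k)] += self._J_EX
            sp += 1
        self._stim_ptr = sp
        osc_now = None
        bg = self.background
        if bg is not None:
            if self._bg_poisson:
                jumps = bg.step_jumps()
                if jumps is not None:
                    self.I_Bp += jumps
            else:
                osc_now = bg.current(t * self.dt)

        # -- 2. exact propagation ------------------------------------------
        V, y1, y2 = self.V, self.y1, self.y2
        V *= self.pV
        V += self.vy1 * y1
        V += self.vy2 * y2
        if self._dap_any:
            V += (self.vconst * self.params.I_dAP) * self.dap_active
        if self.I_EI != 0.0:
            V += self.vEI * self.I_EI
        V += self.vS * self.I_S
        if bg is not None:
            if self._bg_poisson:
                V += self.vB * self.I_Bp
            else:
                V += self.vconst * osc_now
        y2 *= self.a22
        y2 += self.a21 * y1
        y1 *= self.a11
        self.I_EI *= self.dEI
        self.I_S *= self.dS
        if self._bg_poisson:
            self.I_Bp *= self.dB

        refr = self.ref_count > 0
        if refr.any():
            V[refr] = self._V_r
            self.ref_count[refr] -= 1

        self.V_I = self.pVI * self.V_I + self.vIE * self.I_IE
        self.I_IE *= self.dIE
        if self.ref_I > 0:
            self.V_I = self._V_r
            self.ref_I -= 1

        if plast is not None:
            plast.decay_traces()

        # -- 3. dendritic nonlinearity --------------------------------------
        dap = self.dap_active
        if self._dap_any:
            self.dap_count[dap] -= 1
            np.logical_and(dap, self.dap_count > 0, out=dap)
        if self.I_EI < self._I_theta:
            if self._dap_any:
                dap[:] = False
                self.dap_count[:] = 0
                self._dap_any = False
        else:
            onset = (y2 >= self.params.theta_dAP) & ~dap & ~refr
            if onset.any():
                ids = np.flatnonzero(onset)
                dap[ids] = True
                self.dap_count[ids] = self.dap_steps
                y1[ids] = 0.0
                y2[ids] = 0.0
                if self.record_dap:
                    self._dap_events.append((t, ids))
                if plast is not None:
                    plast.on_dap_onsets(ids)
            self._dap_any = bool(dap.any())

        # -- 4. somatic thresholds ------------------------------------------
        fire_ids = np.flatnonzero(V >= self._theta_E)
        if fire_ids.size:
            if not np.all(np.isfinite(V[fire_ids])):
                bad = fire_ids[~np.isfinite(V[fire_ids])][0]
                raise FloatingPointError(
                    f"non-finite membrane potential in neuron {bad} at t={t * self.dt} ms"
                )
            self._spike_events.append((t, fire_ids))
            V[fire_ids] = self._V_r
            self.ref_count[fire_ids] = self.ref_steps
            y1[fire_ids] = 0.0
            y2[fire_ids] = 0.0
            if self._dap_any:
                dap[fire_ids] = False
                self.dap_count[fire_ids] = 0
                self._dap_any = bool(dap.any())
            self.ring[slot] = fire_ids           # delivered at t + d_EE
            self._ie_pending = fire_ids.size     # d_IE = one step
            if plast is not None:
                plast.on_somatic_spikes(fire_ids, t)
        if self.V_I >= self._theta_I and self.ref_I == 0:
            self._inh_steps.append(t)
            self.V_I = self._V_r
            self.ref_I = self.ref_steps_I
            self._ei_pending = 1                 # d_EI = one step

        # -- 5. scheduled plasticity ----------------------------------------
        if plast is not None:
            plast.apply_scheduled(t)

        # -- probes ----------------------------------------------------------
        if self.probe_ids is not None:
            pid = self.probe_ids
            self.probe_V.append(V[pid].copy())
            ied = np.where(self.dap_active[pid], self.params.I_dAP, y2[pid])
            self.probe_I_ED.append(ied)

        self.t_step = t + 1

    # ------------------------------------------------------------------

    def spike_record(self) -> SpikeRecord:
        meta = {
            "mode": self.params.mode,
            "params_hash": self.params.hash(),
            "n_steps": self.t_step,
        }
        return SpikeRecord.from_event_lists(
            self._spike_events, self._dap_events, self._inh_steps,
            self.dt, self.net.subpop_of, meta,
        )

    def I_ED(self) -> np.ndarray:
        """Current dendritic current of every excitatory neuron."""
        return np.where(self.dap_active, self.params.I_dAP, self.y2)


def simulate(
    net: Network,
    params: ModelParams,
    stimulus: StimulusSchedule | None = None,
    duration_ms: float = 0.0,
    seed: int = 0,
    noise: NoiseConfig | None = None,
    probe_ids: np.ndarray | None = None,
) -> SpikeRecord:
    """One-shot convenience wrapper: run ``duration_ms`` and return the record."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    sim = Simulator(net, params, seed=seed, stimulus=stimulus, noise=noise,
                    probe_ids=probe_ids)
    sim.run(duration_ms)
    return sim.spike_record()


def _edge_ranges(ptr: np.ndarray, ids: np.ndarray) -> np.ndarray:
    starts = ptr[ids]
    lens = ptr[ids + 1] - starts
    total = int(lens.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.repeat(starts - np.concatenate([[0], np.cumsum(lens)[:-1]]), lens)
    return out + np.arange(total)
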