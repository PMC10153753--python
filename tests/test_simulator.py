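"""Dynamics of the exact-integration stepping engine."""

import dataclasses

import numpy as np
import pytest

import seqreplay as sq
from seqreplay.inputs import StimulusSchedule
from seqreplay.simulator import Simulator

from conftest import make_manual_net


def two_neuron_params(**over):
    # plasticity off: these tests probe the dynamics with hand-set weights
    # (some above J_max, which the plasticity clip would otherwise pull down)
    base = dict(N_E=2, M=2, K_EE=1, rho=1,
                plasticity=sq.PlasticityParams(enabled=False))
    base.update(over)
    return sq.ModelParams(**base)


def stim(times, pops, duration):
    return StimulusSchedule(np.asarray(times, float),
                            np.asarray(pops, np.int32), duration)


def test_zero_input_stays_at_rest():
    params = two_neuron_params()
    net = make_manual_net(2, 2, [(0, 1)], [0.0])
    sim = Simulator(net, params, seed=0)
    sim.run(50.0)
    assert np.all(sim.V == params.V_r)
    assert sim.spike_record().n_spikes == 0


def test_free_membrane_decays_exponentially():
    params = two_neuron_params()
    net = make_manual_net(2, 2, [(0, 1)], [0.0])
    sim = Simulator(net, params, seed=0)
    sim.V[:] = 5.0
    sim.run(10.0)  # one membrane time constant
    assert sim.V[0] == pytest.approx(5.0 * np.exp(-1.0), rel=1e-12)


def test_exact_integration_matches_fine_euler():
    """One grid step of the propagator = analytic solution; a 100 ms window
    agrees with brute-force Euler at step dt/1000."""
    params = two_neuron_params(theta_E_train=np.inf, theta_dAP=np.inf)
    net = make_manual_net(2, 2, [(0, 1)], [0.0])
    sim = Simulator(net, params, seed=0)
    y1_0, y2_0, IS_0, IEI_0, V_0 = 3.0, 7.0, 11.0, -40.0, 1.5
    sim.y1[0], sim.y2[0], sim.I_S[0], sim.I_EI, sim.V[0] = y1_0, y2_0, IS_0, IEI_0, V_0

    # independent oracle: explicit Euler on the ODE system at dt/1000
    h = params.dt / 1000.0
    n = int(round(100.0 / h))
    y1, y2, i_s, i_ei, v = y1_0, y2_0, IS_0, IEI_0, V_0
    tau_m, tau_a, tau_s, tau_i, C = (params.tau_m_E, params.tau_EE,
                                     params.tau_EX, params.tau_EI, params.C_m)
    for _ in range(n):
        dv = (-v + (tau_m / C) * (y2 + i_s + i_ei)) / tau_m
        dy1 = -y1 / tau_a
        dy2 = -y2 / tau_a + y1
        dis = -i_s / tau_s
        dei = -i_ei / tau_i
        v += h * dv
        y1 += h * dy1
        y2 += h * dy2
        i_s += h * dis
        i_ei += h * dei

    sim.run(100.0)
    assert sim.V[0] == pytest.approx(v, rel=1e-5)
    assert sim.y2[0] == pytest.approx(y2, rel=1e-5)
    assert sim.I_S[0] == pytest.approx(i_s, rel=1e-5)


def test_alpha_kernel_peaks_at_weight_after_tau():
    """A single EE spike of weight J drives I_ED to a maximum of J at
    one synaptic time constant after delivery."""
    J = 30.0  # below theta_dAP so the kernel is never clamped
    params = two_neuron_params()
    net = make_manual_net(2, 2, [(0, 1)], [J])
    sched = stim([0.0], [0], 500.0)
    sim = Simulator(net, params, seed=0, stimulus=sched, probe_ids=np.array([1]))
    sim.run(200.0)
    ied = np.array(sim.probe_I_ED)[:, 0]
    t_peak = np.argmax(ied) * params.dt
    t_spike = sim.spike_record().spike_times[0]
    assert ied.max() == pytest.approx(J, rel=1e-4)
    assert t_peak == pytest.approx(t_spike + params.d_EE + params.tau_EE, abs=0.2)


def test_dap_plateau_held_exactly_then_reset():
    """Crossing theta_dAP clamps I_ED to I_dAP for exactly tau_dAP, then 0;
    in training mode the 8 mV plateau drive stays below threshold, and the
    membrane follows the constant-current charging curve toward R_m*I_dAP."""
    params = two_neuron_params()
    net = make_manual_net(2, 2, [(0, 1)], [100.0])  # crosses theta_dAP = 59 pA
    sched = stim([0.0], [0], 500.0)
    sim = Simulator(net, params, seed=0, stimulus=sched, probe_ids=np.array([1]))
    sim.run(300.0)
    ied = np.array(sim.probe_I_ED)[:, 0]
    plateau = np.flatnonzero(ied == params.I_dAP)
    assert plateau.size == params.steps(params.tau_dAP)
    assert np.all(np.diff(plateau) == 1)
    assert ied[plateau[-1] + 1] == 0.0

    rec = sim.spike_record()
    assert rec.dap_ids.tolist() == [1]
    assert np.all(rec.spike_ids == 0)  # the postsynaptic neuron never fires at 20 mV

    # membrane approaches R_m * I_dAP = 8 mV along 1 - exp(-t/tau_m)
    V = np.array(sim.probe_V)[:, 0]
    onset = plateau[0]
    v_eq = params.R_m_E * params.I_dAP
    assert v_eq == pytest.approx(8.0)
    t_rel = (plateau[-1] - onset) * params.dt
    expected = V[onset] * np.exp(-t_rel / params.tau_m_E) \
        + v_eq * (1 - np.exp(-t_rel / params.tau_m_E))
    assert V[plateau[-1]] == pytest.approx(expected, abs=0.05)


def test_dap_alone_fires_soma_only_in_replay_mode():
    params = two_neuron_params()
    net = make_manual_net(2, 2, [(0, 1)], [100.0])
    rec_train = sq.simulate(net, params, stim([0.0], [0], 300.0), 300.0, seed=0)
    assert 1 not in rec_train.spike_ids
    rec_replay = sq.simulate(net, params.replay_mode(), stim([0.0], [0], 300.0),
                             300.0, seed=0)
    assert 1 in rec_replay.spike_ids  # 8 mV plateau > 7 mV replay threshold


def test_strong_inhibition_terminates_plateau():
    """When the inhibitory feedback current drops below I_theta, an ongoing
    plateau is cut short and I_ED returns to zero at the next grid point."""
    params = two_neuron_params(rho=1, theta_I=0.5, J_IE=5000.0)
    net = make_manual_net(2, 2, [(0, 1)], [100.0])
    # first stimulus triggers neuron 1's dAP; the second (25 ms, after neuron
    # 0 leaves refractoriness) fires neuron 0 again, which now drives the
    # inhibitory neuron above its (lowered) threshold
    sched = stim([0.0, 25.0], [0, 0], 500.0)
    sim = Simulator(net, params, seed=0, stimulus=sched, probe_ids=np.array([1]))
    sim.run(35.0)
    rec = sim.spike_record()
    ied = np.array(sim.probe_I_ED)[:, 0]
    plateau = np.flatnonzero(ied == params.I_dAP)
    assert plateau.size > 0 and np.all(np.diff(plateau) == 1)
    dur = plateau.size * params.dt
    assert dur < params.tau_dAP  # cut short well before the nominal 60 ms
    t_on = plateau[0] * params.dt
    killers = rec.inh_spike_times[rec.inh_spike_times >= t_on]
    assert killers.size >= 1
    t_end = (plateau[-1] + 1) * params.dt
    assert t_end == pytest.approx(killers[0] + params.d_EI + params.dt, abs=0.11)


def test_rho_coincident_inputs_trigger_inhibitory_neuron(default_params):
    """rho simultaneous excitatory spikes fire the WTA neuron; slightly
    fewer do not."""
    def peak_V(n_spikes):
        net = make_manual_net(2, 2, [(0, 1)], [0.0])
        sim = Simulator(net, default_params, seed=0)
        sim._ie_pending = n_spikes
        peaks = []
        for _ in range(50):
            sim._step()
            peaks.append(sim.V_I)
        return max(peaks), sim.spike_record().inh_spike_times.size

    v20, fired20 = peak_V(default_params.rho)
    v18, fired18 = peak_V(18)
    assert fired20 >= 1
    assert fired18 == 0 and v18 < default_params.theta_I < v20 + 1.0


def test_single_inhibitory_spike_hyperpolarizes_everyone(default_params):
    net = make_manual_net(2, 2, [(0, 1)], [0.0])
    sim = Simulator(net, default_params, seed=0)
    sim._ei_pending = 1
    sim._step()
    assert sim.I_EI == pytest.approx(default_params.J_EI * np.exp(-0.1), rel=1e-12)
    sim.run(5.0)
    assert np.all(sim.V < 0)  # both excitatory neurons pushed below rest


def test_inhibitory_current_decays_exponentially(default_params):
    net = make_manual_net(2, 2, [(0, 1)], [0.0])
    sim = Simulator(net, default_params, seed=0)
    sim.I_EI = -100.0
    sim.run(3.0)  # three tau_EI
    assert sim.I_EI == pytest.approx(-100.0 * np.exp(-3.0), rel=1e-12)


def test_empty_schedule_is_silent(micro):
    rec = sq.simulate(micro.net, micro.params, None, 100.0, seed=0)
    assert rec.n_spikes == 0 and rec.dap_times.size == 0


def test_training_stimulus_fires_whole_subpopulation(default_params, default_net):
    """Before any learning, a sequence-element stimulus makes all n_E
    neurons of the subpopulation fire (once)."""
    sched = stim([5.0], [2], 100.0)
    rec = sq.simulate(default_net, default_params, sched, 60.0, seed=0)
    in_pop = rec.spike_subpops() == 2
    assert np.unique(rec.spike_ids[in_pop]).size == default_params.n_E
    assert rec.spike_ids[in_pop].size == default_params.n_E


def test_same_seed_reproduces_identical_records(micro):
    sched = stim([5.0, 45.0], [0, 1], 200.0)
    noise = sq.NoiseConfig(kind="poisson", sigma=10.0, c=1.0)
    params = micro.params.replay_mode()
    recs = [sq.simulate(micro.net, params, sched, 200.0, seed=7, noise=noise)
            for _ in range(2)]
    assert np.array_equal(recs[0].spike_times, recs[1].spike_times)
    assert np.array_equal(recs[0].spike_ids, recs[1].spike_ids)
    assert np.array_equal(recs[0].dap_times, recs[1].dap_times)


def test_refractory_interval_respected(default_params, default_net):
    """Consecutive somatic spikes of any neuron are >= tau_ref apart."""
    times = [5.0, 30.0, 55.0, 80.0]
    sched = stim(times, [0, 0, 0, 0], 200.0)
    rec = sq.simulate(default_net, default_params, sched, 150.0, seed=0)
    for i in np.unique(rec.spike_ids):
        ts = np.sort(rec.spike_times[rec.spike_ids == i])
        if ts.size > 1:
            assert np.all(np.diff(ts) >= default_params.tau_ref_E)
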