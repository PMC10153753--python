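"""Single-edge plasticity against a brute-force rule evaluation.

The oracle below evaluates the weight-update rule literally on a scripted
list of pre-spike / post-spike / dAP-onset times for one edge, using exact
exponential trace values, and is independent of the incremental
trace-and-queue implementation it checks.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seqreplay import ModelParams, PlasticityParams
from seqreplay.plasticity import HomeostaticSTDP

from conftest import make_manual_net


def oracle_single_edge(script, params: ModelParams, w0: float) -> float:
    """Brute-force weight trajectory for edge 0 -> 1.

    ``script`` maps step -> set of events among {"pre", "post", "dap"}
    (dAP onsets are of the postsynaptic neuron). Potentiation and
    homeostasis are applied at the post spike time plus the dendritic
    delay, gated on the nearest presynaptic spike known by then.
    """
    p = params.plasticity
    dt = params.dt
    d = params.steps(params.d_EE)
    pre_steps = sorted(s for s, ev in script.items() if "pre" in ev)
    dap_steps = sorted(s for s, ev in script.items() if "dap" in ev)
    post_steps = sorted(s for s, ev in script.items() if "post" in ev)

    def x_at(step):  # presynaptic spike trace, exact exponential
        return sum(np.exp(-(step - s) * dt / p.tau_plus) for s in pre_steps if s <= step)

    def z_at(step):  # dAP trace of the postsynaptic neuron
        return sum(np.exp(-(step - s) * dt / p.tau_h) for s in dap_steps if s <= step)

    events = []  # (step, order, kind)
    for s in pre_steps:
        events.append((s, 0, "dep"))
    for s in post_steps:
        events.append((s + d, 1, ("pot", s)))
    w = w0
    for step, _, kind in sorted(events, key=lambda e: (e[0], e[1])):
        if kind == "dep":
            w = np.clip(w - p.J_max * p.lambda_minus * p.y_i, p.J_min, p.J_max)
        else:
            t_post = kind[1]
            known_pre = [s for s in pre_steps if s <= t_post + d]
            if not known_pre:
                continue
            tau = (t_post - max(known_pre) + d) * dt
            if not (p.delta_t_min < tau < p.delta_t_max):
                continue
            dw = p.J_max * (p.lambda_plus * x_at(t_post + d)
                            + p.lambda_h * (p.z_star - z_at(t_post)))
            w = np.clip(w + dw, p.J_min, p.J_max)
    return float(w)


def run_incremental(script, params: ModelParams, w0: float) -> float:
    """Drive the event-driven implementation with the same script."""
    net = make_manual_net(2, 2, [(0, 1)], [w0])
    stdp = HomeostaticSTDP(net, params)
    horizon = max(script) + params.steps(params.d_EE) + 1
    for t in range(horizon):
        stdp.decay_traces()
        ev = script.get(t, set())
        if "dap" in ev:
            stdp.on_dap_onsets(np.array([1]))
        ids = []
        if "pre" in ev:
            ids.append(0)
        if "post" in ev:
            ids.append(1)
        if ids:
            stdp.on_somatic_spikes(np.array(ids), t)
        stdp.apply_scheduled(t)
    return float(net.edge_weight[0])


SCRIPTS = [
    # causal pair inside the window: pre at 0, post at 20 ms (tau = 22 ms)
    {0: {"pre"}, 200: {"post"}},
    # pair below the minimum lag: pre at 0, post at 1 ms (tau = 3 ms)
    {0: {"pre"}, 10: {"post"}},
    # pair beyond the maximum lag: pre at 0, post at 60 ms (tau = 62 ms)
    {0: {"pre"}, 600: {"post"}},
    # exactly at the lower bound (tau = delta_t_min): no update (strict window)
    {0: {"pre"}, 20: {"post"}},
    # synchronous pre/post (tau = d_EE)
    {100: {"pre", "post"}},
    # post with no presynaptic spike at all
    {50: {"post"}},
    # dAP onsets raise z and shrink the homeostatic term
    {0: {"dap"}, 5: {"pre", "dap"}, 205: {"post"}},
    # a second pre spike close to the post spike vetoes the update
    {0: {"pre"}, 195: {"pre"}, 200: {"post"}},
    # depression accumulates across repeated pre spikes
    {0: {"pre"}, 50: {"pre"}, 100: {"pre"}, 400: {"post"}},
    # pre spike landing between post spike and its delayed application
    {0: {"pre"}, 200: {"post"}, 210: {"pre"}},
]


@pytest.mark.parametrize("script", SCRIPTS)
def test_single_edge_matches_bruteforce(script, default_params):
    w_inc = run_incremental(script, default_params, w0=5.0)
    w_ref = oracle_single_edge(script, default_params, w0=5.0)
    assert w_inc == pytest.approx(w_ref, abs=1e-12)


def test_depression_magnitude_and_clipping(default_params):
    p = default_params.plasticity
    # one presynaptic spike alone depresses by exactly J_max*lambda_minus*y_i
    w = run_incremental({0: {"pre"}}, default_params, w0=5.0)
    assert w == pytest.approx(5.0 - p.J_max * p.lambda_minus * p.y_i, abs=1e-15)
    # at the lower bound the weight is clipped, not driven negative
    w = run_incremental({0: {"pre"}}, default_params, w0=p.J_min)
    assert w == p.J_min


def test_homeostasis_sign_without_daps(default_params):
    """With z = 0 the homeostatic term pushes eligible synapses up."""
    w = run_incremental({0: {"pre"}, 200: {"post"}}, default_params, w0=5.0)
    p = default_params.plasticity
    dep = p.J_max * p.lambda_minus * p.y_i
    gain = w - (5.0 - dep)
    assert gain > p.J_max * p.lambda_h * (p.z_star - 1) > 0


def test_trace_decay_and_fixed_point(default_params):
    """x decays exponentially; the z fixed point sits at rate*tau_h."""
    net = make_manual_net(2, 2, [(0, 1)], [5.0])
    stdp = HomeostaticSTDP(net, default_params)
    stdp.on_somatic_spikes(np.array([0]), 0)
    for t in range(1, 201):
        stdp.decay_traces()
        stdp.apply_scheduled(t)
    assert stdp.x[0] == pytest.approx(np.exp(-1.0), rel=1e-12)  # 20 ms at tau_+ = 20 ms

    # steady dAP rate r: trace converges to r * tau_h
    p = default_params.plasticity
    period_ms = 220.0
    stdp2 = HomeostaticSTDP(net, default_params)
    n_steps = int(60_000 / default_params.dt)
    period = int(period_ms / default_params.dt)
    for t in range(n_steps):
        stdp2.decay_traces()
        if t % period == 0:
            stdp2.on_dap_onsets(np.array([1]))
    expected = (1.0 / period_ms) * p.tau_h  # rate in 1/ms times tau_h in ms
    assert stdp2.z[1] == pytest.approx(expected, rel=0.05)


@settings(max_examples=25, deadline=None)
@given(st.lists(
    st.tuples(st.integers(0, 400), st.sampled_from(["pre", "post", "dap"])),
    min_size=1, max_size=10,
))
def test_random_scripts_match_oracle_and_stay_bounded(events):
    params = ModelParams(plasticity=PlasticityParams(
        lambda_plus=0.05, lambda_minus=0.01, lambda_h=0.04, z_star=2.0))
    script: dict[int, set] = {}
    for step, kind in events:
        script.setdefault(step, set()).add(kind)
    w_inc = run_incremental(script, params, w0=1.0)
    w_ref = oracle_single_edge(script, params, w0=1.0)
    assert w_inc == pytest.approx(w_ref, abs=1e-12)
    assert params.plasticity.J_min <= w_inc <= params.plasticity.J_max


def test_disabled_plasticity_leaves_weights_untouched(micro):
    import seqreplay as sq
    w0 = micro.net.edge_weight.copy()
    rp = sq.set_replay_mode(micro.params)
    sq.replay(micro.net, rp, micro.task, "A", 2, seed=1)
    assert np.array_equal(micro.net.edge_weight, w0)
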