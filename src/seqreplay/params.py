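"""Model parameters for the spiking temporal-memory network.

All quantities are in fixed units: time in ms, voltage in mV, current in pA,
capacitance in pF. Rates carried by :class:`PlasticityParams` are
dimensionless per-event increments.

The network operates in one of two modes:

``training``
    High somatic threshold (``theta_E_train``): excitatory neurons fire only
    when driven by the external stimulus; plasticity is enabled; no
    background noise.
``replay``
    Lowered somatic threshold (``theta_E_replay``): the plateau current of a
    dendritic action potential alone suffices to drive a neuron across
    threshold, so learned sequences unroll autonomously after a cue;
    plasticity is frozen and background noise may be injected.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field


@dataclass
class PlasticityParams:
    """Homeostatic spike-timing-dependent plasticity on E->E synapses.

    Weight changes combine three event-driven terms (all scaled by
    ``J_max``): potentiation proportional to the presynaptic spike trace at
    the postsynaptic spike (rate ``lambda_plus``), a fixed depression at
    every presynaptic spike (rate ``lambda_minus``, decrement ``y_i``), and
    a homeostatic term ``lambda_h * (z_star - z_i)`` steering the dendritic
    action-potential rate of the postsynaptic cell toward the target
    ``z_star``. Potentiation and homeostasis apply only when the pre/post
    lag (corrected by the dendritic delay) falls strictly inside
    ``(delta_t_min, delta_t_max)``. Weights are hard-clipped to
    ``[J_min, J_max]`` after every increment.
    """

    lambda_plus: float = 0.0009     # potentiation rate
    lambda_minus: float = 0.000014  # depression rate
    lambda_h: float = 0.0008        # homeostasis rate
    J_min: float = 0.0              # pA, minimum weight
    J_max: float = 35.0             # pA, maximum weight
    J0_min: float = 0.0             # pA, minimal initial weight
    J0_max: float = 1.0             # pA, maximal initial weight
    tau_plus: float = 20.0          # ms, potentiation (spike-trace) time constant
    tau_h: float = 2200.0           # ms, homeostasis (dAP-trace) time constant
    z_star: float = 10.35           # target dAP activity
    y_i: float = 1.0                # depression decrement
    delta_t_min: float = 4.0        # ms, minimum eligible pre/post lag
    delta_t_max: float = 50.0       # ms, maximum eligible pre/post lag
    enabled: bool = True

    def validate(self) -> None:
        if not (self.J_min <= self.J0_min <= self.J0_max <= self.J_max):
            raise ValueError(
                "weight bounds must satisfy J_min <= J0_min <= J0_max <= J_max"
            )
        if not self.delta_t_min < self.delta_t_max:
            raise ValueError("delta_t_min must be smaller than delta_t_max")
        for name in ("lambda_plus", "lambda_minus", "lambda_h", "y_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("tau_plus", "tau_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ModelParams:
    """All network, neuron, synapse and simulation parameters.

    Defaults correspond to the two-sequence configuration (six
    subpopulations of 150 excitatory neurons, one inhibitory neuron).
    Derived quantities (``n_E``, ``theta_E``, membrane resistances, the
    background weight ``J_EQ``) are exposed as properties and cannot be set
    inconsistently.
    """

    # -- network ------------------------------------------------------------
    N_E: int = 900      # total number of excitatory neurons
    N_I: int = 1        # total number of inhibitory neurons
    M: int = 6          # number of excitatory subpopulations
    rho: int = 20       # target active neurons per subpopulation after learning

    # -- connectivity --------------------------------------------------------
    K_EE: int = 180     # excitatory in-degree of excitatory neurons
    K_EQ: int = 100     # excitatory Poisson background in-degree
    K_EV: int | None = None  # inhibitory Poisson background in-degree (= K_EQ)

    # -- excitatory neurons ---------------------------------------------------
    tau_m_E: float = 10.0    # ms, membrane time constant
    tau_ref_E: float = 20.0  # ms, absolute refractory period
    C_m: float = 250.0       # pF, membrane capacitance (both neuron types)
    V_r: float = 0.0         # mV, reset potential
    theta_E_train: float = 20.0   # mV, somatic threshold in training mode
    theta_E_replay: float = 7.0   # mV, somatic threshold in replay mode
    I_dAP: float = 200.0     # pA, dAP plateau current amplitude
    tau_dAP: float = 60.0    # ms, dAP plateau duration
    theta_dAP: float = 59.0  # pA, dAP activation threshold
    I_theta: float = -1000.0  # pA, inhibitory current level resetting dAPs

    # -- inhibitory neuron ----------------------------------------------------
    tau_m_I: float = 5.0
    tau_ref_I: float = 2.0
    theta_I: float = 15.0    # mV, spike threshold

    # -- synapses --------------------------------------------------------------
    J_IE: float = 532.76      # pA, E->I weight
    J_EI: float = -12915.49   # pA, I->E weight
    J_EX: float = 4112.20     # pA, stimulus weight
    J_EG: float = 1.0         # pA, oscillatory generator weight
    tau_EE: float = 30.0      # ms, E->E (dendritic, alpha-shaped)
    tau_EI: float = 1.0       # ms, I->E (exponential)
    tau_EX: float = 2.0       # ms, stimulus (exponential)
    tau_IE: float = 0.5       # ms, E->I (exponential)
    tau_EQ: float = 2.0       # ms, Poisson background (exponential)
    d_EE: float = 2.0         # ms, E->E delay (dendritic)
    d_IE: float = 0.1         # ms
    d_EI: float = 0.1         # ms
    d_EX: float = 0.1         # ms
    d_EQ: float = 0.1         # ms

    # -- plasticity -------------------------------------------------------------
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)

    # -- simulation ---------------------------------------------------------------
    dt: float = 0.1           # ms, grid step
    mode: str = "training"    # "training" or "replay"

    # derived ---------------------------------------------------------------

    @property
    def n_E(self) -> int:
        """Number of excitatory neurons per subpopulation."""
        return self.N_E // self.M

    @property
    def theta_E(self) -> float:
        """Somatic threshold of excitatory neurons in the current mode."""
        return self.theta_E_train if self.mode == "training" else self.theta_E_replay

    @property
    def R_m_E(self) -> float:
        """Membrane resistance of excitatory neurons (GOhm = mV/pA)."""
        return self.tau_m_E / self.C_m

    @property
    def R_m_I(self) -> float:
        return self.tau_m_I / self.C_m

    @property
    def tau_EV(self) -> float:
        return self.tau_EQ

    @property
    def d_EV(self) -> float:
        return self.d_EQ

    @property
    def k_EV(self) -> int:
        return self.K_EQ if self.K_EV is None else self.K_EV

    # -------------------------------------------------------------------------

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("training", "replay"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.N_E % self.M != 0:
            raise ValueError("N_E must be an integer multiple of M")
        if self.N_I != 1:
            raise ValueError("the winner-take-all circuit uses a single inhibitory neuron")
        if self.K_EE >= self.N_E:
            raise ValueError(
                f"EE in-degree K_EE={self.K_EE} must be smaller than the "
                f"presynaptic pool of N_E-1={self.N_E - 1} neurons"
            )
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        for name in (
            "tau_m_E", "tau_m_I", "tau_ref_E", "tau_ref_I", "C_m",
            "tau_EE", "tau_EI", "tau_EX", "tau_IE", "tau_EQ", "tau_dAP",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("d_EE", "d_IE", "d_EI", "d_EX", "d_EQ"):
            d = getattr(self, name)
            if d <= 0:
                raise ValueError(f"{name} must be strictly positive")
            if abs(d / self.dt - round(d / self.dt)) > 1e-9:
                raise ValueError(f"{name}={d} ms is not an integer multiple of dt={self.dt} ms")
        self.plasticity.validate()

    def steps(self, interval_ms: float) -> int:
        """Number of grid steps covering ``interval_ms``."""
        return int(round(interval_ms / self.dt))

    def replay_mode(self) -> "ModelParams":
        """Copy of the parameters switched to replay: low threshold, frozen weights."""
        p = dataclasses.replace(self, mode="replay")
        p.plasticity = dataclasses.replace(self.plasticity, enabled=False)
        return p

    def training_mode(self) -> "ModelParams":
        p = dataclasses.replace(self, mode="training")
        p.plasticity = dataclasses.replace(self.plasticity, enabled=True)
        return p

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = dict(d)
        pl = d.pop("plasticity", {})
        known = {f.name for f in dataclasses.fields(cls) if f.name != "plasticity"}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown model parameter(s): {sorted(unknown)}")
        pl_known = {f.name for f in dataclasses.fields(PlasticityParams)}
        pl_unknown = set(pl) - pl_known
        if pl_unknown:
            raise KeyError(f"unknown plasticity parameter(s): {sorted(pl_unknown)}")
        return cls(plasticity=PlasticityParams(**pl), **d)

    def hash(self) -> str:
        """Stable short hash of the full parameter set (for run metadata)."""
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
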