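"""External inputs: sequence stimuli, Poisson background pools, oscillations.

Three kinds of external drive are modeled:

* **Sequence stimuli** — each sequence element is a single spike from a
  symbol-specific source feeding every neuron of the matching subpopulation
  through an exponential synapse (weight ``J_EX``, time constant
  ``tau_EX``). :func:`encode_task` turns a task definition into a flat,
  time-ordered stimulus schedule.

* **Correlated Poisson background** — every subpopulation owns private
  pools of ``n`` excitatory and ``n`` inhibitory Poisson sources firing at
  rate ``nu``; each neuron draws ``K`` sources from each pool without
  replacement (weights ``+J_EQ`` / ``-J_EQ``). Shared sources induce a
  within-subpopulation input-current correlation ``c = K/n`` while neurons
  of different subpopulations stay uncorrelated. ``J_EQ`` is derived from
  the requested current standard deviation ``sigma`` via
  ``sigma^2 = J^2 K nu tau_B``, i.e. ``J_EQ = sigma / sqrt(K nu tau_B)``.
  For ``c = 0`` every neuron has its own independent sources.

* **Oscillatory background** — a sinusoidal current
  ``I_B(t) = J_EG * a * sin(2 pi f t + phi_k)`` with one random phase per
  subpopulation (uniform on ``[0, 2 pi)``), shared by all of its neurons.

Background noise belongs to the replay phase; attaching it to a
training-mode simulation is rejected unless explicitly overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParams

__all__ = [
    "SequenceTask", "StimulusSchedule", "encode_task",
    "NoiseConfig", "PoissonBackground", "OscillatoryBackground",
    "make_poisson_background", "oscillatory_background", "cue_schedule",
    "TWO_SEQUENCE_TASK", "FIVE_SEQUENCE_TASK",
]


# ---------------------------------------------------------------------------
# sequence task and stimulus encoding
# ---------------------------------------------------------------------------

@dataclass
class SequenceTask:
    """An ensemble of symbol sequences with relative training frequencies.

    ``alphabet[k]`` is the symbol encoded by subpopulation ``k``.
    ``delta_T`` is the inter-stimulus interval within a sequence and
    ``delta_T_seq`` the interval between the last element of one sequence
    and the first element of the next. An episode holds ``L`` sequence
    presentations with per-sequence counts proportional to ``probs``;
    training repeats the episode ``N_e`` times, either in a fixed
    deterministic order or reshuffled per episode.
    """

    alphabet: list[str]
    sequences: list[list[str]]
    probs: list[float]
    delta_T: float = 40.0        # ms, inter-stimulus interval
    delta_T_seq: float = 100.0   # ms, inter-sequence interval
    N_e: int = 20                # training episodes
    L: int = 10                  # sequences per episode
    order: str = "fixed"         # "fixed" | "shuffled"

    def __post_init__(self) -> None:
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("relative training frequencies must sum to 1")
        if len(self.probs) != len(self.sequences):
            raise ValueError("one frequency per sequence required")
        if self.order not in ("fixed", "shuffled"):
            raise ValueError(f"unknown order policy {self.order!r}")
        symbols = {s for seq in self.sequences for s in seq}
        missing = symbols - set(self.alphabet)
        if missing:
            raise ValueError(f"sequence symbols not in alphabet: {sorted(missing)}")

    @property
    def S(self) -> int:
        return len(self.sequences)

    def subpop_of_symbol(self, symbol: str) -> int:
        try:
            return self.alphabet.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None

    def last_subpops(self) -> list[int]:
        """Subpopulation of the final element of each sequence."""
        return [self.subpop_of_symbol(seq[-1]) for seq in self.sequences]

    def episode_counts(self, episode: int) -> list[int]:
        """Integer number of presentations of each sequence in one episode.

        Quotas are assigned by a cumulative (Bresenham-style) rule so that
        counts sum to ``L`` in every episode and long-run totals are
        proportional to ``probs`` even when ``p_i * L`` is fractional.
        """
        lo = self._cum_quota(episode * self.L)
        hi = self._cum_quota((episode + 1) * self.L)
        return [int(h - l) for l, h in zip(lo, hi)]

    def _cum_quota(self, total: int) -> np.ndarray:
        ideal = np.asarray(self.probs) * total
        base = np.floor(ideal).astype(int)
        rem = total - base.sum()
        if rem:
            frac = ideal - base
            give = np.argsort(-(frac + 1e-12 * np.arange(len(frac))))[:rem]
            base[give] += 1
        return base


@dataclass
class StimulusSchedule:
    """Time-ordered stimulus spikes: one (time, subpopulation) per element."""

    times_ms: np.ndarray
    subpops: np.ndarray
    duration_ms: float

    def __len__(self) -> int:
        return self.times_ms.size


def encode_task(task: SequenceTask, seed: int | None = None) -> StimulusSchedule:
    """Expand a task into the full training stimulus schedule."""
    rng = np.random.default_rng(seed) if task.order == "shuffled" else None
    times: list[float] = []
    pops: list[int] = []
    t = task.delta_T_seq  # lead-in before the first sequence
    for e in range(task.N_e):
        counts = task.episode_counts(e)
        order = [i for i, c in enumerate(counts) for _ in range(c)]
        if rng is not None:
            rng.shuffle(order)
        for si in order:
            seq = task.sequences[si]
            for j, sym in enumerate(seq):
                times.append(t + j * task.delta_T)
                pops.append(task.subpop_of_symbol(sym))
            t = t + (len(seq) - 1) * task.delta_T + task.delta_T_seq
    return StimulusSchedule(
        times_ms=np.asarray(times, dtype=float),
        subpops=np.asarray(pops, dtype=np.int32),
        duration_ms=t,
    )


# canonical task sets
TWO_SEQUENCE_TASK = (["A", "F", "B", "D", "C", "E"],
                     [["A", "F", "B", "D"], ["A", "F", "C", "E"]])
FIVE_SEQUENCE_TASK = (
    ["A", "F", "B", "D", "C", "E", "G", "H", "I", "J", "K", "L"],
    [["A", "F", "B", "D"], ["A", "F", "C", "E"], ["A", "F", "G", "H"],
     ["A", "F", "I", "J"], ["A", "F", "K", "L"]],
)


# ---------------------------------------------------------------------------
# background noise
# ---------------------------------------------------------------------------

@dataclass
class NoiseConfig:
    """Replay-phase background noise settings.

    ``kind`` is one of ``"none"``, ``"poisson"`` (correlated synaptic
    bombardment parameterized by amplitude ``sigma`` and correlation ``c``)
    or ``"oscillatory"`` (sinusoidal current with amplitude ``a`` and
    frequency ``f``; phases drawn per subpopulation).
    """

    kind: str = "none"
    sigma: float = 0.0          # pA, std of the Poisson background current
    c: float = 0.0              # within-subpopulation input correlation K/n
    nu: float = 1000.0          # 1/s, rate of each Poisson source
    K: int = 100                # background in-degree (K_EQ = K_EV)
    a: float = 0.0              # oscillation amplitude (units of J_EG)
    f: float = 30.0             # Hz, oscillation frequency

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson", "oscillatory"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if not 0.0 <= self.c <= 1.0:
            raise ValueError("correlation c must lie in [0, 1]")
        if self.f < 0:
            raise ValueError("oscillation frequency must be non-negative")

    @property
    def n_sources(self) -> int:
        """Pool size n per subpopulation; ``c = K/n``."""
        if self.c <= 0:
            return 0  # private independent sources per neuron
        n = int(round(self.K / self.c))
        if self.K > n:
            raise ValueError(f"c={self.c} requires pool size n={n} >= K={self.K}")
        return n


class PoissonBackground:
    """Stationary correlated background current generator.

    Supplies, per grid step, the increment that the pooled Poisson spikes
    add to the exponentially filtered background current of every
    excitatory neuron. Exact fast paths exist for ``c = 1`` (all neurons of
    a subpopulation share the whole pool) and ``c = 0`` (private sources);
    intermediate correlations use explicit source-subset assignments.
    """

    decays_in_simulator = True

    def __init__(self, params: ModelParams, cfg: NoiseConfig, seed) -> None:
        if cfg.kind != "poisson":
            raise ValueError("PoissonBackground requires kind='poisson'")
        self.cfg = cfg
        self.N_E = params.N_E
        self.M = params.M
        self.n_E = params.n_E
        self.dt = params.dt
        self.rng = np.random.default_rng(seed)
        nu_per_ms = cfg.nu / 1000.0
        self.J = (cfg.sigma / np.sqrt(cfg.K * nu_per_ms * params.tau_EQ)
                  if cfg.sigma > 0 else 0.0)
        # arrivals are locked to the grid and decay from the step boundary;
        # the half-step factor centres them mid-step so the sampled current
        # variance equals sigma^2 (to O((dt/tau)^2)) instead of losing dt/tau
        self.gain = self.J * np.exp(params.dt / (2.0 * params.tau_EQ))
        self.lam_source = nu_per_ms * params.dt  # expected spikes/source/step
        self.assign_exc = None
        self.assign_inh = None
        if cfg.sigma > 0 and 0.0 < cfg.c < 1.0:
            self._build_assignments()

    def _build_assignments(self) -> None:
        """Per-neuron source subsets for intermediate correlations (sparse)."""
        from scipy import sparse

        n = self.cfg.n_sources
        K = self.cfg.K
        mats = []
        for _ in range(2):  # excitatory then inhibitory pools
            rows, cols = [], []
            for i in range(self.N_E):
                pool0 = (i // self.n_E) * n
                picks = self.rng.choice(n, size=K, replace=False)
                rows.append(np.full(K, i))
                cols.append(pool0 + picks)
            mat = sparse.csr_matrix(
                (np.ones(self.N_E * K), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.N_E, self.M * n),
            )
            mats.append(mat)
        self.assign_exc, self.assign_inh = mats

    def source_sets(self, pool: str = "exc") -> list[np.ndarray]:
        """Source indices per neuron (for diagnostics); only for 0 < c < 1."""
        mat = self.assign_exc if pool == "exc" else self.assign_inh
        if mat is None:
            raise ValueError("explicit source sets exist only for 0 < c < 1")
        return [mat.indices[mat.indptr[i]:mat.indptr[i + 1]] for i in range(self.N_E)]

    def step_jumps(self) -> np.ndarray | None:
        """Current increments (pA) for all excitatory neurons this step."""
        cfg = self.cfg
        if cfg.sigma == 0:
            return None
        if cfg.c >= 1.0:
            n = cfg.n_sources
            counts = self.rng.poisson(n * self.lam_source, size=2 * self.M)
            per_pop = self.gain * (counts[: self.M] - counts[self.M:]).astype(float)
            return np.repeat(per_pop, self.n_E)
        if cfg.c == 0.0:
            counts = self.rng.poisson(cfg.K * self.lam_source, size=2 * self.N_E)
            return self.gain * (counts[: self.N_E] - counts[self.N_E:]).astype(float)
        n_tot = self.M * self.cfg.n_sources
        ce = self.rng.poisson(self.lam_source, size=n_tot).astype(float)
        ci = self.rng.poisson(self.lam_source, size=n_tot).astype(float)
        return self.gain * (self.assign_exc @ ce - self.assign_inh @ ci)


class OscillatoryBackground:
    """Sinusoidal background current with one random phase per subpopulation."""

    decays_in_simulator = False

    def __init__(self, params: ModelParams, cfg: NoiseConfig, seed) -> None:
        if cfg.kind != "oscillatory":
            raise ValueError("OscillatoryBackground requires kind='oscillatory'")
        self.cfg = cfg
        self.M = params.M
        self.n_E = params.n_E
        rng = np.random.default_rng(seed)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=params.M)
        self.amp = params.J_EG * cfg.a
        self.omega = 2.0 * np.pi * cfg.f / 1000.0  # rad per ms

    def current(self, t_ms: float) -> np.ndarray:
        """Background current (pA) of every excitatory neuron at time ``t``."""
        per_pop = self.amp * np.sin(self.omega * t_ms + self.phases)
        return np.repeat(per_pop, self.n_E)


def make_poisson_background(
    params: ModelParams, cfg: NoiseConfig, seed
) -> PoissonBackground:
    return PoissonBackground(params, cfg, seed)


def oscillatory_background(
    params: ModelParams, cfg: NoiseConfig, seed
) -> OscillatoryBackground:
    return OscillatoryBackground(params, cfg, seed)


def make_background(params: ModelParams, cfg: NoiseConfig | None, seed):
    """Instantiate the background generator named by ``cfg`` (or ``None``)."""
    if cfg is None or cfg.kind == "none":
        return None
    if params.mode == "training":
        raise ValueError(
            "background noise is a replay-phase ingredient; switch the "
            "parameters to replay mode (or inject it explicitly) first"
        )
    if cfg.kind == "poisson":
        return PoissonBackground(params, cfg, seed)
    return OscillatoryBackground(params, cfg, seed)


# ---------------------------------------------------------------------------
# cue schedule
# ---------------------------------------------------------------------------

def cue_schedule(
    N_t: int,
    policy: str = "fixed",
    seed=None,
    t0: float = 100.0,
    delta_T_cue: float = 200.0,
    u_min: float = 200.0,
    u_max: float = 400.0,
) -> np.ndarray:
    """Cue onset times for ``N_t`` replay trials.

    ``policy='fixed'`` spaces cues by ``delta_T_cue``; ``policy='uniform'``
    draws each inter-cue interval from ``U(u_min, u_max)`` (used with the
    oscillatory background so that the cue phase is random per trial).
    """
    if N_t < 1:
        raise ValueError("need at least one trial")
    if policy == "fixed":
        return t0 + delta_T_cue * np.arange(N_t)
    if policy == "uniform":
        if u_min > u_max:
            raise ValueError("u_min must not exceed u_max")
        rng = np.random.default_rng(seed)
        gaps = rng.uniform(u_min, u_max, size=N_t - 1)
        return t0 + np.concatenate([[0.0], np.cumsum(gaps)])
    raise ValueError(f"unknown cue policy {policy!r}")
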