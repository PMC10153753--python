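"""Deterministic miniature instances for tests and demos."""

from __future__ import annotations

from dataclasses import dataclass

from .inputs import FIVE_SEQUENCE_TASK, TWO_SEQUENCE_TASK, NoiseConfig, SequenceTask
from .network import Network, build_network
from .params import ModelParams, PlasticityParams

__all__ = ["make_fixture", "FIXTURES", "Fixture"]


@dataclass
class Fixture:
    name: str
    params: ModelParams
    net: Network
    task: SequenceTask
    noise: NoiseConfig | None = None


def _micro(seed: int) -> Fixture:
    """Two subpopulations of 10 neurons; runs end-to-end in well under a second."""
    params = ModelParams(N_E=20, M=2, rho=3, K_EE=10, K_EQ=4)
    net = build_network(params, seed)
    task = SequenceTask(["A", "B"], [["A", "B"]], [1.0], N_e=2, L=2)
    return Fixture("micro", params, net, task)


def _two_seq(seed: int) -> Fixture:
    """The two-sequence ambiguous-cue task at a reduced episode count."""
    params = ModelParams()
    net = build_network(params, seed)
    alphabet, seqs = TWO_SEQUENCE_TASK
    task = SequenceTask(alphabet, seqs, [1 / 3, 2 / 3], N_e=5, L=10)
    noise = NoiseConfig(kind="poisson", sigma=20.0, c=1.0)
    return Fixture("two-seq", params, net, task, noise)


def _five_seq(seed: int) -> Fixture:
    """The five-sequence task (twelve subpopulations) at reduced size."""
    params = ModelParams(
        N_E=1800, M=12, K_EE=360,
        plasticity=PlasticityParams(z_star=21.0, tau_h=4620.0),
    )
    net = build_network(params, seed)
    alphabet, seqs = FIVE_SEQUENCE_TASK
    task = SequenceTask(alphabet, seqs, [0.1, 0.14, 0.2, 0.23, 0.33], N_e=5, L=10)
    noise = NoiseConfig(kind="poisson", sigma=12.0, c=1.0)
    return Fixture("five-seq", params, net, task, noise)


FIXTURES = {"micro": _micro, "two-seq": _two_seq, "five-seq": _five_seq}


def make_fixture(name: str, seed: int = 0) -> Fixture:
    """Build a registered fixture; identical (name, seed) gives identical output."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(FIXTURES)}") from None
    return builder(seed)
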