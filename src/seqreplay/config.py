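"""Structured YAML configuration mirroring the model parameter names.

A config file has up to four sections::

    model:       {N_E: 900, M: 6, K_EE: 180, tau_m_E: 10.0, ...}
    plasticity:  {lambda_plus: 0.0009, J_max: 35.0, ...}
    task:        {alphabet: [...], sequences: [...], probs: [...], ...}
    noise:       {kind: poisson, sigma: 20.0, c: 1.0, ...}

Unknown keys are rejected, as are attempts to set derived quantities
(``n_E``, ``J_EQ``, the connection probability, ...) whose values follow
from other parameters. All values are plain numbers in the fixed units of
the model (ms, mV, pA, pF).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .inputs import NoiseConfig, SequenceTask
from .params import ModelParams, PlasticityParams

__all__ = ["load_config", "save_config", "Configuration"]

_DERIVED = {
    "n_E": "N_E / M",
    "p": "K_EE / N_E",
    "K_EI": "N_I",
    "K_IE": "N_E",
    "K_II": "0 (no I->I connections)",
    "J_EQ": "sigma / sqrt(K_EQ * nu * tau_EQ)",
    "J_EV": "-J_EQ",
    "tau_EV": "tau_EQ",
    "d_EV": "d_EQ",
    "theta_E": "theta_E_train / theta_E_replay via mode",
    "R_m_E": "tau_m_E / C_m",
    "R_m_I": "tau_m_I / C_m",
    "n": "K_EQ / c",
}

_SECTIONS = ("model", "plasticity", "task", "noise")


@dataclasses.dataclass
class Configuration:
    model: ModelParams
    task: SequenceTask | None = None
    noise: NoiseConfig | None = None


def _check_keys(section: str, given: dict, cls) -> None:
    allowed = {f.name for f in dataclasses.fields(cls)}
    for key in given:
        if key in _DERIVED:
            raise KeyError(
                f"config key '{key}' in section '{section}' is derived "
                f"({_DERIVED[key]}) and cannot be set directly"
            )
        if key not in allowed:
            raise KeyError(f"unknown config key '{key}' in section '{section}'")


def load_config(path) -> Configuration:
    """Parse and validate a configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise KeyError(f"unknown config section(s): {sorted(unknown)}")

    model_d = dict(raw.get("model", {}))
    plast_d = dict(raw.get("plasticity", {}))
    _check_keys("model", model_d, ModelParams)
    _check_keys("plasticity", plast_d, PlasticityParams)
    model = ModelParams(plasticity=PlasticityParams(**plast_d), **model_d)

    task = None
    if "task" in raw:
        task_d = dict(raw["task"])
        _check_keys("task", task_d, SequenceTask)
        task = SequenceTask(**task_d)

    noise = None
    if "noise" in raw:
        noise_d = dict(raw["noise"])
        _check_keys("noise", noise_d, NoiseConfig)
        noise = NoiseConfig(**noise_d)
    return Configuration(model, task, noise)


def save_config(cfg: Configuration, path) -> None:
    """Write a configuration that :func:`load_config` parses back identically."""
    out: dict = {}
    md = cfg.model.to_dict()
    out["plasticity"] = md.pop("plasticity")
    out["model"] = md
    if cfg.task is not None:
        out["task"] = dataclasses.asdict(cfg.task)
    if cfg.noise is not None:
        out["noise"] = dataclasses.asdict(cfg.noise)
    Path(path).write_text(yaml.safe_dump(out, sort_keys=True))
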