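"""Run configuration: YAML/JSON files with strict schema validation."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .inference import MCMC_PRESETS, McmcSettings, ModelConfig
from .simulator import SimulationScenario

__all__ = ["RunConfig", "load_config"]

_SCENARIO_KEYS = {f.name for f in dataclasses.fields(SimulationScenario)}
_MCMC_KEYS = {f.name for f in dataclasses.fields(McmcSettings)}
_MODEL_KEYS = {
    "variant", "share_detection", "n_upper_bound", "litter_size_max",
    "repro_conditional_on_detection",
}
_TOP_KEYS = {"scenario", "model", "mcmc", "preset", "seed"}


@dataclass
class RunConfig:
    """Validated configuration for one CLI run."""

    scenario: SimulationScenario = field(default_factory=SimulationScenario)
    model: ModelConfig = field(default_factory=ModelConfig)
    seed: int = 0


def _reject_unknown(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        key = sorted(unknown)[0]
        where = f"{section}.{key}" if section else key
        raise ValueError(f"unknown configuration key {where!r}")


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML or JSON run configuration.

    Unknown keys are rejected (with the offending key path) rather than
    ignored; a missing file section falls back to defaults, with the "desk"
    MCMC preset unless ``preset`` or ``mcmc`` says otherwise.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    _reject_unknown("", raw, _TOP_KEYS)

    cfg_seed = int(raw.get("seed", 0)) if seed is None else int(seed)

    scen_raw = dict(raw.get("scenario") or {})
    _reject_unknown("scenario", scen_raw, _SCENARIO_KEYS)
    if "initial_abundance" in scen_raw:
        scen_raw["initial_abundance"] = np.asarray(scen_raw["initial_abundance"])
    if "harvest_rates" in scen_raw:
        scen_raw["harvest_rates"] = np.asarray(scen_raw["harvest_rates"])
    scen_raw.setdefault("seed", cfg_seed)
    scenario = SimulationScenario(**scen_raw)

    preset = raw.get("preset", "desk")
    if preset not in MCMC_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(MCMC_PRESETS)}")
    mcmc_raw = dict(raw.get("mcmc") or {})
    _reject_unknown("mcmc", mcmc_raw, _MCMC_KEYS)
    mcmc_kwargs = dict(MCMC_PRESETS[preset], seed=cfg_seed)
    mcmc_kwargs.update(mcmc_raw)
    mcmc = McmcSettings(**mcmc_kwargs)

    model_raw = dict(raw.get("model") or {})
    _reject_unknown("model", model_raw, _MODEL_KEYS)
    model = ModelConfig(mcmc=mcmc, **model_raw)
    return RunConfig(scenario=scenario, model=model, seed=cfg_seed)
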