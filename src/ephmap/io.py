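"""Configuration handling and result serialization."""

from __future__ import annotations

import dataclasses
import datetime
import json
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .model import ModelParams, SimulationResult
from .scenarios import (
    ConfigurationError,
    Scenario,
    gap_assay_scenario,
    innervation_scenario,
    knockin_scenario,
    mapping_scenario,
    tectal_entry_scenario,
)

__all__ = [
    "scenario_from_config",
    "load_config",
    "list_bundled_configs",
    "load_bundled_config",
    "write_result_csv",
    "write_manifest",
]

_BUILDERS = {
    "mapping": mapping_scenario,
    "gap_assay": gap_assay_scenario,
    "tectal_entry": tectal_entry_scenario,
    "knockin": knockin_scenario,
    "innervation": innervation_scenario,
}


def scenario_from_config(cfg: Dict) -> Scenario:
    """Build a scenario from a config mapping.

    Two forms are accepted: ``{"builder": name, "args": {...}}`` invoking a
    named builder, or a full structural dump (``Scenario.to_dict`` output)
    under the key ``"scenario"``.  Optional top-level ``"params"`` entries
    are merged into the scenario's parameter overrides.
    """
    if "scenario" in cfg:
        scn = Scenario.from_dict(cfg["scenario"])
    elif "builder" in cfg:
        name = cfg["builder"]
        if name not in _BUILDERS:
            raise ConfigurationError(
                f"unknown builder {name!r}; valid: {sorted(_BUILDERS)}"
            )
        scn = _BUILDERS[name](**cfg.get("args", {}))
    else:
        raise ConfigurationError("config needs a 'builder' or 'scenario' key")
    extra = cfg.get("params", {})
    valid = {f.name for f in dataclasses.fields(ModelParams)}
    bad = set(extra) - valid
    if bad:
        raise ConfigurationError(f"unknown parameter overrides: {sorted(bad)}")
    scn.params_overrides.update(extra)
    return scn


def load_config(path) -> Scenario:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    return scenario_from_config(cfg)


def list_bundled_configs() -> List[str]:
    root = resources.files("ephmap") / "configs"
    return sorted(p.name for p in root.iterdir() if p.name.endswith(".yaml"))


def load_bundled_config(name: str) -> Scenario:
    if not name.endswith(".yaml"):
        name += ".yaml"
    root = resources.files("ephmap") / "configs"
    entry = root / name
    if not entry.is_file():
        raise ConfigurationError(
            f"no bundled config {name!r}; available: {list_bundled_configs()}"
        )
    return scenario_from_config(yaml.safe_load(entry.read_text()))


def write_result_csv(result: SimulationResult, path) -> None:
    result.to_frame().to_csv(path, index=False, float_format="%.10g")


def write_manifest(
    result: SimulationResult,
    path,
    outputs: Optional[Dict[str, str]] = None,
) -> None:
    """JSON manifest sufficient to reproduce the run bit-identically."""
    manifest = {
        "scenario_tag": result.scenario_tag,
        "params": dataclasses.asdict(result.params),
        "seed": result.params.seed,
        "n_terminals": result.n_terminals,
        "analysis_hints": result.analysis_hints,
        "code_version": __version__,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "outputs": outputs or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
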