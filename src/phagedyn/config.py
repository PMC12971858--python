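"""YAML/JSON round-tripping of parameter sets, distributions and scenarios."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .distributions import LatentDistribution, build_distribution
from .kinetics import KineticParameters
from .scenarios import ScenarioSpec

__all__ = [
    "load_config",
    "dump_config",
    "kinetics_from_config",
    "distribution_from_config",
    "scenario_from_config",
]


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(obj, path) -> None:
    path = Path(path)
    if hasattr(obj, "to_dict"):
        obj = obj.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(obj, indent=2))
    else:
        path.write_text(yaml.safe_dump(obj, sort_keys=False))


def kinetics_from_config(cfg: dict) -> KineticParameters:
    sub = cfg.get("kinetics", cfg)
    fields = KineticParameters.__dataclass_fields__
    return KineticParameters(
        **{k: float(v) for k, v in sub.items() if k in fields}
    )


def distribution_from_config(cfg: dict) -> LatentDistribution:
    sub = cfg.get("distribution", cfg)
    return build_distribution(
        sub["family"],
        float(sub["tau_0"]),
        float(sub["rsd_tau"]),
        float(sub.get("tau_min", 0.0)),
    )


def scenario_from_config(cfg: dict) -> ScenarioSpec:
    sub = cfg.get("scenario", cfg)
    return ScenarioSpec(
        label=sub["label"],
        dist=distribution_from_config(sub["dist"]),
        burst_mode=sub.get("burst_mode", "latent-dependent"),
    )
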