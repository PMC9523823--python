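"""Structured configuration files and run manifests.

A run configuration is YAML/JSON with either a ``scenario`` preset name (plus
optional ``sub_scenario`` and field overrides) or a full inline parameter set.
Every CLI run emits a manifest recording the resolved configuration, master
seed, package version, timestamps and output digests, so deterministic steps
can be reproduced byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from .dgm import ConfounderBlock, ScenarioConfig, ConfigError
from .scenarios import get_scenario

__all__ = ["load_config", "dump_config", "config_to_dict", "RunManifest"]


def config_to_dict(cfg: ScenarioConfig) -> dict:
    d = asdict(cfg)

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        return obj

    return clean(d)


def _build(data: dict) -> ScenarioConfig:
    data = dict(data)
    name = data.pop("scenario", None)
    sub = data.pop("sub_scenario", "DE+IE")
    block = data.pop("confounder_block", None)
    if block is not None and not isinstance(block, ConfounderBlock):
        block = ConfounderBlock(
            **{
                k: tuple(map(tuple, v)) if k == "Sigma_L" else (tuple(v) if isinstance(v, list) else v)
                for k, v in block.items()
            }
        )
    for key in ("p_Z0_given_A", "mediator_re_mean", "beta_A_schedule",
                "alpha_M_schedule", "analysis_visits"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    if "mediator_re_cov" in data and isinstance(data["mediator_re_cov"], list):
        data["mediator_re_cov"] = tuple(map(tuple, data["mediator_re_cov"]))
    if name is not None:
        if block is not None:
            data["confounder_block"] = block
        return get_scenario(name, sub_scenario=sub, **data)
    valid_fields = {f.name for f in dataclasses.fields(ScenarioConfig)}
    unknown = set(data) - valid_fields
    if unknown:
        raise ConfigError(f"unknown configuration field(s): {sorted(unknown)}")
    return ScenarioConfig(
        sub_scenario=sub, confounder_block=block, **data
    ).validate()


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario configuration (YAML or JSON)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return _build(data)


def dump_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


@dataclasses.dataclass
class RunManifest:
    command: str
    config: dict
    master_seed: int
    version: str
    started: float = dataclasses.field(default_factory=time.time)
    finished: float | None = None
    outputs: dict = dataclasses.field(default_factory=dict)

    def record_output(self, path) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        self.outputs[str(p)] = digest

    def write(self, path) -> None:
        self.finished = time.time()
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
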