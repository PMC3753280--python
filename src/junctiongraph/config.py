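"""Run configuration: seed, scaling-parameter overrides, conventions."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .builder import DEFAULT_PARAMETERS, ScalingParameters

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ScalingParameters)}


@dataclass
class RunConfig:
    seed: int = 0
    params: ScalingParameters = DEFAULT_PARAMETERS
    annotation: str = "auto"  # "auto" (geometric detection) or "table"
    outdir: str = "."

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "annotation": self.annotation,
            "outdir": self.outdir,
            "params": dataclasses.asdict(self.params),
        }


def load_config(path) -> RunConfig:
    """Key=value config file; scaling-parameter names override defaults."""
    cfg = RunConfig()
    overrides = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        if "=" not in ln:
            raise ValueError(f"config line must be key=value: {ln!r}")
        key, value = (x.strip() for x in ln.split("=", 1))
        if key == "seed":
            cfg.seed = int(value)
        elif key == "annotation":
            cfg.annotation = value
        elif key == "outdir":
            cfg.outdir = value
        elif key in _PARAM_FIELDS:
            overrides[key] = float(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if overrides:
        cfg.params = dataclasses.replace(DEFAULT_PARAMETERS, **overrides)
    return cfg
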