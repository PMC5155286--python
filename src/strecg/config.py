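"""Structured run configuration: YAML file + flag overrides, echoed to output.

A run is reproducible from its echoed config and seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Validated configuration for simulation / inversion runs."""

    # geometry
    nodes: int = 184
    r_inner: float = 1.0
    r_outer: float = 1.5
    dt_ms: float = 1.0
    # solver
    method: str = "stre"            # stre | tikh0 | tikh1 | l1_1st
    lam: float = 1e-3               # baseline penalty weight
    lambda_s: float = 0.015
    lambda_t: float = 0.5
    window: int = 2
    stre_solver: str = "direct"     # direct | mu
    max_iter: int = 5000
    tol: float = 1e-8
    # noise / replication
    noise_levels: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
    replicates: int = 20
    seed: int = 0
    # output
    out_dir: str = "strecg-run"
    verbosity: int = 1

    def __post_init__(self):
        if self.method not in ("stre", "tikh0", "tikh1", "l1_1st"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.stre_solver not in ("direct", "mu"):
            raise ValueError(f"unknown stre_solver {self.stre_solver!r}")
        if not 1 <= self.window:
            raise ValueError("window must be >= 1")
        if self.nodes < 4 or self.dt_ms <= 0 or self.replicates < 1:
            raise ValueError("invalid geometry/replication settings")
        if any(s < 0 for s in self.noise_levels):
            raise ValueError("noise levels must be nonnegative")
        self.noise_levels = tuple(float(s) for s in self.noise_levels)


_FIELDS = {f.name: f for f in fields(RunConfig)}


def parse_config(path=None, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from an optional YAML file plus overrides.

    Flags (overrides) win over file values.  Unknown keys and type
    mismatches raise with the offending key named.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    for key, value in data.items():
        if key not in _FIELDS:
            raise ValueError(f"unknown config key: {key!r}")
        want = _FIELDS[key].type
        if want in ("int",) and not isinstance(value, int):
            raise TypeError(f"config key {key!r} must be an integer, got {value!r}")
        if want in ("float",) and not isinstance(value, (int, float)):
            raise TypeError(f"config key {key!r} must be a number, got {value!r}")
    return RunConfig(**data)


def echo_config(config: RunConfig, directory) -> Path:
    """Write the fully-resolved config into the run's output directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "config.yaml"
    payload = asdict(config)
    payload["noise_levels"] = list(config.noise_levels)
    with open(out, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return out
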