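"""Run configuration for the end-to-end workflow.

A :class:`RunConfig` collects every knob of the pipeline (grids, realization
count, seeds, thresholds) and can be loaded from YAML with ``--set key=value``
overrides.  Two presets exist: ``full`` (radius step 1, N step 0.1, five
realizations, 36 cases) and ``coarse`` (radius step 10, N step 5, two
realizations, 12 cases) for quick runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .metrics import SCENARIOS, VALUE_KINDS
from .search import COARSE_N_GRID, COARSE_RADII, DEFAULT_N_GRID, DEFAULT_RADII


@dataclass
class RunConfig:
    cohort_dir: str = "cohort"
    out_dir: str = "out"
    iso_mm: float = 2.0
    radii: tuple = DEFAULT_RADII
    n_grid: tuple = DEFAULT_N_GRID
    scenarios: tuple = SCENARIOS
    value_kinds: tuple = VALUE_KINDS
    n_realizations: int = 5
    base_seed: int = 0
    top_k: int = 5
    dlco_threshold: float = 60.0
    fev1_threshold: float = 70.0
    fev1_fvc_threshold: float = 70.0
    subset_cap: int | None = None
    n_cases: int = 36
    preset: str = "full"

    def validate(self) -> None:
        if not self.radii or not self.n_grid:
            raise ValueError("radius and N grids must be nonempty")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        for t in (self.dlco_threshold, self.fev1_threshold, self.fev1_fvc_threshold):
            if t <= 0:
                raise ValueError("classification thresholds must be positive")

    def resolved(self) -> dict:
        d = asdict(self)
        for key in ("radii", "n_grid", "scenarios", "value_kinds"):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def coarse_preset(**overrides) -> RunConfig:
    cfg = RunConfig(
        radii=COARSE_RADII,
        n_grid=COARSE_N_GRID,
        n_realizations=2,
        n_cases=12,
        preset="coarse",
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def _coerce(value: str):
    try:
        return json.loads(value)
    except json.JSONDecodeError:
        return value


def load_config(path=None, preset: str = "full", sets: tuple[str, ...] = ()) -> RunConfig:
    """Build a RunConfig from an optional YAML file, a preset and overrides."""
    cfg = coarse_preset() if preset == "coarse" else RunConfig()
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, tuple(value) if isinstance(value, list) else value)
    for item in sets:
        if "=" not in item:
            raise ValueError(f"--set expects key=value, got {item!r}")
        key, _, value = item.partition("=")
        if not hasattr(cfg, key):
            raise ValueError(f"unknown config key {key!r}")
        parsed = _coerce(value)
        setattr(cfg, key, tuple(parsed) if isinstance(parsed, list) else parsed)
    cfg.validate()
    return cfg


__all__ = ["RunConfig", "coarse_preset", "load_config"]
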