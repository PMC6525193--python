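"""YAML run configuration, validation and output manifests.

One structured-text dialect (schema version 1) describes everything a run
needs: fe overrides for the reaction network, kinetic parameter sets, the
column grid/schedule, and module-specific blocks.  Validation is strict —
unknown keys are reported by name — and every run directory receives a
manifest recording the config hash, seed and library versions so results
can be reproduced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from .batch import KineticParams

SCHEMA_VERSION = 1

_TOP_KEYS = {
    "schema_version",
    "seed",
    "units",
    "fe_overrides",
    "kinetics",
    "grid",
    "schedule",
    "batch",
    "fitting",
    "mechanism",
    "synth",
}
_KINETICS_KEYS = {"mu_max", "K_d", "K_a", "I", "b", "X0"}
_GRID_KEYS = {
    "length_cm",
    "n_cells",
    "diameter_cm",
    "porosity",
    "dispersivity_cm",
    "molecular_diffusion_m2_s",
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int = 0
    units: str = "mM"  # preferred display unit: mM | mg/l
    fe_overrides: dict[str, float] = field(default_factory=dict)
    kinetics: dict[str, KineticParams] = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    schedule: list = field(default_factory=list)
    batch: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    mechanism: dict = field(default_factory=dict)
    synth: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "units": self.units,
            "fe_overrides": dict(self.fe_overrides),
            "kinetics": {
                k: {a: b for a, b in asdict(v).items() if b is not None}
                for k, v in self.kinetics.items()
            },
            "grid": dict(self.grid),
            "schedule": [list(s) for s in self.schedule],
            "batch": dict(self.batch),
            "fitting": dict(self.fitting),
            "mechanism": dict(self.mechanism),
            "synth": dict(self.synth),
        }
        return d


def _check_keys(mapping: dict, allowed: set[str], where: str):
    unknown = sorted(set(mapping) - allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(unknown)}")


def parse_config(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config root")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"unsupported schema_version {version}")
    units = raw.get("units", "mM")
    if units not in ("mM", "mg/l"):
        raise ConfigError(f"units must be 'mM' or 'mg/l', got {units!r}")
    kinetics = {}
    for name, block in (raw.get("kinetics") or {}).items():
        _check_keys(block, _KINETICS_KEYS, f"kinetics.{name}")
        try:
            kinetics[name] = KineticParams(**block)
        except (TypeError, ValueError) as e:
            raise ConfigError(f"kinetics.{name}: {e}") from None
    grid = raw.get("grid") or {}
    _check_keys(grid, _GRID_KEYS, "grid")
    schedule = raw.get("schedule") or []
    for i, step in enumerate(schedule):
        if len(step) != 3:
            raise ConfigError(f"schedule[{i}] must be [t_start_days, flow_ml_h, influent]")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        units=units,
        fe_overrides={k: float(v) for k, v in (raw.get("fe_overrides") or {}).items()},
        kinetics=kinetics,
        grid=grid,
        schedule=[tuple(s) for s in schedule],
        batch=raw.get("batch") or {},
        fitting=raw.get("fitting") or {},
        mechanism=raw.get("mechanism") or {},
        synth=raw.get("synth") or {},
    )


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file {path} does not exist")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return parse_config(raw)


def write_config(cfg: RunConfig, path: str | Path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir: str | Path, cfg: RunConfig | None = None, **extra):
    """Record how a run was produced (config hash, seed, versions)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "soursim": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        **extra,
    }
    if cfg is not None:
        manifest["config_hash"] = config_hash(cfg)
        manifest["seed"] = cfg.seed
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def write_tidy_csv(df: pd.DataFrame, path: str | Path, unit_columns: dict[str, str] | None = None):
    """Write a tidy table, renaming value columns to carry their units."""
    if unit_columns:
        df = df.rename(columns=unit_columns)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
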