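"""Declarative run configuration: schema, validation, and artifact writing.

A run config (YAML or JSON) names the designs, the scenarios with their
correlations, and the Monte Carlo settings; :func:`run_from_config`
validates it, simulates the full design x scenario sweep, and writes
boundary tables, the operating-characteristics table, and a manifest
(seed, package versions, config hash) so a run is reproducible and
auditable.  Every CSV carries the config hash and seed in a header comment.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .cohort import AccrualModel, ObservationWindows
from .designs import DESIGN_KINDS, make_design
from .engine import scenario_sweep
from .scenarios import OutcomeScenario, reference_scenarios

__all__ = ["RunConfig", "ConfigError", "load_config", "run_from_config"]

logger = logging.getLogger("toptrial")


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    p_eff: float = Field(ge=0.0, le=1.0)
    p_tox: float = Field(ge=0.0, le=1.0)
    r: float | str = 0.0
    label: str = ""


class RunConfig(BaseModel):
    """Validated sweep configuration."""

    model_config = ConfigDict(extra="forbid")

    designs: list[str] = Field(min_length=1)
    scenarios: list[ScenarioConfig] | Literal["reference"] = "reference"
    r_preset: float | str = "pos1"  # correlation for "reference" scenarios
    reps: int = Field(ge=1)
    seed: int
    out_dir: str = "toptrial-results"
    mean_interarrival: float = Field(default=6.0, gt=0.0)
    accrual_mode: Literal["exponential", "fixed"] = "exponential"
    t_eff: float = Field(default=180.0, gt=0.0)
    t_tox: float = Field(default=42.0, gt=0.0)

    def model_post_init(self, __context) -> None:
        unknown = [k for k in self.designs if k not in DESIGN_KINDS]
        if unknown:
            raise ValueError(
                f"unknown design kinds {unknown}; choose from {DESIGN_KINDS}")

    def resolved_scenarios(self) -> list[OutcomeScenario]:
        if self.scenarios == "reference":
            return reference_scenarios(self.r_preset)
        return [OutcomeScenario.from_dict(s.model_dump())
                for s in self.scenarios]


def _canonical_hash(data: dict) -> str:
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    Raises :class:`ConfigError` naming the offending field on schema
    violations.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must hold a mapping")
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        fields = sorted({".".join(str(p) for p in err["loc"]) or "<root>"
                         for err in exc.errors()})
        raise ConfigError(
            f"invalid configuration {path}: problem with field(s) "
            f"{', '.join(fields)}\n{exc}") from exc


def _write_csv(df: pd.DataFrame, path: Path, config_hash: str,
               seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# toptrial config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh, index=False)


def run_from_config(path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Execute the sweep described by a config file; return the output dir.

    Writes, under the output directory:

    * ``boundaries_<design>_{efficacy,toxicity}.csv`` -- decision boundaries;
    * ``operating_characteristics.csv`` -- the long-format sweep table;
    * ``manifest.json`` -- seed, config hash, package/library versions.

    The run is deterministic given the config's seed: re-running writes
    byte-identical CSVs.
    """
    config = load_config(path)
    config_dict = config.model_dump()
    config_hash = _canonical_hash(config_dict)
    out = Path(out_dir) if out_dir is not None else Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    designs = [make_design(kind) for kind in config.designs]
    scenarios = config.resolved_scenarios()
    accrual = AccrualModel(mean_interarrival=config.mean_interarrival,
                           mode=config.accrual_mode)
    windows = ObservationWindows(t_eff=config.t_eff, t_tox=config.t_tox)

    for design in designs:
        _write_csv(design.efficacy_boundaries().frame,
                   out / f"boundaries_{design.kind}_efficacy.csv",
                   config_hash, config.seed)
        if design.tox_rule is not None:
            _write_csv(design.toxicity_boundaries().frame,
                       out / f"boundaries_{design.kind}_toxicity.csv",
                       config_hash, config.seed)

    logger.info("sweep: %d designs x %d scenarios, %d replicates",
                len(designs), len(scenarios), config.reps)
    table = scenario_sweep(designs, scenarios, reps=config.reps,
                           seed=config.seed, accrual=accrual, windows=windows)
    _write_csv(table, out / "operating_characteristics.csv",
               config_hash, config.seed)

    manifest = {
        "config": config_dict,
        "config_hash": config_hash,
        "seed": config.seed,
        "toptrial_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True, default=str))
    return out
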