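"""Run configuration (TOML) and reproducibility manifests.

Every declared default that fills a protocol gap (schedule lengths, RH
grid, electrostatics parameters, barostat time constant, HB convention)
is surfaced as a config key so it is visible and overridable; seeds are
explicit — there is no silent time-based seeding anywhere in the package.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .energy import NonbondedSettings
from .hbonds import HBCriterion
from .model import InvalidInputError
from .sorption import DEFAULT_RH_GRID, ScheduleSpec


@dataclass
class RunConfig:
    # host build
    n_chains: int = 3
    units_per_chain: int = 10
    target_density: float = 1.2
    forcefield: str = "surrogate_host"
    # ensemble / reservoir
    T: float = 300.0
    sigma_ext: list = field(default_factory=lambda: [0.0, 0.0, 0.0])  # Pa
    rh_grid: list = field(default_factory=lambda: list(DEFAULT_RH_GRID))
    # schedule
    gcmc_moves_per_block: int = 2000
    md_steps_per_block: int = 1000
    max_blocks: int = 60
    group: int = 10
    tol: float = 0.02
    production_blocks: int = 10
    dt: float = 0.001
    # nonbonded
    cutoff: float = 0.9
    dsf_alpha: float = 0.0
    # HB criterion
    hb_d_max: float = 0.35
    hb_angle_max: float = 30.0
    hb_distance_convention: str = "O_to_O"
    hb_angle_convention: str = "donor"
    # seeds & paths
    seed: int = 1
    n_realizations: int = 3
    input_structure: str = ""
    output_dir: str = "."

    def validate(self):
        if self.seed is None:
            raise InvalidInputError("an explicit seed is required")
        if self.input_structure and not Path(self.input_structure).exists():
            raise InvalidInputError(
                f"input structure not found: {self.input_structure}")
        if not all(0.0 <= r <= 1.0 for r in self.rh_grid):
            raise InvalidInputError("RH grid values must lie in [0, 1]")
        return self

    # -- views ----------------------------------------------------------
    def schedule(self, **overrides) -> ScheduleSpec:
        import numpy as np
        kw = dict(gcmc_moves_per_block=self.gcmc_moves_per_block,
                  md_steps_per_block=self.md_steps_per_block,
                  max_blocks=self.max_blocks, group=self.group,
                  tol=self.tol, production_blocks=self.production_blocks,
                  dt=self.dt, T=self.T,
                  sigma_ext=np.asarray(self.sigma_ext, float),
                  hb_criterion=self.hb_criterion())
        kw.update(overrides)
        return ScheduleSpec(**kw)

    def nonbonded(self) -> NonbondedSettings:
        return NonbondedSettings(cutoff=self.cutoff, dsf_alpha=self.dsf_alpha)

    def hb_criterion(self) -> HBCriterion:
        return HBCriterion(d_max=self.hb_d_max, angle_max=self.hb_angle_max,
                           distance_convention=self.hb_distance_convention,
                           angle_convention=self.hb_angle_convention)


def load_config(path) -> RunConfig:
    """Load a TOML config; unknown keys are rejected (typo safety)."""
    doc = tomllib.loads(Path(path).read_text())
    flat = {}
    for key, val in doc.items():
        if isinstance(val, dict):
            flat.update(val)
        else:
            flat[key] = val
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(flat) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**flat).validate()


def write_manifest(out_dir, config_path=None, seeds=None, extras=None):
    """Emit a reproducibility manifest next to run outputs."""
    from . import __version__
    from .forcefield import load_forcefield
    man = {
        "code_version": __version__,
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "seeds": seeds or [],
    }
    if config_path and Path(config_path).exists():
        man["config_sha256"] = hashlib.sha256(
            Path(config_path).read_bytes()).hexdigest()
        man["config_path"] = str(config_path)
    for name in ("spce", "surrogate_host"):
        man[f"forcefield_{name}_checksum"] = load_forcefield(name).checksum
    man.update(extras or {})
    out = Path(out_dir) / "manifest.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(man, indent=2, default=str))
    return out
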