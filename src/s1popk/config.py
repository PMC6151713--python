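"""Declarative run configuration (TOML: key = value sections, no code execution)."""

from __future__ import annotations

import hashlib
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

from . import reference

__all__ = ["RunConfig", "SimulationConfig", "NcaConfig", "FitConfig",
           "DiagnosticsConfig", "load_config", "config_hash"]


def _from_mapping(cls, data: Mapping[str, Any], section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in [{section}]: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


@dataclass
class SimulationConfig:
    n_per_group: int = 5
    n_iv: int = 0
    dose: float = reference.TEGAFUR_DOSE
    iv_dose: float = reference.IV_5FU_DOSE
    include_gimeracil: bool = False
    bsv_is_sd: bool = False


@dataclass
class NcaConfig:
    welch: bool = False
    gimeracil_dose: float = reference.GIMERACIL_DOSE
    alpha: float = 0.05


@dataclass
class FitConfig:
    n_importance: int = 300
    max_iter: int = 100
    tol: float = 1e-4
    group_params: list[str] = field(
        default_factory=lambda: ["ka", "ka_met", "cl_5fu"]
    )
    bsv_params: list[str] = field(default_factory=list)  # empty = all
    estimate_residual: bool = True


@dataclass
class DiagnosticsConfig:
    n_sim_vpc: int = 200
    n_sim_npde: int = 1000


@dataclass
class RunConfig:
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    nca: NcaConfig = field(default_factory=NcaConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    diagnostics: DiagnosticsConfig = field(default_factory=DiagnosticsConfig)
    source: str = ""  # path of the file this was loaded from, if any


_SECTIONS = {
    "simulation": SimulationConfig,
    "nca": NcaConfig,
    "fit": FitConfig,
    "diagnostics": DiagnosticsConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a TOML run configuration; unknown keys are rejected."""
    raw = tomllib.loads(Path(path).read_text())
    kwargs: dict[str, Any] = {"source": str(path)}
    for key, value in raw.items():
        if key == "seed":
            kwargs["seed"] = int(value)
        elif key in _SECTIONS:
            kwargs[key] = _from_mapping(_SECTIONS[key], value, key)
        else:
            raise ValueError(f"unknown top-level key {key!r}")
    return RunConfig(**kwargs)


def config_hash(path: str | Path | None) -> str:
    """Stable identifier of the configuration file contents ('' if none)."""
    if path is None or str(path) == "":
        return ""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
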