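"""Run configuration: one validated record tying all engines together.

A :class:`RunConfig` bundles the material constants, size law, thermal
environment, excitation protocol, demodulation grid and Monte Carlo
dimensions, with defaults matching the magnetite/nanomag-D reference
parameter set.  Configs load from and save to YAML; cross-field
consistency (e.g. an integer tone ratio for demodulation runs) is
checked at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .ensemble import Environment, MagneticMaterial, SizeDistribution
from .langevin import DemodGrid, ExcitationProtocol
from .micromag import SimulationConfig

__all__ = ["RunConfig", "load_config", "save_config"]

_SECTIONS = {
    "material": MagneticMaterial,
    "distribution": SizeDistribution,
    "environment": Environment,
    "protocol": ExcitationProtocol,
    "demod_grid": DemodGrid,
    "mc": SimulationConfig,
}

_DEFAULTS = {
    "material": dict(Ms=476e3, K=11e3, alpha=1.0, tau0=1e-9, rho=5200.0),
    "distribution": dict(d0=7.81e-9, sigma=0.346, Np=1.0),
    "environment": dict(T=300.0, eta=8.9e-4, dh=20e-9),
    "protocol": dict(H0=0.0, H1=1e-3, f1=40000.0, H2=16e-3, f2=2000.0, T_sample=300.0),
    "demod_grid": dict(steps_per_hf_period=10, ratio=20),
    "mc": dict(),
}


@dataclass
class RunConfig:
    material: MagneticMaterial
    distribution: SizeDistribution
    environment: Environment
    protocol: ExcitationProtocol
    demod_grid: DemodGrid
    mc: SimulationConfig
    seed: int = 0

    def validate_for_demod(self) -> None:
        """Demodulation runs need an integer physical tone ratio."""
        ratio = self.protocol.f1 / self.protocol.f2
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"f1/f2 = {ratio:g} is not an integer; demodulation windows "
                "would not close on a common period"
            )

    def to_dict(self) -> dict:
        out = {name: asdict(getattr(self, name)) for name in _SECTIONS}
        out["seed"] = self.seed
        return out


def _build(name: str, data: dict) -> object:
    cls = _SECTIONS[name]
    merged = dict(_DEFAULTS[name])
    unknown = set(data) - set(cls.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
    merged.update(data)
    return cls(**merged)


def load_config(path: str | Path | dict) -> RunConfig:
    """Load and validate a YAML config; omitted fields take the defaults."""
    if isinstance(path, dict):
        raw = path
    else:
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    sections = {name: _build(name, raw.get(name, {})) for name in _SECTIONS}
    return RunConfig(seed=int(raw.get("seed", 0)), **sections)


def save_config(config: RunConfig, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
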