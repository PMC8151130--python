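"""Delimited-text sweep files shared by the Langevin and demodulation paths.

One schema for every offset sweep: commented ``# key = value`` header
lines carrying the acquisition parameters, then a tab-separated table
with the offset field in mT/µ0 and real/imaginary columns per mixing
order.  Internally all fields are SI (tesla); the file unit follows the
instrument convention.
"""

from __future__ import annotations

import io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import Environment, MagneticMaterial
from .langevin import DemodGrid, ExcitationProtocol, MixingSpectrum
from .fitting import SweepDataset

__all__ = ["write_sweep", "read_sweep", "sweep_to_dataset"]

SWEEP_COLUMNS = ["H0_mT"] + [f"m{n}_{p}" for n in (1, 2, 3, 4) for p in ("re", "im")]


def write_sweep(path: str | Path, spectrum: MixingSpectrum, meta: dict | None = None) -> None:
    """Write a mixing spectrum as a commented, tab-separated sweep file."""
    path = Path(path)
    header = dict(meta or {})
    header.setdefault("format", "fmmd-sweep/1")
    header.setdefault("version", __version__)
    header["normalized"] = spectrum.normalized
    lines = [f"# {k} = {json.dumps(v, default=float)}" for k, v in header.items()]
    df = spectrum.to_frame()
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10e")


def read_sweep(path: str | Path) -> tuple[MixingSpectrum, dict]:
    """Read a sweep file back into a spectrum plus its header metadata."""
    path = Path(path)
    meta: dict = {}
    lines = path.read_text().splitlines(keepends=True)
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, raw = line[1:].partition("=")
        try:
            meta[key.strip()] = json.loads(raw.strip())
        except json.JSONDecodeError:
            meta[key.strip()] = raw.strip()
        n_header += 1
    df = pd.read_csv(io.StringIO("".join(lines[n_header:])), sep="\t")
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sweep file {path} lacks columns {missing}")
    comps = np.array(
        [df[f"m{n}_re"].to_numpy() + 1j * df[f"m{n}_im"].to_numpy() for n in (1, 2, 3, 4)]
    )
    spectrum = MixingSpectrum(
        H0=df["H0_mT"].to_numpy() * 1e-3,
        components=comps,
        normalized=bool(meta.get("normalized", False)),
    )
    return spectrum, meta


def sweep_to_dataset(
    spectrum: MixingSpectrum,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    meta: dict | None = None,
) -> SweepDataset:
    """View a (read) spectrum as a fit-ready dataset of real components."""
    return SweepDataset(
        H0=spectrum.H0,
        observed=spectrum.components.real,
        protocol=protocol,
        grid=grid,
        material=material,
        env=env,
        meta=dict(meta or {}),
    )
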