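"""Relaxation-time estimates and interaction-energy bookkeeping.

Field-dependent Brownian and Néel relaxation times, their harmonic
(effective) combination, the uniaxial anisotropy field, the blocking
condition f·τ ≳ 1 marking the onset of dynamic hysteresis, and an
order-of-magnitude estimate of the dipole–dipole interaction energy
relative to kB·T that justifies treating the ensemble as noninteracting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import (
    KB,
    MU0,
    Environment,
    MagneticMaterial,
    core_volume,
    hydrodynamic_volume,
    particle_moment,
)

__all__ = [
    "RelaxationTimes",
    "anisotropy_field",
    "brownian_time",
    "neel_time",
    "effective_time",
    "relaxation_times",
    "dipole_thermal_ratio",
]

#: Iron mass fraction of magnetite Fe3O4 (3·55.845 / 231.533).
IRON_MASS_FRACTION_MAGNETITE = 3 * 55.845 / 231.533


@dataclass(frozen=True)
class RelaxationTimes:
    """Relaxation-time summary at a given AC amplitude.

    All times in seconds; ``blocked`` flags f·τ ≥ 1 (the drive outruns
    the particle's relaxation, opening the hysteresis loop).
    """

    tauB0: float
    tauB: float
    tauN: float
    tau: float
    blocked: bool


def anisotropy_field(material: MagneticMaterial) -> float:
    """Uniaxial anisotropy field µ0·H_K = 2K/Ms, tesla."""
    return 2.0 * material.K / material.Ms


def brownian_time(
    env: Environment,
    muH_AC: float = 0.0,
    dc: float | None = None,
    material: MagneticMaterial | None = None,
    dh: float | None = None,
) -> float:
    """Field-corrected Brownian relaxation time τB/√(1 + 0.21·ξ²), s.

    τB = 3·η·V_H/(kB·T) is the zero-field rotational time;
    ξ = mp(dc)·µ0H_AC/(kB·T) the reduced AC amplitude.  Strictly
    decreasing in the drive amplitude (a strong drive rocks the particle
    past its viscous lag).
    """
    tauB0 = 3.0 * env.eta * hydrodynamic_volume(env.dh if dh is None else dh) / (
        KB * env.T
    )
    if muH_AC == 0.0:
        return float(tauB0)
    if dc is None or material is None:
        raise ValueError("dc and material required for the field correction")
    xi = particle_moment(dc, material) * muH_AC / (KB * env.T)
    return float(tauB0 / np.sqrt(1.0 + 0.21 * xi**2))


def neel_time(
    material: MagneticMaterial, env: Environment, muH_AC: float, dc: float
) -> float:
    """Field-corrected Néel time τ0·exp[K·Vc/(kB·T)·(1 − H_AC/H_K)²], s.

    Equals τ0·exp(K·Vc/kBT) at zero drive and τ0 once the drive reaches
    the anisotropy field (amplitudes beyond H_K clamp the barrier at
    zero — the barrier is destroyed, not restored).
    """
    if muH_AC < 0:
        raise ValueError("AC amplitude must be non-negative")
    hk = anisotropy_field(material)
    reduced = 1.0 - muH_AC / hk if hk > 0 else 0.0
    reduced = max(reduced, 0.0)
    barrier = material.K * core_volume(dc) / (KB * env.T)
    return float(material.tau0 * np.exp(barrier * reduced**2))


def effective_time(tauB: float, tauN: float) -> float:
    """Effective relaxation time τ = (τB⁻¹ + τN⁻¹)⁻¹ — the faster channel wins."""
    if tauB <= 0 or tauN <= 0:
        raise ValueError("relaxation times must be positive")
    if np.isinf(tauB):
        return float(tauN)
    if np.isinf(tauN):
        return float(tauB)
    return float(1.0 / (1.0 / tauB + 1.0 / tauN))


def relaxation_times(
    material: MagneticMaterial,
    env: Environment,
    dc: float,
    muH_AC: float,
    f_drive: float,
    dh: float | None = None,
) -> RelaxationTimes:
    """Full relaxation assessment at drive amplitude µ0·H_AC and frequency f."""
    tauB0 = brownian_time(env, dh=dh)
    tauB = brownian_time(env, muH_AC, dc, material, dh=dh)
    tauN = neel_time(material, env, muH_AC, dc)
    tau = effective_time(tauB, tauN)
    return RelaxationTimes(
        tauB0=tauB0, tauB=tauB, tauN=tauN, tau=tau, blocked=bool(f_drive * tau >= 1.0)
    )


def dipole_thermal_ratio(
    concentration: float,
    dc: float,
    material: MagneticMaterial,
    env: Environment,
    iron_mass_fraction: float = IRON_MASS_FRACTION_MAGNETITE,
) -> float:
    """Point-dipole pair energy over kB·T at the mean particle spacing.

    ``concentration`` is the iron mass concentration in kg(Fe)/m³ (the
    data-sheet unit mg(Fe)/mL equals kg/m³).  The particle number density
    follows from the per-particle iron mass ρ·Vc·w_Fe, the spacing from a
    cubic lattice r = n⁻¹ᐟ³, and the interaction scale is the point-dipole
    energy µ0·mp²/(4π·r³).  Ratios ≪ 1 justify the noninteracting
    ensemble treatment; the ratio scales linearly with number density.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    mass_per_particle = material.rho * core_volume(dc) * iron_mass_fraction
    number_density = concentration / mass_per_particle
    r3 = 1.0 / number_density  # r = n^(-1/3), used only cubed
    mp = particle_moment(dc, material)
    e_dip = MU0 * mp**2 / (4.0 * np.pi * r3)
    return float(e_dip / (KB * env.T))
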