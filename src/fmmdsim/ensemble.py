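"""Particle material properties and lognormal core-size statistics.

Magnetic nanoparticle (MNP) ensembles are described by intrinsic material
constants (saturation magnetization, uniaxial anisotropy, damping, ...) and
a lognormal distribution of core diameters.  This module holds those record
types and every size statistic derived from them: the single-particle
saturation moment, the diameter PDF/CDF, tail fractions ("reverse CDF",
counted from the large-size end), tail quantiles, and the polydispersity
index.

Unit conventions, used package-wide
-----------------------------------
* lengths in meters,
* magnetic moments in A·m²,
* magnetic fields as flux density ``B = µ0·H`` in tesla (data sheets and
  sweep files quote "mT/µ0"; :func:`mT` / :func:`to_mT` convert),
* energies in joule, temperatures in kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "KB",
    "MU0",
    "GAMMA_E",
    "MagneticMaterial",
    "SizeDistribution",
    "Environment",
    "MAGNETITE",
    "WATER_300K",
    "NANOMAG_D",
    "mT",
    "to_mT",
    "particle_moment",
    "core_volume",
    "hydrodynamic_volume",
    "lognormal_pdf",
    "lognormal_cdf",
    "reverse_cdf",
    "diameter_for_tail_fraction",
    "sample_diameters",
    "polydispersity_index",
]

# Physical constants (SI)
KB = 1.380649e-23  # Boltzmann constant, J/K
MU0 = 4e-7 * np.pi  # vacuum permeability, T·m/A
GAMMA_E = 1.76085963e11  # electron gyromagnetic ratio, rad s^-1 T^-1


def mT(value: float | np.ndarray) -> float | np.ndarray:
    """Convert a field quoted in mT/µ0 to the internal tesla (µ0·H) unit."""
    return np.asarray(value, dtype=float) * 1e-3


def to_mT(value: float | np.ndarray) -> float | np.ndarray:
    """Convert an internal tesla (µ0·H) field to mT/µ0 for display/files."""
    return np.asarray(value, dtype=float) * 1e3


@dataclass(frozen=True)
class MagneticMaterial:
    """Intrinsic single-domain particle constants.

    Parameters
    ----------
    Ms : float
        Saturation magnetization, A/m.
    K : float
        Effective uniaxial anisotropy constant, J/m³.
    alpha : float
        Dimensionless LLG damping parameter.
    gamma : float
        Electron gyromagnetic ratio, rad s⁻¹ T⁻¹.
    tau0 : float
        Néel attempt time, s.
    rho : float
        Mass density, kg/m³.
    """

    Ms: float
    K: float = 0.0
    alpha: float = 1.0
    gamma: float = GAMMA_E
    tau0: float = 1e-9
    rho: float = 5200.0

    def __post_init__(self) -> None:
        if self.Ms <= 0:
            raise ValueError(f"Ms must be positive, got {self.Ms}")
        if self.K < 0:
            raise ValueError(f"K must be non-negative, got {self.K}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.tau0 <= 0:
            raise ValueError(f"tau0 must be positive, got {self.tau0}")


@dataclass(frozen=True)
class SizeDistribution:
    """Lognormal law of core diameters: median ``d0`` (m), shape ``sigma``.

    ``ln(dc)`` is normal with mean ``ln(d0)`` and standard deviation
    ``sigma``.  ``Np`` is the total number of particles in the ensemble.
    """

    d0: float
    sigma: float
    Np: float = 1.0

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError(f"d0 must be positive, got {self.d0}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be non-negative, got {self.sigma}")
        if self.Np <= 0:
            raise ValueError(f"Np must be positive, got {self.Np}")

    @property
    def frozen(self) -> stats.rv_continuous:
        """The scipy frozen lognormal distribution of diameters."""
        return stats.lognorm(s=max(self.sigma, 1e-300), scale=self.d0)

    def mean_diameter(self) -> float:
        """Arithmetic mean diameter d0·exp(σ²/2), m."""
        return self.d0 * np.exp(0.5 * self.sigma**2)

    def moment(self, order: int) -> float:
        """Raw moment E[dc^order] = d0^order · exp(order²σ²/2)."""
        return self.d0**order * np.exp(0.5 * (order * self.sigma) ** 2)


@dataclass(frozen=True)
class Environment:
    """Thermal and hydrodynamic surroundings of the particles.

    T in kelvin, carrier viscosity ``eta`` in Pa·s, hydrodynamic diameter
    ``dh`` in meters (core plus nonmagnetic shell; must not be smaller
    than the core under consideration).
    """

    T: float
    eta: float = 8.9e-4
    dh: float = 20e-9

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"T must be positive, got {self.T}")
        if self.eta <= 0:
            raise ValueError(f"eta must be positive, got {self.eta}")
        if self.dh <= 0:
            raise ValueError(f"dh must be positive, got {self.dh}")


# Reference parameter sets: bulk magnetite constants and the nanomag-D
# SPIO size law obtained from fitting dual-frequency offset sweeps.
MAGNETITE = MagneticMaterial(Ms=476e3, K=11e3, alpha=1.0, rho=5200.0)
WATER_300K = Environment(T=300.0, eta=8.9e-4, dh=20e-9)
NANOMAG_D = SizeDistribution(d0=7.81e-9, sigma=0.346, Np=1.0)


def core_volume(dc: float | np.ndarray) -> float | np.ndarray:
    """Volume of a spherical core of diameter ``dc``, m³."""
    dc = np.asarray(dc, dtype=float)
    return np.pi / 6.0 * dc**3


def hydrodynamic_volume(dh: float | np.ndarray) -> float | np.ndarray:
    """Hydrodynamic volume π/6·dh³, m³."""
    return core_volume(dh)


def particle_moment(
    dc: float | np.ndarray, material: MagneticMaterial
) -> float | np.ndarray:
    """Saturation magnetic moment of a spherical particle, A·m².

    ``mp = Ms · π·dc³/6`` — strictly cubic in the core diameter.
    """
    dc = np.asarray(dc, dtype=float)
    if np.any(dc < 0):
        raise ValueError("core diameter must be non-negative")
    out = material.Ms * core_volume(dc)
    return float(out) if out.ndim == 0 else out


def lognormal_pdf(
    dc: float | np.ndarray, dist: SizeDistribution
) -> float | np.ndarray:
    """Lognormal probability density of core diameters, m⁻¹."""
    dc = np.asarray(dc, dtype=float)
    if np.any(dc <= 0):
        raise ValueError("diameter must be positive")
    out = dist.frozen.pdf(dc)
    return float(out) if out.ndim == 0 else out


def lognormal_cdf(
    dc: float | np.ndarray, dist: SizeDistribution
) -> float | np.ndarray:
    """Fraction of particles with diameter below ``dc``."""
    dc = np.asarray(dc, dtype=float)
    if np.any(dc <= 0):
        raise ValueError("diameter must be positive")
    out = dist.frozen.cdf(dc)
    return float(out) if out.ndim == 0 else out


def reverse_cdf(
    dmin: float | np.ndarray, dist: SizeDistribution
) -> float | np.ndarray:
    """Number fraction of particles with core diameter ≥ ``dmin``.

    The survival function of the lognormal law — the tail quantile counted
    from the large-size end.  ``reverse_cdf(d0) == 0.5`` by definition of
    the median.
    """
    dmin = np.asarray(dmin, dtype=float)
    if np.any(dmin <= 0):
        raise ValueError("diameter threshold must be positive")
    out = dist.frozen.sf(dmin)
    return float(out) if out.ndim == 0 else out


def diameter_for_tail_fraction(
    frac: float | np.ndarray, dist: SizeDistribution
) -> float | np.ndarray:
    """Diameter threshold whose large-size tail holds the fraction ``frac``.

    Inverse of :func:`reverse_cdf`: ``reverse_cdf(result) == frac``.
    """
    frac = np.asarray(frac, dtype=float)
    if np.any((frac <= 0) | (frac >= 1)):
        raise ValueError("tail fraction must lie strictly inside (0, 1)")
    out = dist.frozen.isf(frac)
    return float(out) if out.ndim == 0 else out


def sample_diameters(
    n: int, dist: SizeDistribution, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` core diameters from the lognormal law (m)."""
    return dist.d0 * np.exp(dist.sigma * rng.standard_normal(n))


def polydispersity_index(dist: SizeDistribution) -> float:
    """Polydispersity index of the diameter law: exp(σ²) − 1.

    The squared coefficient of variation Var[dc]/E[dc]² of a lognormal
    distribution; 0 for a monodisperse ensemble.
    """
    return float(np.expm1(dist.sigma**2))
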