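"""Equilibrium Langevin model of dual-frequency excitation (FMMD forward model).

In frequency mixing magnetic detection (FMMD) a nanoparticle ensemble is
driven by a two-tone field with a static offset,

    B(t) = B0 + B1·sin(2π f1 t) + B2·sin(2π f2 t),

and the nonlinearity of the equilibrium magnetization generates
intermodulation products at f1 + n·f2.  In thermodynamic equilibrium the
moment of a particle of core diameter dc follows the Langevin function
L(ξ) = coth ξ − 1/ξ with ξ = mp(dc)·B/(kB·T).  The mixing component of
order n is the synchronous Fourier sum of the sampled L-response against a
reference tone at f1 + n·f2 — cosine-referenced for odd n, sine-referenced
for even n (the responses alternate between point-symmetric and
axisymmetric functions of the offset field).  Ensemble components follow by
integration over the lognormal size law.

The sums use a numeric frequency ratio f1/f2 = 20 with 10 samples per
high-frequency period (k = 200 samples over exactly one low-frequency
period); the physical high frequency only enters through its amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .ensemble import (
    KB,
    Environment,
    MagneticMaterial,
    SizeDistribution,
    lognormal_pdf,
    particle_moment,
)

__all__ = [
    "ExcitationProtocol",
    "DemodGrid",
    "MixingSpectrum",
    "EXPERIMENTAL_PROTOCOL",
    "MC_PROTOCOL",
    "DEFAULT_H0_GRID",
    "langevin",
    "xi_of",
    "applied_field",
    "equilibrium_moment",
    "saturation_moment",
    "mixing_component_single",
    "mixing_spectrum",
    "signal_fraction",
    "threshold_for_signal_fraction",
]

#: Default quadrature node count for size integrals (log-spaced).
SIZE_QUAD_NODES = 801
#: Half-width of the size quadrature window in units of sigma.
SIZE_QUAD_SPAN = 6.0


@dataclass(frozen=True)
class ExcitationProtocol:
    """Two-tone excitation with static offset.

    Fields are flux densities µ0·H in tesla; ``f1 > f2 > 0`` in Hz;
    ``T_sample`` is the sample temperature in kelvin.
    """

    H0: float
    H1: float
    f1: float
    H2: float
    f2: float
    T_sample: float

    def __post_init__(self) -> None:
        if not (self.f1 > self.f2 > 0):
            raise ValueError("frequencies must satisfy f1 > f2 > 0")
        if self.H1 < 0 or self.H2 < 0:
            raise ValueError("tone amplitudes must be non-negative")
        if self.T_sample <= 0:
            raise ValueError("temperature must be positive")

    def with_offset(self, H0: float) -> "ExcitationProtocol":
        return replace(self, H0=float(H0))

    def numeric(self, grid: "DemodGrid") -> "ExcitationProtocol":
        """Copy with f1 replaced by the numeric ratio × f2 (same amplitudes)."""
        return replace(self, f1=grid.ratio * self.f2)


@dataclass(frozen=True)
class DemodGrid:
    """Sampling grid of the synchronous demodulation sums.

    ``steps_per_hf_period`` samples per 1/f1 period, a numeric frequency
    ratio ``ratio = f1/f2``, and ``k = steps_per_hf_period × ratio`` samples
    covering exactly one low-frequency period.
    """

    steps_per_hf_period: int = 10
    ratio: int = 20

    def __post_init__(self) -> None:
        if self.steps_per_hf_period < 1 or self.ratio < 1:
            raise ValueError("grid counts must be positive integers")

    @property
    def k(self) -> int:
        return self.steps_per_hf_period * self.ratio

    def sample_times(self, f2: float) -> np.ndarray:
        """k uniform samples t_i = i·Δt, Δt = 0.1/f1, over one period 1/f2.

        The i = 0 .. k−1 window spans exactly one low-frequency period,
        keeping the tone basis orthogonal (the closing sample t_k would
        duplicate t_0 of the next period).
        """
        dt = 1.0 / (f2 * self.ratio * self.steps_per_hf_period)
        return dt * np.arange(self.k)


# Measurement-head protocol: tones of the offset-sweep experiment, sample
# heated to ~318 K by coil currents.
EXPERIMENTAL_PROTOCOL = ExcitationProtocol(
    H0=0.0, H1=1.29e-3, f1=30543.0, H2=16.4e-3, f2=62.95, T_sample=318.0
)
# Protocol of the stochastic simulations (integer tone ratio, 300 K bath).
MC_PROTOCOL = ExcitationProtocol(
    H0=0.0, H1=1.0e-3, f1=40000.0, H2=16.0e-3, f2=2000.0, T_sample=300.0
)
#: Offset-field sweep 0..24 mT in 1 mT steps (tesla).
DEFAULT_H0_GRID = np.arange(0.0, 24.0 + 0.5, 1.0) * 1e-3


@dataclass
class MixingSpectrum:
    """Demodulated mixing components m_n(H0), n = 1..4.

    ``components`` has shape (4, len(H0)); the real part is the
    reference-phase (cos for odd n, sin for even n) amplitude in A·m²
    (or dimensionless if normalized).
    """

    H0: np.ndarray
    components: np.ndarray
    normalized: bool = False
    Mmax: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.H0 = np.asarray(self.H0, dtype=float)
        self.components = np.asarray(self.components, dtype=complex)
        if self.components.shape != (4, self.H0.size):
            raise ValueError("components must have shape (4, len(H0))")

    def component(self, n: int) -> np.ndarray:
        if n not in (1, 2, 3, 4):
            raise ValueError("mixing order n must be in 1..4")
        return self.components[n - 1]

    def normalize(self) -> "MixingSpectrum":
        """Scale each component to unit maximum magnitude."""
        mmax = np.abs(self.components).max(axis=1)
        return MixingSpectrum(
            self.H0, self.components / mmax[:, None], normalized=True, Mmax=mmax
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: offset in mT/µ0, real/imag columns per order."""
        data = {"H0_mT": self.H0 * 1e3}
        for n in (1, 2, 3, 4):
            data[f"m{n}_re"] = self.components[n - 1].real
            data[f"m{n}_im"] = self.components[n - 1].imag
        return pd.DataFrame(data)


def langevin(xi: float | np.ndarray) -> float | np.ndarray:
    """Langevin function L(ξ) = coth(ξ) − 1/ξ, the equilibrium moment fraction.

    Odd, bounded by (−1, 1); the removable singularity at ξ = 0 is handled
    by the series L(ξ) = ξ/3 − ξ³/45 + 2ξ⁵/945 (relative error < 1e-14 for
    |ξ| < 1e-2).
    """
    xi = np.asarray(xi, dtype=float)
    small = np.abs(xi) < 1e-2
    xs = np.where(small, 1.0, xi)  # keep 1/xi finite where unused
    series = xi / 3.0 - xi**3 / 45.0 + 2.0 * xi**5 / 945.0
    with np.errstate(over="ignore"):
        full = 1.0 / np.tanh(xs) - 1.0 / xs
    out = np.where(small, series, full)
    return float(out) if out.ndim == 0 else out


def xi_of(
    dc: float | np.ndarray,
    muH: float | np.ndarray,
    material: MagneticMaterial,
    env: Environment,
) -> float | np.ndarray:
    """Dimensionless field parameter ξ = mp(dc)·µ0H/(kB·T)."""
    if env.T <= 0:
        raise ValueError("temperature must be positive")
    out = particle_moment(dc, material) * np.asarray(muH, dtype=float) / (KB * env.T)
    return float(out) if np.ndim(out) == 0 else out


def applied_field(
    t: float | np.ndarray, protocol: ExcitationProtocol
) -> float | np.ndarray:
    """Two-tone excitation field B(t) = B0 + B1·sin(2πf1t) + B2·sin(2πf2t), T."""
    t = np.asarray(t, dtype=float)
    out = (
        protocol.H0
        + protocol.H1 * np.sin(2 * np.pi * protocol.f1 * t)
        + protocol.H2 * np.sin(2 * np.pi * protocol.f2 * t)
    )
    return float(out) if out.ndim == 0 else out


def _size_nodes(
    dist: SizeDistribution,
    nodes: int = SIZE_QUAD_NODES,
    span: float = SIZE_QUAD_SPAN,
) -> np.ndarray:
    """Log-spaced diameter nodes covering d0·exp(±span·σ)."""
    sigma = max(dist.sigma, 1e-8)
    u = np.linspace(
        np.log(dist.d0) - span * sigma, np.log(dist.d0) + span * sigma, nodes
    )
    return np.exp(u)


def _log_trapz(f: np.ndarray, d: np.ndarray, axis: int = -1) -> np.ndarray:
    """∫ f(dc) ddc over the node range, trapezoid in u = ln dc."""
    u = np.log(d)
    return np.trapezoid(f * d, u, axis=axis)


def saturation_moment(dist: SizeDistribution, material: MagneticMaterial) -> float:
    """Large-field ensemble moment Np·Ms·(π/6)·d0³·exp(4.5σ²), A·m².

    Closed form from the third raw moment of the lognormal law.
    """
    return float(
        dist.Np * material.Ms * np.pi / 6.0 * dist.d0**3 * np.exp(4.5 * dist.sigma**2)
    )


def equilibrium_moment(
    muH: float | np.ndarray,
    dist: SizeDistribution,
    material: MagneticMaterial,
    env: Environment,
    nodes: int = SIZE_QUAD_NODES,
) -> float | np.ndarray:
    """Total equilibrium moment of the lognormal ensemble at field µ0H, A·m².

    Np·∫ PDF(dc)·mp(dc)·L(ξ(dc, µ0H)) ddc, odd in the field and saturating
    to :func:`saturation_moment` as the field grows.
    """
    muH = np.atleast_1d(np.asarray(muH, dtype=float))
    d = _size_nodes(dist, nodes)
    w = lognormal_pdf(d, dist) * particle_moment(d, material)  # (nd,)
    xi = xi_of(d[None, :], muH[:, None], material, env)  # (nH, nd)
    vals = dist.Np * _log_trapz(w[None, :] * langevin(xi), d)
    return float(vals[0]) if vals.size == 1 else vals


def _reference(n: int, freq: float, t: np.ndarray) -> np.ndarray:
    """Reference tone at f1 + n·f2: cosine for odd n, sine for even n."""
    phase = 2 * np.pi * freq * t
    return np.cos(phase) if n % 2 == 1 else np.sin(phase)


def _component_profile(
    d: np.ndarray,
    n: int,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    response: Callable[[np.ndarray], np.ndarray] = langevin,
) -> np.ndarray:
    """Per-particle mixing amplitude m_n(dc) for an array of diameters, A·m²."""
    if n not in (1, 2, 3, 4):
        raise ValueError("mixing order n must be in 1..4")
    num = protocol.numeric(grid)
    t = grid.sample_times(num.f2)
    B = applied_field(t, num)  # (k,)
    ref = _reference(n, num.f1 + n * num.f2, t)  # (k,)
    mp = particle_moment(d, material)
    xi = mp[:, None] * B[None, :] / (KB * env.T)  # (nd, k)
    return mp * (2.0 / grid.k) * (response(xi) @ ref)


def mixing_component_single(
    dc: float,
    n: int,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    response: Callable[[np.ndarray], np.ndarray] = langevin,
) -> float:
    """Mixing response m_n of one particle of diameter ``dc``, A·m².

    Synchronous Fourier sum (2/k)·mp·Σᵢ ref(tᵢ)·L(ξ(tᵢ)) over one
    low-frequency period, cos-referenced for odd n, sin-referenced for
    even n.  ``response`` may replace the Langevin function (e.g. the
    identity map yields exactly zero — a linear medium produces no
    intermodulation).
    """
    return float(
        _component_profile(
            np.atleast_1d(float(dc)), n, protocol, grid, material, env, response
        )[0]
    )


def mixing_spectrum(
    dist: SizeDistribution,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    H0_grid: np.ndarray = DEFAULT_H0_GRID,
    nodes: int = SIZE_QUAD_NODES,
) -> MixingSpectrum:
    """Ensemble mixing components m_n(H0) over an offset sweep.

    Integrates the per-particle responses over the lognormally weighted
    ensemble; linear in Np.  The imaginary part of each component holds
    the quadrature orthogonal to the reference phase (vanishing for the
    equilibrium model up to roundoff from the finite sample grid).
    """
    H0_grid = np.atleast_1d(np.asarray(H0_grid, dtype=float))
    if H0_grid.size == 0:
        raise ValueError("H0 grid must be non-empty")
    d = _size_nodes(dist, nodes)
    pdf = lognormal_pdf(d, dist)
    mp = particle_moment(d, material)
    num = protocol.numeric(grid)
    t = grid.sample_times(num.f2)
    comps = np.empty((4, H0_grid.size), dtype=complex)
    for j, H0 in enumerate(H0_grid):
        B = applied_field(t, num.with_offset(H0))
        L = langevin(mp[:, None] * B[None, :] / (KB * env.T))  # (nd, k)
        for n in (1, 2, 3, 4):
            phase = 2 * np.pi * (num.f1 + n * num.f2) * t
            ref = np.cos(phase) if n % 2 == 1 else np.sin(phase)
            orth = np.sin(phase) if n % 2 == 1 else np.cos(phase)
            amp_i = mp * (2.0 / grid.k) * (L @ ref)
            amp_q = mp * (2.0 / grid.k) * (L @ orth)
            comps[n - 1, j] = dist.Np * (
                _log_trapz(pdf * amp_i, d) + 1j * _log_trapz(pdf * amp_q, d)
            )
    return MixingSpectrum(H0_grid, comps)


def _tail_cumulative(
    n: int,
    dist: SizeDistribution,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    H0_grid: np.ndarray,
    nodes: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal fraction carried by the tail dc ≥ d, on the size node grid.

    Evaluated at the offset field maximizing |m_n| on ``H0_grid``.  Returns
    (diameter nodes, tail fraction at each node); tail[0] = 1.
    """
    H0_grid = np.atleast_1d(np.asarray(H0_grid, dtype=float))
    d = _size_nodes(dist, nodes)
    pdf = lognormal_pdf(d, dist)
    # locate the peak offset of the ensemble |m_n|
    vals = np.empty(H0_grid.size)
    for j, H0 in enumerate(H0_grid):
        prof = _component_profile(d, n, protocol.with_offset(H0), grid, material, env)
        vals[j] = abs(_log_trapz(pdf * prof, d))
    H0_peak = H0_grid[int(np.argmax(vals))]
    prof = _component_profile(d, n, protocol.with_offset(H0_peak), grid, material, env)
    u = np.log(d)
    g = pdf * prof * d  # integrand in u-space
    # cumulative trapezoid from the large-size end
    seg = 0.5 * (g[1:] + g[:-1]) * np.diff(u)
    tail = np.concatenate([[seg.sum()], seg.sum() - np.cumsum(seg)])
    return d, tail / tail[0]


def signal_fraction(
    dmin: float,
    n: int,
    dist: SizeDistribution,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    H0_grid: np.ndarray = DEFAULT_H0_GRID,
    nodes: int = SIZE_QUAD_NODES,
) -> float:
    """Fraction of the ensemble mixing signal from particles with dc ≥ dmin.

    The size integral of component n restricted to [dmin, ∞), divided by
    the unrestricted integral, both evaluated at the offset field where
    |m_n| peaks on ``H0_grid``.  Equals 1 at dmin = 0 and decreases toward
    0 — almost all of the FMMD signal lives in the large-size tail.
    """
    if dmin < 0:
        raise ValueError("dmin must be non-negative")
    d, tail = _tail_cumulative(n, dist, protocol, grid, material, env, H0_grid, nodes)
    if dmin <= d[0]:
        return 1.0
    if dmin >= d[-1]:
        return 0.0
    return float(np.interp(np.log(dmin), np.log(d), tail))


def threshold_for_signal_fraction(
    frac: float,
    n: int,
    dist: SizeDistribution,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    H0_grid: np.ndarray = DEFAULT_H0_GRID,
    nodes: int = SIZE_QUAD_NODES,
) -> float:
    """Smallest size cutoff whose tail still carries the fraction ``frac``.

    Inverse of :func:`signal_fraction` in its first argument; solved by
    bisection on the cumulative tail profile.
    """
    if not 0.0 < frac <= 1.0:
        raise ValueError("signal fraction must lie in (0, 1]")
    d, tail = _tail_cumulative(n, dist, protocol, grid, material, env, H0_grid, nodes)
    if frac >= tail[0]:
        return float(d[0])
    u = np.log(d)

    def f(x: float) -> float:
        return float(np.interp(x, u, tail)) - frac

    lo, hi = u[0], u[-1]
    return float(np.exp(brentq(f, lo, hi, xtol=1e-12)))
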