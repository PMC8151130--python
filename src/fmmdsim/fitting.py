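"""Least-squares fitting of the Langevin forward model to offset sweeps.

The forward model (lognormal ensemble mixing components vs offset field)
carries three parameters: the median core diameter d0, the lognormal
width σ, and the particle count Np.  Sweeps — experimental-format or
demodulated Monte Carlo output — are fitted on the real parts of all four
components pooled, with a damped least-squares (Levenberg–Marquardt type)
algorithm; any parameter may be held fixed.  Np enters the model linearly
and is exactly degenerate with any multiplicative calibration of the
data: fits of normalized data must fix Np (or fit scale only through it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .ensemble import Environment, MagneticMaterial, SizeDistribution
from .langevin import DemodGrid, ExcitationProtocol, MixingSpectrum, mixing_spectrum

__all__ = [
    "SweepDataset",
    "FitResult",
    "DEFAULT_BOUNDS",
    "fit_langevin",
    "r_squared",
    "generate_synthetic_sweep",
]

#: Default fit bounds: d0 in [2, 30] nm, sigma in [0.05, 1.5], Np free in log.
DEFAULT_BOUNDS = {
    "d0": (2e-9, 30e-9),
    "sigma": (0.05, 1.5),
    "log10_Np": (-30.0, 30.0),
}


@dataclass
class SweepDataset:
    """Observed real mixing components m_n(H0) with their acquisition context.

    ``observed`` has shape (4, len(H0)), in A·m² (or normalized units —
    in that case fix Np when fitting).
    """

    H0: np.ndarray
    observed: np.ndarray
    protocol: ExcitationProtocol
    grid: DemodGrid
    material: MagneticMaterial
    env: Environment
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.H0 = np.asarray(self.H0, dtype=float)
        self.observed = np.asarray(self.observed, dtype=float)
        if self.H0.ndim != 1 or np.any(np.diff(self.H0) <= 0):
            raise ValueError("H0 grid must be strictly increasing")
        if self.observed.shape != (4, self.H0.size):
            raise ValueError("observed must have shape (4, len(H0))")


@dataclass
class FitResult:
    """Point estimates, covariance, and goodness of fit of a sweep fit."""

    distribution: SizeDistribution
    covariance: np.ndarray | None
    r2_components: np.ndarray
    r2_pooled: float
    success: bool
    message: str
    n_evaluations: int
    cost: float
    fixed: tuple[str, ...] = ()


def r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination R² = 1 − SS_res/SS_tot.

    Equals 1 only for a perfect prediction; can be arbitrarily negative.
    Raises on constant observations (SS_tot = 0), where R² is undefined.
    """
    observed = np.asarray(observed, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if observed.size != predicted.size or observed.size < 2:
        raise ValueError("need equal-length sequences of at least 2 points")
    ss_tot = np.sum((observed - observed.mean()) ** 2)
    if ss_tot == 0.0:
        raise ValueError("R² undefined: observations have zero variance")
    ss_res = np.sum((observed - predicted) ** 2)
    return float(1.0 - ss_res / ss_tot)


_PARAMS = ("d0", "sigma", "log10_Np")


def _model_real(
    theta: dict[str, float], data: SweepDataset, nodes: int
) -> np.ndarray:
    dist = SizeDistribution(
        d0=theta["d0"], sigma=theta["sigma"], Np=10.0 ** theta["log10_Np"]
    )
    spec = mixing_spectrum(
        dist, data.protocol, data.grid, data.material, data.env, data.H0, nodes=nodes
    )
    return spec.components.real


def fit_langevin(
    data: SweepDataset,
    init: SizeDistribution,
    bounds: dict[str, tuple[float, float]] | None = None,
    fixed: tuple[str, ...] = (),
    normalize_components: bool = False,
    nodes: int = 301,
) -> FitResult:
    """Fit (d0, σ, Np) of the lognormal ensemble to an offset sweep.

    Pooled residuals over the real parts of all four mixing components,
    minimized with scipy's damped (trust-region reflective) least squares;
    Np is log-parameterized.  ``fixed`` names parameters ("d0", "sigma",
    "Np") held at their ``init`` values — e.g. the consistency fit of
    Monte Carlo sweeps fixes d0 and frees only σ (and Np).
    ``normalize_components`` weights each component's residuals by its
    observed maximum so weak high orders count equally.

    Non-convergence is reported in the returned diagnostics rather than
    raised; all-zero data is rejected.
    """
    if not np.any(data.observed):
        raise ValueError("degenerate sweep: all observations are zero")
    fixed = tuple("log10_Np" if f == "Np" else f for f in fixed)
    if any(f not in _PARAMS for f in fixed):
        raise ValueError(f"unknown fixed parameter in {fixed}")
    b = dict(DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    init_full = {
        "d0": init.d0,
        "sigma": max(init.sigma, b["sigma"][0]),
        "log10_Np": np.log10(init.Np),
    }
    free = [p for p in _PARAMS if p not in fixed]
    if not free:
        raise ValueError("at least one parameter must be free")
    n_data = data.observed.size
    if n_data < len(free) + 3:
        raise ValueError("need at least 3 more residuals than free parameters")
    for p in free:
        lo, hi = b[p]
        if not lo <= init_full[p] <= hi:
            raise ValueError(f"initial {p}={init_full[p]:g} outside bounds {b[p]}")
    # residuals are scaled to O(1) so the optimizer's stopping criteria
    # are meaningful for data spanning many decades of absolute moment
    if normalize_components:
        w = np.abs(data.observed).max(axis=1)
        w[w == 0] = 1.0
    else:
        w = np.full(4, np.abs(data.observed).max())

    # optimize in O(1) units: d0 in nm, sigma as-is, Np through log10
    scale = {"d0": 1e9, "sigma": 1.0, "log10_Np": 1.0}

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = dict(init_full)
        theta.update({p: xv / scale[p] for p, xv in zip(free, x)})
        model = _model_real(theta, data, nodes)
        return ((model - data.observed) / w[:, None]).ravel()

    x0 = np.array([init_full[p] * scale[p] for p in free])
    lo = np.array([b[p][0] * scale[p] for p in free])
    hi = np.array([b[p][1] * scale[p] for p in free])
    res = least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", x_scale="jac",
        xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    theta = dict(init_full)
    theta.update({p: xv / scale[p] for p, xv in zip(free, res.x)})
    dist = SizeDistribution(
        d0=theta["d0"], sigma=theta["sigma"], Np=10.0 ** theta["log10_Np"]
    )
    model = _model_real(theta, data, nodes)
    r2c = np.array(
        [
            r_squared(data.observed[i], model[i])
            if np.ptp(data.observed[i]) > 0
            else np.nan
            for i in range(4)
        ]
    )
    r2p = r_squared(data.observed, model)
    cov = None
    if res.jac is not None and np.all(np.isfinite(res.jac)):
        jtj = res.jac.T @ res.jac
        try:
            dof = max(n_data - len(free), 1)
            cov = np.linalg.inv(jtj) * 2.0 * res.cost / dof
        except np.linalg.LinAlgError:
            cov = None
    return FitResult(
        distribution=dist,
        covariance=cov,
        r2_components=r2c,
        r2_pooled=r2p,
        success=bool(res.success),
        message=str(res.message),
        n_evaluations=int(res.nfev),
        cost=float(res.cost),
        fixed=fixed,
    )


def generate_synthetic_sweep(
    dist: SizeDistribution,
    protocol: ExcitationProtocol,
    grid: DemodGrid,
    material: MagneticMaterial,
    env: Environment,
    H0_grid: np.ndarray,
    noise_level: float = 0.0,
    seed: int = 0,
    nodes: int = 301,
) -> SweepDataset:
    """Forward-model sweep with additive Gaussian noise, bit-reproducible.

    Noise on component n has standard deviation
    ``noise_level × max|m_n(H0)|`` (per-component scaling, emulating the
    roughly uniform absolute noise floor of a lock-in sweep).
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    spec: MixingSpectrum = mixing_spectrum(
        dist, protocol, grid, material, env, H0_grid, nodes=nodes
    )
    clean = spec.components.real
    rng = np.random.default_rng(seed)
    scale = noise_level * np.abs(clean).max(axis=1, keepdims=True)
    observed = clean + scale * rng.standard_normal(clean.shape)
    return SweepDataset(
        H0=np.asarray(H0_grid, dtype=float),
        observed=observed,
        protocol=protocol,
        grid=grid,
        material=material,
        env=env,
        meta={"noise_level": noise_level, "seed": seed, "true": {
            "d0": dist.d0, "sigma": dist.sigma, "Np": dist.Np}},
    )
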