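# fmmdsim

Modeling toolkit for **frequency mixing magnetic detection (FMMD)** of
magnetic nanoparticles: dual-frequency magnetic excitation of
superparamagnetic iron-oxide labels and the nonlinear intermodulation
products it generates.

FMMD biosensors drive an immobilized nanoparticle ensemble with a strong
low-frequency tone, a weak high-frequency tone and a static offset,

    µ0·H(t) = B0 + B1·sin(2π f1 t) + B2·sin(2π f2 t),

and detect the mixing components at f1 + n·f2 (n = 1..4) as a function of
the offset B0. This package implements both modeling engines for that
response and the analyses connecting them:

* **Equilibrium Langevin engine** (`fmmdsim.langevin`) — the moment of a
  core of diameter `dc` is `mp = Ms·π·dc³/6` and its equilibrium
  magnetization fraction is the Langevin function `L(ξ) = coth ξ − 1/ξ`
  with `ξ = mp·µ0H/(kB·T)`. Mixing components are synchronous Fourier
  sums of the sampled response (cos-referenced for odd n, sin for even n,
  normalization 2/k), integrated over a lognormal diameter law
  (median `d0`, width `σ`, count `Np`).
* **Stochastic Néel–Brown Monte Carlo engine** (`fmmdsim.micromag`) —
  coupled stochastic Landau–Lifshitz–Gilbert dynamics of the moment
  direction and Brownian rotation of the easy axis in a viscous carrier,
  integrated with a Stratonovich–Heun scheme, yielding magnetization
  traces and dynamic hysteresis (M(H)) loops.
* **Demodulation** (`fmmdsim.demod`) — leakage-free lock-in extraction of
  the mixing components from any sampled trace, making Monte Carlo output
  column-compatible with the equilibrium sweeps.
* **Fitting** (`fmmdsim.fitting`) — Levenberg–Marquardt-type least-squares
  estimation of (d0, σ, Np) from offset sweeps, plus a seeded synthetic
  sweep generator.
* **Relaxation analysis** (`fmmdsim.relaxation`) — field-dependent
  Brownian and Néel times, effective time `τ = (τB⁻¹+τN⁻¹)⁻¹`, anisotropy
  field `2K/Ms`, the blocking condition `f·τ ~ 1`, and a dipole-vs-thermal
  energy estimate justifying the noninteracting treatment.

## Worked example

Which particles actually produce the FMMD signal? For the fitted
nanomag-D size law (d0 = 7.81 nm, σ = 0.346) under the experimental tones
(µ0H1 = 1.29 mT, µ0H2 = 16.4 mT, 318 K):

```python
from fmmdsim import (Environment, MAGNETITE, SizeDistribution, reverse_cdf)
from fmmdsim.langevin import (DemodGrid, EXPERIMENTAL_PROTOCOL,
                              threshold_for_signal_fraction)

dist = SizeDistribution(d0=7.81e-9, sigma=0.346)
env = Environment(T=318.0)
for frac in (0.90, 0.99, 0.999):
    d = threshold_for_signal_fraction(frac, 1, dist, EXPERIMENTAL_PROTOCOL,
                                      DemodGrid(), MAGNETITE, env)
    print(f"{frac:.1%} of the f1+f2 signal comes from dc >= {d*1e9:.2f} nm "
          f"(the largest {reverse_cdf(d, dist):.1%} of particles)")
```

prints

```
90.0% of the f1+f2 signal comes from dc >= 11.76 nm (the largest 11.9% of particles)
99.0% of the f1+f2 signal comes from dc >= 9.09 nm (the largest 33.1% of particles)
99.9% of the f1+f2 signal comes from dc >= 7.46 nm (the largest 55.2% of particles)
```

— i.e. essentially the whole mixing signal originates from the large-size
tail of the distribution: the median-sized and smaller particles are
nearly invisible to the readout. The same engine puts the peak of the
f1+f2 component at an offset of 15 mT/µ0 on the 0–24 mT sweep.

The command-line surface wraps the same engines
(`fmmdsim simulate-langevin | generate-synthetic | fit | simulate-mc |
demodulate | size-analysis | relaxation`), each taking a YAML config and
writing deterministic, config-stamped outputs.

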