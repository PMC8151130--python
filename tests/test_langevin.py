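"""Equilibrium forward model: Langevin response, mixing sums, size integrals."""

import numpy as np
import pytest
from dataclasses import replace

from fmmdsim import (
    KB,
    SizeDistribution,
    particle_moment,
    reverse_cdf,
)
from fmmdsim.langevin import (
    DemodGrid,
    EXPERIMENTAL_PROTOCOL,
    applied_field,
    equilibrium_moment,
    langevin,
    mixing_component_single,
    mixing_spectrum,
    saturation_moment,
    signal_fraction,
    threshold_for_signal_fraction,
    xi_of,
)


class TestLangevinFunction:
    def test_zero_limit(self):
        assert langevin(0.0) == 0.0

    def test_series_regime(self):
        assert langevin(0.01) == pytest.approx(0.01 / 3 - 0.01**3 / 45, rel=1e-10)

    def test_saturation(self):
        assert langevin(100.0) == pytest.approx(0.99, rel=1e-6)

    def test_odd_and_bounded(self):
        xi = np.linspace(-80, 80, 2001)
        vals = langevin(xi)
        assert np.allclose(vals, -langevin(-xi), atol=1e-14)
        assert np.all(np.abs(vals) < 1.0)

    def test_continuous_across_series_switch(self):
        # the series and coth branches must agree at the crossover
        xi = np.array([0.00999999, 0.01000001])
        v = langevin(xi)
        assert abs(v[1] - v[0]) < 1e-8


class TestFieldParameter:
    def test_reference_value(self, material, env318):
        assert xi_of(7.81e-9, 16.4e-3, material, env318) == pytest.approx(
            0.444, rel=2e-3
        )

    def test_zero_field(self, material, env318):
        assert xi_of(7.81e-9, 0.0, material, env318) == 0.0

    def test_cubic_in_diameter(self, material, env318):
        r = xi_of(2 * 8e-9, 5e-3, material, env318) / xi_of(8e-9, 5e-3, material, env318)
        assert r == pytest.approx(8.0, rel=1e-12)


class TestAppliedField:
    def test_t0_is_offset(self, exp_protocol):
        assert applied_field(0.0, exp_protocol.with_offset(3e-3)) == pytest.approx(3e-3)

    def test_bounded_by_amplitude_sum(self, mc_protocol):
        p = mc_protocol.with_offset(2e-3)
        t = np.linspace(0, 1 / p.f2, 2_000_001)
        vals = applied_field(t, p)
        bound = p.H0 + p.H1 + p.H2
        assert np.all(vals <= bound + 1e-15)
        assert np.all(vals >= p.H0 - p.H1 - p.H2 - 1e-15)
        # the strong tone's crest is reached up to an HF ripple
        assert vals.max() >= p.H0 + p.H2 - p.H1

    def test_quarter_lf_period(self, mc_protocol):
        # f1/f2 = 20: the HF sine vanishes at t = 1/(4 f2)
        p = mc_protocol.with_offset(1e-3)
        assert applied_field(1 / (4 * p.f2), p) == pytest.approx(
            p.H0 + p.H2, rel=1e-12
        )


class TestEquilibriumMoment:
    def test_zero_field(self, nanomag, material, env318):
        assert equilibrium_moment(0.0, nanomag, material, env318) == 0.0

    def test_saturation_closed_form(self, nanomag, material, env318):
        msat = saturation_moment(nanomag, material)
        val = equilibrium_moment(50.0, nanomag, material, env318)  # xi >> 1 for all sizes
        assert val == pytest.approx(msat, rel=1e-4)

    def test_monotone_and_odd(self, nanomag, material, env318):
        muH = np.linspace(0, 0.1, 60)
        vals = equilibrium_moment(muH, nanomag, material, env318)
        assert np.all(np.diff(vals) > 0)
        assert equilibrium_moment(-0.03, nanomag, material, env318) == pytest.approx(
            -equilibrium_moment(0.03, nanomag, material, env318), rel=1e-12
        )


class TestMixingComponentSingle:
    def test_linear_medium_gives_zero(self, exp_protocol, grid, material, env318):
        for n in (1, 2, 3, 4):
            val = mixing_component_single(
                9e-9, n, exp_protocol.with_offset(10e-3), grid, material, env318,
                response=lambda x: x,
            )
            scale = abs(
                mixing_component_single(
                    9e-9, 1, exp_protocol.with_offset(10e-3), grid, material, env318
                )
            )
            assert abs(val) < 1e-12 * scale

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_offset_parity(self, n, exp_protocol, grid, material, env318):
        plus = mixing_component_single(
            10e-9, n, exp_protocol.with_offset(8e-3), grid, material, env318
        )
        minus = mixing_component_single(
            10e-9, n, exp_protocol.with_offset(-8e-3), grid, material, env318
        )
        assert minus == pytest.approx((-1) ** n * plus, rel=1e-8)

    def test_odd_component_vanishes_at_zero_offset(
        self, exp_protocol, grid, material, env318
    ):
        val = mixing_component_single(
            10e-9, 1, exp_protocol.with_offset(0.0), grid, material, env318
        )
        scale = abs(
            mixing_component_single(
                10e-9, 1, exp_protocol.with_offset(15e-3), grid, material, env318
            )
        )
        assert abs(val) < 1e-10 * scale

    def test_invalid_order(self, exp_protocol, grid, material, env318):
        with pytest.raises(ValueError):
            mixing_component_single(9e-9, 5, exp_protocol, grid, material, env318)

    def test_taylor_limit_second_derivative(self, material, env318, grid):
        """Weak two-tone drive: m1 = −(H1·H2/2)·d²m_eq/dB² at the offset."""
        dc = 9e-9
        p = replace(EXPERIMENTAL_PROTOCOL, H1=2e-5, H2=2e-5, H0=8e-3)
        m1 = mixing_component_single(dc, 1, p, grid, material, env318)
        mp = particle_moment(dc, material)
        h = 2e-4

        def m_eq(B):
            return mp * langevin(mp * B / (KB * env318.T))

        d2 = (m_eq(p.H0 + h) - 2 * m_eq(p.H0) + m_eq(p.H0 - h)) / h**2
        assert m1 == pytest.approx(-0.5 * p.H1 * p.H2 * d2, rel=1e-3)


class TestMixingSpectrum:
    def test_delta_distribution_limit(self, exp_protocol, grid, material, env318):
        H0 = np.array([5e-3, 15e-3])
        dist = SizeDistribution(d0=9e-9, sigma=1e-6, Np=3.0)
        spec = mixing_spectrum(dist, exp_protocol, grid, material, env318, H0)
        for n in (1, 2, 3, 4):
            for j, h in enumerate(H0):
                single = mixing_component_single(
                    9e-9, n, exp_protocol.with_offset(h), grid, material, env318
                )
                assert spec.component(n)[j].real == pytest.approx(
                    3.0 * single, rel=1e-4
                )

    def test_linear_in_particle_count(self, nanomag, exp_protocol, grid, material, env318):
        H0 = np.array([10e-3])
        s1 = mixing_spectrum(nanomag, exp_protocol, grid, material, env318, H0)
        s2 = mixing_spectrum(
            replace(nanomag, Np=2.0), exp_protocol, grid, material, env318, H0
        )
        assert np.allclose(s2.components, 2 * s1.components, rtol=1e-12)

    def test_no_mixing_without_both_tones(self, nanomag, grid, material, env318, exp_protocol):
        H0 = np.array([10e-3])
        full = mixing_spectrum(nanomag, exp_protocol, grid, material, env318, H0)
        scale = np.abs(full.components.real).max()
        for zeroed in ({"H1": 0.0}, {"H2": 0.0}):
            p = replace(exp_protocol, **zeroed)
            spec = mixing_spectrum(nanomag, p, grid, material, env318, H0)
            assert np.abs(spec.components.real).max() < 1e-8 * scale

    def test_sampling_convergence(self, nanomag, exp_protocol, grid, material, env318):
        """Doubling the per-period sampling changes components by < 0.1%."""
        H0 = np.array([15e-3])
        fine = DemodGrid(steps_per_hf_period=20)
        a = mixing_spectrum(nanomag, exp_protocol, grid, material, env318, H0)
        b = mixing_spectrum(nanomag, exp_protocol, fine, material, env318, H0)
        for n in (1, 2, 3, 4):
            ra, rb = a.component(n)[0].real, b.component(n)[0].real
            assert ra == pytest.approx(rb, rel=1e-3)

    def test_normalize(self, nanomag, exp_protocol, grid, material, env318):
        spec = mixing_spectrum(
            nanomag, exp_protocol, grid, material, env318, np.linspace(0, 24e-3, 13)
        )
        normed = spec.normalize()
        assert np.allclose(np.abs(normed.components).max(axis=1), 1.0)

    def test_empty_grid_rejected(self, nanomag, exp_protocol, grid, material, env318):
        with pytest.raises(ValueError):
            mixing_spectrum(nanomag, exp_protocol, grid, material, env318, np.array([]))


class TestSignalFraction:
    def test_full_range_is_one(self, nanomag, exp_protocol, grid, material, env318):
        assert signal_fraction(0.0, 1, nanomag, exp_protocol, grid, material, env318) == 1.0

    def test_non_increasing(self, nanomag, exp_protocol, grid, material, env318):
        dmins = np.array([4, 7, 9, 12, 16]) * 1e-9
        vals = [
            signal_fraction(d, 1, nanomag, exp_protocol, grid, material, env318)
            for d in dmins
        ]
        assert np.all(np.diff(vals) < 0)

    def test_threshold_roundtrip(self, nanomag, exp_protocol, grid, material, env318):
        for frac in (0.90, 0.99):
            d = threshold_for_signal_fraction(
                frac, 1, nanomag, exp_protocol, grid, material, env318
            )
            back = signal_fraction(d, 1, nanomag, exp_protocol, grid, material, env318)
            assert back == pytest.approx(frac, rel=1e-6)

    def test_chains_with_reverse_cdf(self, nanomag, exp_protocol, grid, material, env318):
        """The particle-count tail at the 90%-signal cutoff is ~a tenth."""
        d90 = threshold_for_signal_fraction(
            0.90, 1, nanomag, exp_protocol, grid, material, env318
        )
        tail = reverse_cdf(d90, nanomag)
        assert 0.08 < tail < 0.14

    def test_bad_fraction_rejected(self, nanomag, exp_protocol, grid, material, env318):
        with pytest.raises(ValueError):
            threshold_for_signal_fraction(
                1.5, 1, nanomag, exp_protocol, grid, material, env318
            )
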