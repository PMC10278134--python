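"""Vibronic chain: couplings, spectral density, g(t), lineshapes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from blufspec import (
    VibronicCoupling,
    auto_time_grid,
    build_spectral_density,
    compute_modes,
    gradient_with_couplings,
    homogeneous_spectrum,
    lineshape_g,
    vg_couplings,
)
from blufspec.errors import TruncationError, ValidationError
from blufspec.units import CM1_TO_EV, HBAR_EV_FS, KB_EV, cm1_to_rad_per_fs


def single_mode(w_cm1=1500.0, s=1.0):
    return VibronicCoupling(
        np.array([0]), np.array([w_cm1]), np.array([s]), np.array([])
    )


class TestVgCouplings:
    def test_zero_gradient_gives_zero_couplings(self, water_like):
        h, m, c = water_like
        nm = compute_modes(h, m, c)
        coup = vg_couplings(np.zeros(9), nm)
        assert np.all(coup.huang_rhys == 0.0)
        assert coup.reorganization_energy_ev == 0.0

    def test_unit_huang_rhys_closed_form(self, diatomic_modes):
        """Gradient built to give S=1 analytically is recovered to 1e-9."""
        grad = gradient_with_couplings(diatomic_modes, {0: 1.0})
        coup = vg_couplings(grad, diatomic_modes)
        assert coup.huang_rhys[0] == pytest.approx(1.0, abs=1e-9)

    def test_doubling_gradient_quadruples_s(self, water_like):
        h, m, c = water_like
        nm = compute_modes(h, m, c)
        grad = gradient_with_couplings(nm, {0: 0.3, 1: 0.1})
        s1 = vg_couplings(grad, nm).huang_rhys
        s2 = vg_couplings(2.0 * grad, nm).huang_rhys
        assert s2 == pytest.approx(4.0 * s1, rel=1e-12)

    def test_dimension_mismatch_rejected(self, diatomic_modes):
        with pytest.raises(ValidationError):
            vg_couplings(np.zeros(5), diatomic_modes)

    def test_lambda_equals_sum_of_per_mode_lambdas(self, water_like):
        h, m, c = water_like
        nm = compute_modes(h, m, c)
        coup = vg_couplings(gradient_with_couplings(nm, {0: 0.2, 2: 0.5}), nm)
        assert coup.reorganization_energy_ev == pytest.approx(
            coup.lambda_per_mode_ev.sum(), rel=0
        )


class TestSpectralDensity:
    def test_single_mode_reorganization_quadrature(self):
        dens = build_spectral_density(single_mode(1000.0, 1.0), width=1.0)
        lam_grid = dens.reorganization_energy_from_grid_ev()
        assert lam_grid == pytest.approx(1000.0 * CM1_TO_EV, rel=1e-3)

    def test_linearity_in_modes(self):
        d1 = build_spectral_density(single_mode(800.0, 0.5), width=2.0)
        d2 = build_spectral_density(single_mode(1400.0, 0.3), width=2.0, grid=d1.grid_cm1)
        both = VibronicCoupling(
            np.array([0, 1]),
            np.array([800.0, 1400.0]),
            np.array([0.5, 0.3]),
            np.array([]),
        )
        d12 = build_spectral_density(both, width=2.0, grid=d1.grid_cm1)
        assert d12.j_cm1 == pytest.approx(d1.j_cm1 + d2.j_cm1, rel=1e-12)

    def test_sticks_keep_exact_reorganization_energy(self):
        dens = build_spectral_density(single_mode(1000.0, 2.0), width=50.0)
        assert dens.reorganization_energy_ev == pytest.approx(
            2.0 * 1000.0 * CM1_TO_EV, rel=0
        )

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_reorganization_conserved_through_broadening(self, seed):
        """(1/pi) int J/omega domega recovers sum S_j hbar omega_j to 1e-4."""
        rng = np.random.default_rng(seed)
        n = 50
        freqs = rng.uniform(200.0, 1800.0, n)
        s = rng.uniform(0.0, 0.5, n)
        coup = VibronicCoupling(np.arange(n), freqs, s, np.array([]))
        dens = build_spectral_density(coup, width=1.0)
        assert dens.reorganization_energy_from_grid_ev() == pytest.approx(
            dens.reorganization_energy_ev, rel=1e-4
        )

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValidationError):
            build_spectral_density(single_mode(), width=0.0)


class TestLineshape:
    def test_zero_coupling_gives_zero_g(self):
        dens = build_spectral_density(single_mode(1500.0, 0.0), width=1.0)
        g = lineshape_g(dens, 300.0, np.linspace(0, 100, 64)).g
        assert np.allclose(g, 0.0)

    def test_single_mode_t0_closed_form(self):
        """g(t) = S(1 - e^{-i w t}) - i S w t at T = 0, pointwise 1e-6."""
        s, w_cm1 = 0.8, 1200.0
        dens = build_spectral_density(single_mode(w_cm1, s), width=1.0)
        t = np.linspace(0.0, 200.0, 512)
        g = lineshape_g(dens, 0.0, t).g
        w = cm1_to_rad_per_fs(w_cm1)
        exact = s * (1.0 - np.exp(-1j * w * t)) - 1j * s * w * t
        assert np.abs(g - exact).max() < 1e-6

    def test_grid_quadrature_matches_sticks(self):
        dens = build_spectral_density(single_mode(1000.0, 0.5), width=1.0)
        t = np.linspace(0.0, 50.0, 256)
        g_sticks = lineshape_g(dens, 300.0, t, method="sticks").g
        g_grid = lineshape_g(dens, 300.0, t, method="grid").g
        assert np.abs(g_sticks - g_grid).max() < 1e-3 * max(1.0, np.abs(g_sticks).max())

    def test_high_temperature_short_time_expansion(self):
        """Re g -> (lambda kB T / hbar^2) t^2 at early times, within 1%."""
        s, w_cm1 = 1.0, 500.0
        lam = s * w_cm1 * CM1_TO_EV
        temp = 20.0 * w_cm1 * CM1_TO_EV / KB_EV
        dens = build_spectral_density(single_mode(w_cm1, s), width=1.0)
        t = np.linspace(0.0, 0.5, 64)  # well inside one vibrational period
        g = lineshape_g(dens, temp, t).g
        expected = lam * KB_EV * temp * t**2 / HBAR_EV_FS**2
        mask = t > 0
        assert np.abs(g.real[mask] / expected[mask] - 1.0).max() < 0.01

    def test_nonuniform_time_grid_rejected(self):
        dens = build_spectral_density(single_mode(), width=1.0)
        with pytest.raises(ValidationError):
            lineshape_g(dens, 300.0, np.array([0.0, 1.0, 3.0]))


class TestHomogeneousSpectrum:
    def test_zero_g_gives_lorentzian(self):
        """Pure damping yields a Lorentzian of half-width gamma at E_vert."""
        dens = build_spectral_density(single_mode(1500.0, 0.0), width=1.0)
        gamma = 1e-3
        t = auto_time_grid(dens, 0.0, gamma)
        g = lineshape_g(dens, 0.0, t)
        grid = np.linspace(2.2, 4.2, 8001)
        spec = homogeneous_spectrum(g, 3.2, grid, gamma)
        lor = (gamma / math.pi) / ((grid - 3.2) ** 2 + gamma**2)
        lor /= np.trapezoid(lor, grid)
        peak_region = np.abs(grid - 3.2) < 0.05
        assert spec.intensity[peak_region] == pytest.approx(
            lor[peak_region], rel=0.01
        )

    def test_poisson_progression_intensities(self):
        """T=0 displaced oscillator: integrated peaks follow e^-S S^n/n!."""
        s, w_cm1, gamma = 1.0, 1500.0, 5e-4
        dens = build_spectral_density(single_mode(w_cm1, s), width=1.0)
        t = auto_time_grid(dens, 0.0, gamma)
        g = lineshape_g(dens, 0.0, t)
        lam = s * w_cm1 * CM1_TO_EV
        grid = np.linspace(3.2 - 1.2, 3.2 + 1.8, 15001)
        spec = homogeneous_spectrum(g, 3.2, grid, gamma)
        hw = w_cm1 * CM1_TO_EV
        for n in range(6):
            center = 3.2 - lam + n * hw
            m = np.abs(grid - center) < hw / 2
            got = np.trapezoid(spec.intensity[m], grid[m])
            assert got == pytest.approx(
                math.exp(-s) * s**n / math.factorial(n), abs=0.01
            )

    @pytest.mark.parametrize("s,temp", [(0.3, 0.0), (1.0, 300.0), (2.0, 600.0)])
    def test_first_moment_equals_vertical_energy(self, s, temp):
        dens = build_spectral_density(single_mode(1400.0, s), width=1.0)
        gamma = 1e-3
        t = auto_time_grid(dens, temp, gamma)
        g = lineshape_g(dens, temp, t)
        grid = np.linspace(1.2, 5.2, 8001)
        spec = homogeneous_spectrum(g, 3.2, grid, gamma)
        assert abs(spec.first_moment() - 3.2) < grid[1] - grid[0]

    def test_area_invariant_under_grid_refinement(self):
        dens = build_spectral_density(single_mode(1500.0, 0.5), width=1.0)
        gamma = 1e-3
        t = auto_time_grid(dens, 300.0, gamma)
        g = lineshape_g(dens, 300.0, t)
        areas = []
        for n in (4001, 8001, 16001):
            grid = np.linspace(1.7, 4.7, n)
            areas.append(homogeneous_spectrum(g, 3.2, grid, gamma).area())
        assert areas[1] == pytest.approx(areas[0], rel=1e-4)
        assert areas[2] == pytest.approx(areas[1], rel=1e-4)

    def test_narrow_grid_raises_truncation(self):
        dens = build_spectral_density(single_mode(1500.0, 1.0), width=1.0)
        gamma = 1e-3
        t = auto_time_grid(dens, 0.0, gamma)
        g = lineshape_g(dens, 0.0, t)
        with pytest.raises(TruncationError):
            homogeneous_spectrum(g, 3.2, np.linspace(3.15, 3.25, 501), gamma)
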