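"""Vertical-gradient vibronic model and second-order cumulant lineshapes.

The chain implemented here is the standard post-processing route from a
ground-state normal-mode analysis plus an excited-state energy gradient to
a homogeneous absorption lineshape:

1.  Project the mass-weighted excited-state gradient on each normal mode
    to get Huang-Rhys factors ``S_j = g_j^2 / (2 hbar omega_j^3)`` and
    per-mode reorganization energies ``lambda_j = S_j hbar omega_j``.
2.  Collect them into a spectral density
    ``J(omega) = pi sum_j S_j omega_j^2 B(omega - omega_j)``
    with a unit-area broadening kernel ``B``.
3.  Build the second-order cumulant lineshape function

        g(t) = (1/pi) int_0^inf domega J(omega)/omega^2
               [coth(hbar omega / 2 kB T)(1 - cos omega t)
                + i (sin omega t - omega t)]

4.  Fourier-transform ``exp(-g(t) - gamma t / hbar)`` to the absorption
    lineshape, normalized to unit area.

Conventions: the vertical excitation energy sits at the spectrum's first
moment; the 0-0 line is at ``E_vert - lambda``.  For a single displaced
mode at T=0 the result is the Franck-Condon Poisson progression with
weights ``exp(-S) S^n / n!``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, TruncationError, ValidationError
from .normal_modes import NormalModeSet
from .units import (
    CM1_TO_EV,
    HBAR_EV_FS,
    KB_EV,
    cm1_to_rad_per_fs,
    huang_rhys,
)

__all__ = [
    "VibronicCoupling",
    "SpectralDensity",
    "Lineshape",
    "Spectrum",
    "vg_couplings",
    "build_spectral_density",
    "lineshape_g",
    "auto_time_grid",
    "homogeneous_spectrum",
    "default_energy_grid",
]


@dataclass
class VibronicCoupling:
    """Per-mode Huang-Rhys factors and reorganization energies."""

    mode_indices: np.ndarray  # indices into the source NormalModeSet
    frequencies_cm1: np.ndarray
    huang_rhys: np.ndarray  # dimensionless S_j >= 0
    excluded_modes: np.ndarray  # indices dropped by the low-frequency cutoff

    @property
    def lambda_per_mode_ev(self) -> np.ndarray:
        return self.huang_rhys * self.frequencies_cm1 * CM1_TO_EV

    @property
    def reorganization_energy_ev(self) -> float:
        return float(np.sum(self.lambda_per_mode_ev))


@dataclass
class SpectralDensity:
    """Broadened spectral density J(omega) plus the underlying sticks.

    ``grid_cm1``/``j_cm1`` hold the broadened density (both in cm^-1:
    J inherits the energy unit of omega).  ``stick_freqs_cm1`` and
    ``stick_s`` keep the discrete (omega_j, S_j) pairs so that downstream
    quadrature can use exact per-mode closed forms.
    """

    grid_cm1: np.ndarray
    j_cm1: np.ndarray
    stick_freqs_cm1: np.ndarray
    stick_s: np.ndarray
    kind: str = "gaussian"
    width_cm1: float = 0.0

    @property
    def reorganization_energy_ev(self) -> float:
        """lambda = sum_j S_j hbar omega_j from the sticks, in eV."""
        return float(np.sum(self.stick_s * self.stick_freqs_cm1)) * CM1_TO_EV

    def reorganization_energy_from_grid_ev(self) -> float:
        """lambda = (1/pi) int J(omega)/omega domega from the broadened grid."""
        integrand = np.zeros_like(self.grid_cm1)
        nz = self.grid_cm1 > 0
        integrand[nz] = self.j_cm1[nz] / self.grid_cm1[nz]
        return float(np.trapezoid(integrand, self.grid_cm1) / math.pi) * CM1_TO_EV


@dataclass
class Lineshape:
    """Complex cumulant lineshape function g(t) on a uniform time grid (fs)."""

    t_fs: np.ndarray
    g: np.ndarray
    temperature: float

    def __post_init__(self) -> None:
        self.t_fs = np.asarray(self.t_fs, dtype=float)
        self.g = np.asarray(self.g, dtype=complex)


@dataclass
class Spectrum:
    """Absorption spectrum on an energy grid (eV)."""

    energy_ev: np.ndarray
    intensity: np.ndarray
    normalized: bool = False
    kind: str = "homogeneous"  # homogeneous | inhomogeneous | aligned
    e_vert: float | None = None

    def __post_init__(self) -> None:
        self.energy_ev = np.asarray(self.energy_ev, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.energy_ev))

    def first_moment(self) -> float:
        a = self.area()
        if a == 0.0:
            raise NumericalError("zero-area spectrum has no first moment")
        return float(np.trapezoid(self.energy_ev * self.intensity, self.energy_ev) / a)

    def variance(self) -> float:
        mu = self.first_moment()
        return float(
            np.trapezoid((self.energy_ev - mu) ** 2 * self.intensity, self.energy_ev)
            / self.area()
        )

    def normalize(self) -> "Spectrum":
        a = self.area()
        if a <= 0.0:
            raise NumericalError("cannot normalize a non-positive-area spectrum")
        return Spectrum(
            self.energy_ev, self.intensity / a, True, self.kind, self.e_vert
        )


def vg_couplings(gradient: np.ndarray, modes: NormalModeSet) -> VibronicCoupling:
    """Huang-Rhys factors from an excited-state gradient (vertical gradient).

    Parameters
    ----------
    gradient
        Cartesian excited-state energy gradient at the ground-state
        minimum, length 3N, hartree/bohr.
    modes
        Normal modes of the same geometry.  Modes at or below the
        low-frequency cutoff (and imaginary modes) are excluded and
        reported in ``excluded_modes``.
    """
    gradient = np.asarray(gradient, dtype=float)
    if gradient.shape != (3 * len(modes.masses),):
        raise ValidationError(
            f"gradient length {gradient.shape} does not match 3N={3 * len(modes.masses)}"
        )
    g_mw = gradient / np.repeat(np.sqrt(modes.masses), 3)
    keep = modes.retained
    idx = np.nonzero(keep)[0]
    freqs = modes.frequencies[idx]
    s = np.array(
        [huang_rhys(float(modes.modes[j] @ g_mw), f) for j, f in zip(idx, freqs)]
    )
    return VibronicCoupling(
        mode_indices=idx,
        frequencies_cm1=freqs,
        huang_rhys=s,
        excluded_modes=np.nonzero(~keep)[0],
    )


def build_spectral_density(
    coupling: VibronicCoupling,
    width: float,
    kind: str = "gaussian",
    grid: np.ndarray | None = None,
) -> SpectralDensity:
    """Broaden the discrete couplings into J(omega) on a wavenumber grid.

    ``width`` (cm^-1) is the standard deviation of the Gaussian kernel or
    the half-width at half-maximum of the Lorentzian.  The default grid
    covers [0, 1.2 max(omega_j)] with spacing width/8.
    """
    if width <= 0:
        raise ValidationError("broadening width must be positive")
    if kind not in ("gaussian", "lorentzian"):
        raise ValidationError(f"unknown broadening kind {kind!r}")
    if len(coupling.frequencies_cm1) == 0:
        raise ValidationError("coupling has no retained modes")
    omega_j = coupling.frequencies_cm1
    s_j = coupling.huang_rhys
    if grid is None:
        top = 1.2 * float(omega_j.max())
        step = width / 8.0
        grid = np.linspace(0.0, top, int(round(top / step)) + 1)
    grid = np.asarray(grid, dtype=float)
    j = np.zeros_like(grid)
    for w0, s in zip(omega_j, s_j):
        if kind == "gaussian":
            kern = np.exp(-0.5 * ((grid - w0) / width) ** 2) / (
                width * math.sqrt(2.0 * math.pi)
            )
        else:
            kern = (width / math.pi) / ((grid - w0) ** 2 + width**2)
        j += math.pi * s * w0**2 * kern
    return SpectralDensity(
        grid_cm1=grid,
        j_cm1=j,
        stick_freqs_cm1=omega_j.copy(),
        stick_s=s_j.copy(),
        kind=kind,
        width_cm1=width,
    )


def _coth_half_beta(omega_cm1: np.ndarray, temperature: float) -> np.ndarray:
    """coth(hbar omega / 2 kB T) with the T=0 limit coth -> 1."""
    if temperature <= 0.0:
        return np.ones_like(omega_cm1)
    x = omega_cm1 * CM1_TO_EV / (2.0 * KB_EV * temperature)
    return 1.0 / np.tanh(x)


def lineshape_g(
    density: SpectralDensity,
    temperature: float,
    t_fs: np.ndarray,
    method: str = "auto",
) -> Lineshape:
    """Second-order cumulant lineshape function on a uniform time grid.

    With ``method='sticks'`` (the default whenever sticks are available)
    each mode contributes its closed form

        S_j [ coth(hbar w_j / 2 kB T)(1 - cos w_j t) + i (sin w_j t - w_j t) ]

    which makes the quadrature exact.  ``method='grid'`` integrates the
    broadened J(omega) by the trapezoidal rule instead.
    """
    t_fs = np.asarray(t_fs, dtype=float)
    if len(t_fs) < 2:
        raise ValidationError("time grid needs at least two points")
    dt = np.diff(t_fs)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValidationError("time grid must be uniform")
    if temperature < 0:
        raise ValidationError("temperature must be >= 0")
    if method == "auto":
        method = "sticks" if len(density.stick_freqs_cm1) else "grid"
    if method == "sticks":
        g = np.zeros(len(t_fs), dtype=complex)
        coth = _coth_half_beta(density.stick_freqs_cm1, temperature)
        for w_cm1, s, c in zip(density.stick_freqs_cm1, density.stick_s, coth):
            w = cm1_to_rad_per_fs(w_cm1)
            wt = w * t_fs
            g += s * (c * (1.0 - np.cos(wt)) + 1j * (np.sin(wt) - wt))
    elif method == "grid":
        w_cm1 = density.grid_cm1
        nz = w_cm1 > 0
        w = cm1_to_rad_per_fs(w_cm1[nz])
        pref = density.j_cm1[nz] / w_cm1[nz] ** 2 / math.pi  # dimensionless density
        coth = _coth_half_beta(w_cm1[nz], temperature)
        wt = np.outer(t_fs, w)
        integrand = pref * (coth * (1.0 - np.cos(wt)) + 1j * (np.sin(wt) - wt))
        g = np.trapezoid(integrand, w_cm1[nz], axis=1)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return Lineshape(t_fs=t_fs, g=g, temperature=temperature)


def auto_time_grid(
    density: SpectralDensity,
    temperature: float,
    damping_ev: float,
    n_points: int = 2**15,
    envelope_floor: float = 1e-8,
    energy_span_ev: float = 8.0,
) -> np.ndarray:
    """Uniform time grid long enough that the damped envelope decays away.

    The extent is chosen so ``exp(-Re g(t) - gamma t / hbar)`` falls below
    ``envelope_floor`` at the final time; the pure-damping bound
    ``t_max = hbar ln(1/floor) / gamma`` serves as the ceiling.  The point
    count is raised above ``n_points`` if needed so the time step resolves
    a spectral window of ``energy_span_ev`` (the Fourier range of the
    spectrum is 2 pi hbar / dt).
    """
    if damping_ev <= 0:
        raise ValidationError("auto time grid requires positive damping")
    t_cap = HBAR_EV_FS * math.log(1.0 / envelope_floor) / damping_ev
    trial = np.linspace(0.0, t_cap, 2048)
    g = lineshape_g(density, temperature, trial).g
    env = np.exp(-g.real - damping_ev * trial / HBAR_EV_FS)
    # vibrational recurrences revive the envelope periodically: truncate
    # only where the whole tail (suffix maximum) has decayed
    tail_max = np.maximum.accumulate(env[::-1])[::-1]
    below = np.nonzero(tail_max < envelope_floor)[0]
    t_max = t_cap if len(below) == 0 else float(trial[below[0]])
    dt_max = 2.0 * math.pi * HBAR_EV_FS / energy_span_ev
    n = n_points
    while (n - 1) * dt_max < t_max and n < 2**22:
        n *= 2
    return np.linspace(0.0, t_max, n)


def default_energy_grid(
    e_vert: float, lam: float, step: float = 5e-4
) -> np.ndarray:
    """Energy grid spanning E_vert +/- max(5 lambda, 1 eV), step in eV."""
    half = max(5.0 * lam, 1.0)
    n = int(round(2.0 * half / step)) + 1
    return np.linspace(e_vert - half, e_vert + half, n)


def homogeneous_spectrum(
    lineshape: Lineshape,
    e_vert: float,
    grid: np.ndarray,
    damping: float = 1e-3,
) -> Spectrum:
    """Absorption lineshape from the cumulant g(t), normalized to unit area.

    sigma(E) proportional to Re int_0^tmax dt exp(i (E - E_vert) t / hbar
    - g(t) - gamma t / hbar), evaluated by trapezoidal quadrature on the
    lineshape's own time grid via a zero-padded FFT (padding only refines
    the energy sampling of the same quadrature sum), then interpolated
    onto the requested grid.  In this convention the spectrum's first
    moment equals ``e_vert`` (up to grid resolution).

    Raises
    ------
    TruncationError
        If the energy grid cuts off non-negligible intensity at its edges.
    """
    if damping < 0:
        raise ValidationError("damping must be >= 0")
    grid = np.asarray(grid, dtype=float)
    t = lineshape.t_fs
    dt = t[1] - t[0]
    weights = np.full(len(t), dt)
    weights[0] *= 0.5
    weights[-1] *= 0.5
    f = np.exp(-lineshape.g - damping * t / HBAR_EV_FS) * weights
    # FFT resolution at least 4x finer than both the requested grid and
    # the damping width, so interpolation error is negligible
    grid_step = float(np.min(np.diff(grid))) if len(grid) > 1 else 1e-3
    target = min(grid_step, damping if damping > 0 else grid_step) / 4.0
    n_fft = len(t)
    needed = 2.0 * math.pi * HBAR_EV_FS / (dt * target)
    while n_fft < needed and n_fft < 2**22:
        n_fft *= 2
    e_fft = e_vert + 2.0 * math.pi * HBAR_EV_FS * np.fft.fftfreq(n_fft, d=dt)
    sig_fft = (np.fft.ifft(f, n=n_fft) * n_fft).real
    order = np.argsort(e_fft)
    e_full, sig_full = e_fft[order], sig_fft[order]
    if grid[0] < e_full[0] or grid[-1] > e_full[-1]:
        raise ValidationError(
            f"energy grid [{grid[0]:.3f}, {grid[-1]:.3f}] eV exceeds the "
            f"Fourier range [{e_full[0]:.3f}, {e_full[-1]:.3f}] eV of the "
            "time grid; use a finer time step (larger energy_span_ev)"
        )
    sigma = np.interp(grid, e_full, sig_full)
    peak = sigma.max()
    if peak <= 0:
        raise NumericalError("homogeneous spectrum came out non-positive")
    if sigma.min() < -5e-3 * peak:
        raise NumericalError(
            "spectrum has significant negative intensity; refine the time grid"
        )
    sigma = np.clip(sigma, 0.0, None)
    # the requested window must capture 99.9% of the full-range area
    full_area = np.trapezoid(np.clip(sig_full, 0.0, None), e_full)
    inside = (e_full >= grid[0]) & (e_full <= grid[-1])
    captured = np.trapezoid(np.clip(sig_full[inside], 0.0, None), e_full[inside])
    if captured < 0.999 * full_area:
        raise TruncationError(
            f"energy grid too narrow: it contains {100 * captured / full_area:.2f}%"
            " of the spectral area (99.9% required)"
        )
    spec = Spectrum(grid, sigma, normalized=False, kind="homogeneous", e_vert=e_vert)
    return spec.normalize()
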