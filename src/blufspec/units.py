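"""Unit conventions and conversion constants.

External conventions follow the spectroscopy literature: Hessians in
hartree/bohr^2, Cartesian gradients in hartree/bohr, atomic masses in amu,
vibrational frequencies in cm^-1, electronic energies in eV, temperatures
in kelvin.  Internally, lineshape functions use femtoseconds for time so
that E/hbar products stay O(1).

All constants are CODATA-2018 values taken from :mod:`scipy.constants`
and frozen here to keep every conversion in one place.
"""

from __future__ import annotations

import math

from scipy import constants as _const

#: Hartree energy in joule.
HARTREE_J: float = _const.physical_constants["Hartree energy"][0]
#: Hartree energy in eV.
HARTREE_EV: float = _const.physical_constants["Hartree energy in eV"][0]
#: Bohr radius in metre.
BOHR_M: float = _const.physical_constants["Bohr radius"][0]
#: Atomic mass constant (amu) in kg.
AMU_KG: float = _const.physical_constants["atomic mass constant"][0]
#: Speed of light in cm/s.
C_CM_S: float = _const.c * 100.0
#: Speed of light in cm/fs.
C_CM_FS: float = C_CM_S * 1e-15
#: Reduced Planck constant in J s.
HBAR_JS: float = _const.hbar
#: Reduced Planck constant in eV s.
HBAR_EVS: float = _const.physical_constants["reduced Planck constant in eV s"][0]
#: Reduced Planck constant in eV fs.
HBAR_EV_FS: float = HBAR_EVS * 1e15
#: Boltzmann constant in eV/K.
KB_EV: float = _const.physical_constants["Boltzmann constant in eV/K"][0]
#: Photon energy of a 1 cm^-1 wavenumber, in eV (h c / 1 cm, over e).
CM1_TO_EV: float = _const.h * C_CM_S / _const.e

EV_TO_CM1: float = 1.0 / CM1_TO_EV


def hessian_eigval_to_cm1(eigval: float) -> float:
    """Convert a mass-weighted Hessian eigenvalue to a wavenumber.

    The eigenvalue carries units hartree/(bohr^2 amu); negative values
    (imaginary frequencies) are returned as negative wavenumbers.
    """
    omega_sq_si = eigval * HARTREE_J / (BOHR_M**2 * AMU_KG)  # rad^2/s^2
    nu = math.sqrt(abs(omega_sq_si)) / (2.0 * math.pi * C_CM_S)
    return -nu if eigval < 0 else nu


def cm1_to_rad_per_fs(wavenumber: float) -> float:
    """Angular frequency (rad/fs) of a vibrational wavenumber (cm^-1)."""
    return 2.0 * math.pi * C_CM_FS * wavenumber


def mode_gradient_for_s(s: float, wavenumber: float) -> float:
    """Mass-weighted mode gradient giving a target Huang-Rhys factor.

    Inverse of :func:`huang_rhys`: returns g in hartree/(bohr sqrt(amu))
    such that S = g^2 / (2 hbar omega^3) equals ``s`` at the given
    wavenumber (cm^-1).
    """
    omega_si = 2.0 * math.pi * C_CM_S * wavenumber
    g_si = math.sqrt(2.0 * HBAR_JS * omega_si**3 * s)
    return g_si / (HARTREE_J / (BOHR_M * math.sqrt(AMU_KG)))


def huang_rhys(g_mw: float, wavenumber: float) -> float:
    """Huang-Rhys factor from a mass-weighted mode gradient.

    Parameters
    ----------
    g_mw
        Excited-state gradient projected on the mode, in
        hartree/(bohr sqrt(amu)).
    wavenumber
        Mode frequency in cm^-1 (must be positive).

    Returns
    -------
    float
        Dimensionless S = g^2 / (2 hbar omega^3) evaluated in SI.
    """
    g_si = g_mw * HARTREE_J / (BOHR_M * math.sqrt(AMU_KG))
    omega_si = 2.0 * math.pi * C_CM_S * wavenumber
    return g_si**2 / (2.0 * HBAR_JS * omega_si**3)
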