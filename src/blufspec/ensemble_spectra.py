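"""Per-frame bright-state bookkeeping, inhomogeneous broadening, alignment.

An MD-sampled ensemble of vertical excitation energies carries the static
(inhomogeneous) part of the absorption broadening.  Each frame supplies
several excited states; the lowest is S1 and the "second bright" state,
called S2' to distinguish it from the (dark) adiabatic S2, is identified
per frame as the higher state with the largest oscillator strength.  The
homogeneous lineshape is convolved with the empirical energy distribution
of the chosen band, and computed spectra are aligned to a reference with
a single shift/scale pair determined on the first maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, ValidationError
from .vibronic import Spectrum

__all__ = [
    "FrameEnsemble",
    "select_bright_states",
    "inhomogeneous_spectrum",
    "sum_spectra",
    "find_first_maximum",
    "align_spectra",
]

_VALID_LIGHT_REPLICAS = {1, 2, 3}


@dataclass
class FrameEnsemble:
    """Per-frame excited-state energies/strengths for one protein state.

    Attributes
    ----------
    label
        'dark' or 'light'.
    replica
        Per-frame replica id; light-state frames must belong to one of
        three replicas.
    energies, osc_strengths
        Arrays of shape (n_frames, n_states), eV / dimensionless.
    s1_index, s2p_index
        Per-frame selected state indices (filled by
        :meth:`assign_bright_states`).
    """

    label: str
    replica: np.ndarray
    energies: np.ndarray
    osc_strengths: np.ndarray
    s1_index: np.ndarray | None = None
    s2p_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.energies = np.atleast_2d(np.asarray(self.energies, dtype=float))
        self.osc_strengths = np.atleast_2d(
            np.asarray(self.osc_strengths, dtype=float)
        )
        self.replica = np.asarray(self.replica, dtype=int)
        if self.label not in ("dark", "light"):
            raise ValidationError(f"state label must be dark|light, got {self.label!r}")
        if self.energies.shape != self.osc_strengths.shape:
            raise ValidationError("energies and oscillator strengths differ in shape")
        if len(self.replica) != self.n_frames:
            raise ValidationError("replica array length does not match frame count")
        if not np.all(np.isfinite(self.energies)) or np.any(self.energies <= 0):
            raise ValidationError("excitation energies must be finite and positive")
        if self.label == "light" and not set(self.replica).issubset(
            _VALID_LIGHT_REPLICAS
        ):
            raise ValidationError("light-state replica ids must be in {1, 2, 3}")

    @property
    def n_frames(self) -> int:
        return self.energies.shape[0]

    @property
    def n_states(self) -> int:
        return self.energies.shape[1]

    def assign_bright_states(self) -> "FrameEnsemble":
        """Select S1 and S2' for every frame (in place); returns self."""
        s1 = np.empty(self.n_frames, dtype=int)
        s2p = np.empty(self.n_frames, dtype=int)
        for i in range(self.n_frames):
            s1[i], s2p[i] = select_bright_states(
                self.energies[i], self.osc_strengths[i]
            )
        self.s1_index = s1
        self.s2p_index = s2p
        return self

    def band_energies(self, band: str) -> np.ndarray:
        """Per-frame energies of the selected band ('S1' or 'S2p')."""
        if band == "S1":
            idx = self.s1_index
        elif band in ("S2p", "S2'"):
            idx = self.s2p_index
        else:
            raise ValidationError(f"unknown band {band!r}; expected S1 or S2p")
        if idx is None:
            raise ValidationError(
                "bright states not assigned; call assign_bright_states() first"
            )
        return self.energies[np.arange(self.n_frames), idx]


def select_bright_states(
    energies: np.ndarray, osc_strengths: np.ndarray
) -> tuple[int, int]:
    """Identify S1 and the second bright state S2' for one frame.

    S1 is the lowest-energy state.  S2' is the state, among all others,
    carrying the largest oscillator strength — the per-frame assignment
    needed because that strength concentrates in different adiabatic
    states (S3 or S4) depending on the geometry.  Strength ties within
    1e-6 resolve to the lower-energy state with a warning.
    """
    energies = np.asarray(energies, dtype=float)
    osc = np.asarray(osc_strengths, dtype=float)
    if energies.ndim != 1 or len(energies) < 3:
        raise ValidationError("bright-state selection needs >= 3 states per frame")
    s1 = int(np.argmin(energies))
    rest = np.array([k for k in range(len(energies)) if k != s1])
    best_f = osc[rest].max()
    tied = rest[osc[rest] >= best_f - 1e-6]
    if len(tied) > 1:
        warnings.warn(
            "oscillator-strength tie for S2'; choosing the lower-energy state",
            stacklevel=2,
        )
    s2p = int(tied[np.argmin(energies[tied])])
    return s1, s2p


def inhomogeneous_spectrum(
    hom: Spectrum, ensemble: FrameEnsemble, band: str = "S1"
) -> Spectrum:
    """Convolve a homogeneous lineshape with the ensemble energy spread.

    Each frame contributes the homogeneous spectrum displaced by its
    vertical energy relative to the homogeneous reference energy
    (equal frame weights):

        sigma_inh(E) = (1/N) sum_f sigma_hom(E - (dE_f - E_vert))

    The shift is applied exactly in Fourier space on the homogeneous
    spectrum's own (uniform) grid, so the area is preserved and the
    output first moment equals the ensemble mean energy plus whatever
    offset the homogeneous lineshape carries relative to its E_vert.
    """
    if not hom.normalized:
        raise ValidationError("homogeneous spectrum must be normalized")
    if hom.e_vert is None:
        raise ValidationError("homogeneous spectrum lacks its vertical energy tag")
    if ensemble.n_frames == 0:
        raise ValidationError("ensemble is empty")
    energies = ensemble.band_energies(band)
    bad = np.nonzero(~np.isfinite(energies))[0]
    if len(bad):
        raise ValidationError(f"band {band} energies missing for frames {bad.tolist()}")
    grid = hom.energy_ev
    step = np.diff(grid)
    if not np.allclose(step, step[0], rtol=1e-9, atol=1e-15):
        raise ValidationError("homogeneous spectrum grid must be uniform")
    shifts = energies - hom.e_vert
    freqs = np.fft.fftfreq(len(grid), d=step[0])
    kernel = np.mean(np.exp(-2j * np.pi * np.outer(shifts, freqs)), axis=0)
    sigma = np.fft.ifft(np.fft.fft(hom.intensity) * kernel).real
    sigma = np.clip(sigma, 0.0, None)
    return Spectrum(
        grid.copy(),
        sigma,
        normalized=True,
        kind="inhomogeneous",
        e_vert=float(np.mean(energies)),
    )


def sum_spectra(spectra: list[Spectrum], grid: np.ndarray | None = None) -> Spectrum:
    """Sum spectra (e.g. the S1 and S2' bands) on a common energy grid."""
    if not spectra:
        raise ValidationError("no spectra to sum")
    if grid is None:
        lo = min(float(s.energy_ev[0]) for s in spectra)
        hi = max(float(s.energy_ev[-1]) for s in spectra)
        step = min(float(np.min(np.diff(s.energy_ev))) for s in spectra)
        grid = np.linspace(lo, hi, int(round((hi - lo) / step)) + 1)
    total = np.zeros_like(grid)
    for s in spectra:
        total += np.interp(grid, s.energy_ev, s.intensity, left=0.0, right=0.0)
    return Spectrum(grid, total, normalized=False, kind=spectra[0].kind)


def find_first_maximum(
    spec: Spectrum, grid_step: float = 1e-3, threshold: float = 0.05
) -> tuple[float, float]:
    """Lowest-energy local maximum above ``threshold`` of the global max.

    The spectrum is resampled on a uniform ``grid_step`` (eV) grid first,
    so the answer is defined to that resolution.

    Returns
    -------
    (energy, intensity) of the first maximum.
    """
    e = spec.energy_ev
    n = int(round((e[-1] - e[0]) / grid_step)) + 1
    if n < 3:
        raise AlignmentError("spectrum support too narrow for maximum detection")
    grid = e[0] + grid_step * np.arange(n)
    y = np.interp(grid, e, spec.intensity)
    floor = threshold * y.max()
    is_max = (y[1:-1] > y[:-2]) & (y[1:-1] >= y[2:]) & (y[1:-1] > floor)
    idx = np.nonzero(is_max)[0]
    if len(idx) == 0:
        raise AlignmentError("no local maximum above threshold found")
    i = idx[0] + 1
    return float(grid[i]), float(y[i])


def align_spectra(
    spectra: list[Spectrum],
    reference: Spectrum,
    subject: int = 0,
    grid_step: float = 1e-3,
) -> tuple[list[Spectrum], float, float]:
    """Shift/scale a family of computed spectra onto a reference.

    A single energy shift and intensity scale are determined by matching
    the first maximum of ``spectra[subject]`` to the first maximum of
    ``reference``; the same affine map is then applied to every spectrum,
    so all between-spectrum differences (peak offsets, relative
    intensities) are preserved.

    Returns
    -------
    (aligned spectra, shift_eV, scale)
    """
    if not spectra:
        raise ValidationError("no spectra to align")
    if not 0 <= subject < len(spectra):
        raise ValidationError(f"subject index {subject} out of range")
    e_ref, i_ref = find_first_maximum(reference, grid_step)
    e_sub, i_sub = find_first_maximum(spectra[subject], grid_step)
    if i_sub <= 0:
        raise AlignmentError("subject spectrum has non-positive first maximum")
    shift = e_ref - e_sub
    scale = i_ref / i_sub
    aligned = [
        Spectrum(
            s.energy_ev + shift,
            s.intensity * scale,
            normalized=False,
            kind="aligned",
            e_vert=None if s.e_vert is None else s.e_vert + shift,
        )
        for s in spectra
    ]
    return aligned, float(shift), float(scale)
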