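"""Mass-weighted normal-mode analysis.

Takes a Cartesian Hessian (hartree/bohr^2) and atomic masses (amu),
projects out rigid-body translations/rotations, and returns harmonic
frequencies in cm^-1 together with mass-weighted displacement vectors.
A bond-stretch assignment locates the mode with maximal overlap on a
given bond-elongation coordinate — the procedure used here to identify
the flavin C4=O4 carbonyl stretch among the modes of a binding pocket.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .units import hessian_eigval_to_cm1

#: Modes below this wavenumber (cm^-1) are excluded from vibronic couplings:
#: Huang-Rhys factors diverge as omega -> 0 under the vertical-gradient model.
LOW_FREQ_CUTOFF_CM1 = 10.0

#: Moment-of-inertia eigenvalue below this (amu A^2) counts as zero
#: when deciding whether a molecule is linear (5 vs 6 projected modes).
INERTIA_RANK_TOL = 1e-6


@dataclass
class NormalModeSet:
    """Vibrational frequencies and mass-weighted normal modes.

    ``frequencies`` holds one wavenumber per internal mode (3N - n_projected
    of them), sorted ascending; imaginary frequencies are stored as negative
    wavenumbers.  ``modes[j]`` is the unit-norm mass-weighted Cartesian
    displacement vector of mode j (length 3N).
    """

    frequencies: np.ndarray
    modes: np.ndarray
    masses: np.ndarray
    n_projected: int
    coords: np.ndarray | None = None
    low_freq_cutoff: float = LOW_FREQ_CUTOFF_CM1
    imaginary: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.modes = np.asarray(self.modes, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.imaginary = self.frequencies < 0.0

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)

    @property
    def retained(self) -> np.ndarray:
        """Boolean mask of modes above the low-frequency cutoff (real only)."""
        return self.frequencies > self.low_freq_cutoff


def _projection_basis(masses: np.ndarray, coords: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis (3N x k) spanning rigid translations and rotations."""
    n = len(masses)
    sqm = np.sqrt(masses)
    cols = []
    for axis in range(3):
        v = np.zeros(3 * n)
        v[axis::3] = sqm
        cols.append(v)
    if coords is not None:
        com = np.average(coords, axis=0, weights=masses)
        rel = coords - com
        # moment-of-inertia rank decides linear (2 nonzero) vs nonlinear (3)
        inertia = np.zeros((3, 3))
        for m, r in zip(masses, rel):
            inertia += m * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
        evals, evecs = np.linalg.eigh(inertia)
        n_rot = int(np.sum(evals > INERTIA_RANK_TOL))
        # rotation about each principal axis with nonzero inertia
        for k in range(3):
            if evals[k] <= INERTIA_RANK_TOL:
                continue
            axis_vec = evecs[:, k]
            v = np.zeros(3 * n)
            for i in range(n):
                v[3 * i : 3 * i + 3] = sqm[i] * np.cross(axis_vec, rel[i])
            cols.append(v)
        del n_rot
    basis = np.column_stack(cols)
    # orthonormalize, dropping numerically null columns (e.g. single atom)
    q, r = np.linalg.qr(basis)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())
    return q[:, keep]


def compute_modes(
    hessian: np.ndarray,
    masses: np.ndarray,
    coords: np.ndarray | None = None,
    low_freq_cutoff: float = LOW_FREQ_CUTOFF_CM1,
) -> NormalModeSet:
    """Diagonalize a mass-weighted Hessian after rigid-body projection.

    Parameters
    ----------
    hessian
        Cartesian second derivatives, shape (3N, 3N), hartree/bohr^2.
    masses
        Atomic masses, shape (N,), amu.
    coords
        Cartesian geometry (N, 3) in angstrom.  Required to project out
        rotations; with ``None`` only the three translations are removed.
    low_freq_cutoff
        Wavenumber below which modes are flagged for exclusion from
        vertical-gradient couplings.

    Returns
    -------
    NormalModeSet
        Frequencies (cm^-1, ascending; negative = imaginary) and unit-norm
        mass-weighted modes spanning the internal subspace.
    """
    hessian = np.asarray(hessian, dtype=float)
    masses = np.asarray(masses, dtype=float)
    n = len(masses)
    if hessian.shape != (3 * n, 3 * n):
        raise ValidationError(
            f"Hessian shape {hessian.shape} does not match 3N={3 * n}"
        )
    if np.any(masses <= 0):
        raise ValidationError("masses must be positive")
    scale = np.abs(hessian).max()
    if scale == 0.0:
        raise ValidationError("degenerate input: Hessian is identically zero")
    if np.abs(hessian - hessian.T).max() > 1e-8 * scale:
        raise ValidationError("Hessian is not symmetric within 1e-8 relative")

    sqm = np.repeat(np.sqrt(masses), 3)
    h_mw = hessian / np.outer(sqm, sqm)

    if coords is not None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (n, 3):
            raise ValidationError(f"coords shape {coords.shape}, expected ({n}, 3)")
    basis = _projection_basis(masses, coords)
    n_proj = basis.shape[1]

    # orthonormal complement of the rigid-body space
    proj = np.eye(3 * n) - basis @ basis.T
    evals_p, evecs_p = np.linalg.eigh(proj)
    comp = evecs_p[:, evals_p > 0.5]  # eigenvalues are 0 or 1
    h_int = comp.T @ h_mw @ comp
    h_int = 0.5 * (h_int + h_int.T)
    evals, evecs = np.linalg.eigh(h_int)
    modes = (comp @ evecs).T  # rows are modes, unit norm by construction
    freqs = np.array([hessian_eigval_to_cm1(ev) for ev in evals])
    order = np.argsort(freqs)
    return NormalModeSet(
        frequencies=freqs[order],
        modes=modes[order],
        masses=masses,
        n_projected=n_proj,
        coords=coords,
        low_freq_cutoff=low_freq_cutoff,
    )


def assign_bond_stretch(
    modes: NormalModeSet, atom_pair: tuple[int, int]
) -> tuple[int, float]:
    """Find the mode that best represents stretching of a given bond.

    The bond-elongation internal coordinate is expressed in mass-weighted
    Cartesians and normalized; the returned score is the absolute overlap
    with the winning mode, in [0, 1].  Ties within 1e-6 resolve to the
    lower-frequency mode with a warning.
    """
    if modes.n_modes == 0:
        raise ValidationError("mode set is empty")
    if modes.coords is None:
        raise ValidationError("bond assignment requires the geometry (coords)")
    a, b = atom_pair
    n = len(modes.masses)
    if not (0 <= a < n and 0 <= b < n) or a == b:
        raise ValidationError(f"invalid atom pair {atom_pair} for {n} atoms")
    bond = modes.coords[b] - modes.coords[a]
    norm = np.linalg.norm(bond)
    if norm < 1e-10:
        raise ValidationError("bond atoms coincide")
    e = bond / norm
    s = np.zeros(3 * n)
    s[3 * a : 3 * a + 3] = -e / np.sqrt(modes.masses[a])
    s[3 * b : 3 * b + 3] = e / np.sqrt(modes.masses[b])
    s /= np.linalg.norm(s)
    scores = np.abs(modes.modes @ s)
    best = int(np.argmax(scores))
    # deterministic tie-break: lowest frequency among near-equal scores
    tied = np.nonzero(scores >= scores[best] - 1e-6)[0]
    if len(tied) > 1:
        warnings.warn(
            f"bond-stretch assignment tie among modes {tied.tolist()}; "
            "choosing the lowest-frequency one",
            stacklevel=2,
        )
        best = int(tied[np.argmin(modes.frequencies[tied])])
    return best, float(scores[best])
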