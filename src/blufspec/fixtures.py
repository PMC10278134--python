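"""Seeded synthetic-data generators for every pipeline input.

These fixtures emulate the statistical structure of the study's inputs —
QM normal-mode/gradient records, MD-sampled excitation-energy ensembles
for a dark and a light protein state, and trajectories with known
hydrogen-bond fractions and helix/sheet geometries — at toy scale and
with analytically known answers, so every downstream operation can be
tested against its construction.

Defaults mirror the study conditions: four low-lying excited states with
dark-state means (3.20, 3.60, 3.95, 3.97) eV and light-state means
red-shifted by (0.07, 0.05, 0.05, 0.05) eV, per-frame standard
deviations back-derived from the published bootstrap confidence
intervals (~0.05 eV for S1, ~0.07 eV above), 200 frames per state, and
three light-state replicas.  Every generator takes one explicit seed and
keeps no global RNG state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ensemble_spectra import FrameEnsemble
from .errors import ValidationError
from .trajectory import TrajectoryView
from .units import mode_gradient_for_s

__all__ = [
    "FixtureConfig",
    "gen_toy_hessian",
    "gen_energy_ensemble",
    "gen_dark_light_pair",
    "gen_hb_trajectory",
    "gen_helix_pair",
    "gen_sheet_quad",
    "gradient_with_couplings",
]

_DEF_DARK_MEANS = (3.20, 3.60, 3.95, 3.97)
_DEF_LIGHT_MEANS = (3.13, 3.55, 3.90, 3.92)
_DEF_SDS = (0.05, 0.07, 0.07, 0.07)


@dataclass
class FixtureConfig:
    """Parameters of the synthetic ensemble/trajectory generators.

    ``energy_mean`` maps the state label to per-electronic-state mean
    vertical excitation energies (eV); ``energy_sd`` gives per-state
    Gaussian widths.  ``osc_strengths`` holds the strength-distribution
    parameters: S1 carries ``s1_mean``; exactly one of the two top states
    carries ``bright_mean`` per frame (a fair seeded coin), the other
    ``weak_mean``; the second state is always nearly dark.  With
    ``paired_noise`` the dark and light ensembles share their Gaussian
    draws, so the configured dark-light mean offset is carried exactly
    by the samples (common random numbers).
    """

    seed: int = 0
    n_frames: int = 200
    n_states: int = 4
    energy_mean: dict = field(
        default_factory=lambda: {
            "dark": list(_DEF_DARK_MEANS),
            "light": list(_DEF_LIGHT_MEANS),
        }
    )
    energy_sd: list = field(default_factory=lambda: list(_DEF_SDS))
    osc_strengths: dict = field(
        default_factory=lambda: {
            "s1_mean": 0.25,
            "dark_mean": 0.003,
            "bright_mean": 0.15,
            "weak_mean": 0.02,
            "sd": 0.01,
        }
    )
    hb_fraction: float = 0.85
    helix_angle: float = 25.0
    sheet_dihedral: float = 12.0
    paired_noise: bool = True

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not 0.0 <= self.hb_fraction <= 1.0:
            raise ValidationError("hb_fraction must lie in [0, 1]")
        if np.isscalar(self.energy_sd):
            self.energy_sd = [float(self.energy_sd)] * self.n_states
        if any(sd < 0 for sd in self.energy_sd):
            raise ValidationError("energy_sd must be >= 0")


def gen_toy_hessian(
    molecule_spec: dict, seed: int = 0, jitter: float = 0.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cartesian Hessian of a harmonic bond-spring network.

    ``molecule_spec`` is a mapping with ``masses`` (amu), ``positions``
    (N x 3, angstrom) and ``bonds`` as (i, j, k) triples with force
    constants in hartree/bohr^2.  Each bond contributes the textbook
    spring blocks ``k e e^T`` along its unit vector, so the Hessian is
    symmetric and translationally invariant by construction.  ``jitter``
    optionally displaces positions by seeded Gaussian noise of that
    amplitude (angstrom) before building the springs.

    Returns
    -------
    (hessian, masses, coords)
    """
    masses = np.asarray(molecule_spec["masses"], dtype=float)
    coords = np.asarray(molecule_spec["positions"], dtype=float).copy()
    bonds = molecule_spec["bonds"]
    n = len(masses)
    if n < 2:
        raise ValidationError("toy molecule needs at least 2 atoms")
    if coords.shape != (n, 3):
        raise ValidationError(f"positions shape {coords.shape}, expected ({n}, 3)")
    if jitter > 0:
        rng = np.random.default_rng(seed)
        coords = coords + jitter * rng.standard_normal(coords.shape)
    hess = np.zeros((3 * n, 3 * n))
    for i, j, k in bonds:
        if k <= 0:
            raise ValidationError(f"non-positive force constant on bond ({i}, {j})")
        e = coords[j] - coords[i]
        norm = np.linalg.norm(e)
        if norm < 1e-10:
            raise ValidationError(f"bonded atoms {i}, {j} coincide")
        e = e / norm
        block = k * np.outer(e, e)
        sl_i = slice(3 * i, 3 * i + 3)
        sl_j = slice(3 * j, 3 * j + 3)
        hess[sl_i, sl_i] += block
        hess[sl_j, sl_j] += block
        hess[sl_i, sl_j] -= block
        hess[sl_j, sl_i] -= block
    return hess, masses, coords


def _draw_strengths(cfg: FixtureConfig, rng: np.random.Generator) -> np.ndarray:
    p = cfg.osc_strengths
    f = np.abs(
        p["dark_mean"] + 0.1 * p["sd"] * rng.standard_normal((cfg.n_frames, cfg.n_states))
    )
    f[:, 0] = np.abs(p["s1_mean"] + p["sd"] * rng.standard_normal(cfg.n_frames))
    bright = rng.integers(cfg.n_states - 2, cfg.n_states, size=cfg.n_frames)
    weak = np.where(bright == cfg.n_states - 1, cfg.n_states - 2, cfg.n_states - 1)
    rows = np.arange(cfg.n_frames)
    f[rows, bright] = np.abs(p["bright_mean"] + p["sd"] * rng.standard_normal(cfg.n_frames))
    f[rows, weak] = np.abs(p["weak_mean"] + p["sd"] * rng.standard_normal(cfg.n_frames))
    return f


def _replicas(label: str, n_frames: int) -> np.ndarray:
    if label == "dark":
        return np.ones(n_frames, dtype=int)
    return 1 + (np.arange(n_frames) % 3)


def gen_energy_ensemble(
    cfg: FixtureConfig,
    state: str = "dark",
    noise: np.ndarray | None = None,
) -> FrameEnsemble:
    """Gaussian per-frame, per-state excitation-energy ensemble.

    Energies for electronic state s are drawn as
    ``mean[state][s] + sd[s] * z`` with standard-normal ``z``; oscillator
    strengths are drawn so that exactly one of the two top states is
    bright in each frame.  ``noise`` injects pre-drawn z-scores (used for
    common-random-number dark/light pairs).
    """
    if cfg.n_states < 2:
        raise ValidationError("energy ensembles need at least 2 states")
    if state not in cfg.energy_mean:
        raise ValidationError(f"no configured means for state {state!r}")
    means = np.asarray(cfg.energy_mean[state], dtype=float)
    if len(means) != cfg.n_states:
        raise ValidationError(
            f"{len(means)} means configured for n_states={cfg.n_states}"
        )
    sds = np.asarray(cfg.energy_sd, dtype=float)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 0 if state == "dark" else 1])
    )
    if noise is None:
        noise = rng.standard_normal((cfg.n_frames, cfg.n_states))
    energies = means[None, :] + sds[None, :] * noise
    osc = _draw_strengths(cfg, rng)
    return FrameEnsemble(
        label=state,
        replica=_replicas(state, cfg.n_frames),
        energies=energies,
        osc_strengths=osc,
    ).assign_bright_states()


def gen_dark_light_pair(cfg: FixtureConfig) -> tuple[FrameEnsemble, FrameEnsemble]:
    """Dark and light ensembles, sharing Gaussian draws when paired."""
    noise = None
    if cfg.paired_noise:
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
        noise = rng.standard_normal((cfg.n_frames, cfg.n_states))
    dark = gen_energy_ensemble(cfg, "dark", noise=noise)
    light = gen_energy_ensemble(cfg, "light", noise=noise)
    return dark, light


def _rigid_motions(
    coords: np.ndarray, rng: np.random.Generator, amplitude: float = 5.0
) -> np.ndarray:
    """Apply an independent random rotation + translation to every frame."""
    from scipy.spatial.transform import Rotation

    out = np.empty_like(coords)
    for i in range(coords.shape[0]):
        rot = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
        out[i] = coords[i] @ rot.as_matrix().T + amplitude * rng.uniform(-1, 1, 3)
    return out


def gen_hb_trajectory(cfg: FixtureConfig, rigid_motion: bool = True) -> TrajectoryView:
    """Donor-hydrogen-acceptor triad with an exactly known H-bond fraction.

    Bonded frames put the acceptor 2.9 A from the donor on a linear
    D-H...A axis (0.3 A inside the 3.2 A cutoff, 45 deg inside the
    135 deg one); unbonded frames use a 3.47 A donor-acceptor distance
    and a 100 deg angle at the hydrogen, both outside their cutoffs by
    more than the 0.2 A / 10 deg safety margins.  Exactly
    ``round(hb_fraction * n_frames)`` frames are bonded, scattered by a
    seeded shuffle; a per-frame rigid motion (rotation + translation)
    leaves every metric invariant but avoids trivially static geometry.
    """
    n = cfg.n_frames
    bonded_geo = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.9, 0.0, 0.0]])
    # broken: acceptor 3.5 A from the hydrogen at 100 deg to the H->D axis
    alpha = math.radians(80.0)
    broken_geo = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [1.0 + 3.5 * math.cos(alpha), 3.5 * math.sin(alpha), 0.0],
        ]
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    n_bonded = int(round(cfg.hb_fraction * n))
    order = rng.permutation(n)
    coords = np.empty((n, 3, 3))
    coords[order[:n_bonded]] = bonded_geo
    coords[order[n_bonded:]] = broken_geo
    if rigid_motion:
        coords = _rigid_motions(coords, rng)
    return TrajectoryView(
        coords=coords,
        atom_names=["ND2", "HD21", "O4"],
        res_names=["ASN", "ASN", "FMN"],
        res_ids=np.array([45, 45, 200]),
    )


def _ideal_helix(n_res: int, radius: float = 2.3, rise: float = 1.5) -> np.ndarray:
    """C-alpha trace of a canonical alpha-helix along +z (100 deg twist)."""
    theta = np.radians(100.0) * np.arange(n_res)
    return np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n_res)]
    )


def gen_helix_pair(
    angle: float, n_frames: int = 1, n_res: int = 22, seed: int = 0,
    rigid_motion: bool = False,
) -> TrajectoryView:
    """Two ideal alpha-helix C-alpha traces enclosing a given axis angle.

    The second helix is the first rotated about y by ``angle`` and
    displaced sideways.  With 22 residues the two 4-residue terminal
    windows sit 18 residues apart (18 x 100 deg = 5 full turns), so
    their centroids carry identical off-axis offsets and the
    centroid-difference vector reproduces the helix axis — and hence the
    requested angle — exactly.
    """
    if not 0.0 <= angle <= 180.0:
        raise ValidationError("helix angle must lie in [0, 180] degrees")
    h1 = _ideal_helix(n_res)
    a = math.radians(angle)
    rot_y = np.array(
        [[math.cos(a), 0.0, math.sin(a)], [0.0, 1.0, 0.0], [-math.sin(a), 0.0, math.cos(a)]]
    )
    h2 = h1 @ rot_y.T + np.array([12.0, 0.0, 0.0])
    coords = np.tile(np.vstack([h1, h2])[None], (n_frames, 1, 1))
    if rigid_motion:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
        coords = _rigid_motions(coords, rng)
    return TrajectoryView(
        coords=coords,
        atom_names=["CA"] * (2 * n_res),
        res_names=["ALA"] * (2 * n_res),
        res_ids=np.concatenate([np.arange(1, n_res + 1), np.arange(101, 101 + n_res)]),
    )


def gen_sheet_quad(
    dihedral: float, n_frames: int = 1, seed: int = 0, rigid_motion: bool = False
) -> TrajectoryView:
    """Four C-alpha atoms with an exactly prescribed signed torsion.

    Uses the standard construction with the central bond along x; the
    residue numbering mirrors the beta-sheet corners tracked in the
    dark/light comparison (Ser18, Leu50, Gly59, Glu89).
    """
    phi = math.radians(dihedral)
    r = 1.5
    quad = np.array(
        [
            [0.0, r, 0.0],
            [0.0, 0.0, 0.0],
            [1.5, 0.0, 0.0],
            [1.5, r * math.cos(phi), r * math.sin(phi)],
        ]
    )
    coords = np.tile(quad[None], (n_frames, 1, 1))
    if rigid_motion:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 5]))
        coords = _rigid_motions(coords, rng)
    return TrajectoryView(
        coords=coords,
        atom_names=["CA"] * 4,
        res_names=["SER", "LEU", "GLY", "GLU"],
        res_ids=np.array([18, 50, 59, 89]),
    )


def gradient_with_couplings(modes, s_by_mode: dict[int, float]) -> np.ndarray:
    """Cartesian excited-state gradient realizing target Huang-Rhys factors.

    ``s_by_mode`` maps mode indices (into the NormalModeSet) to the
    desired dimensionless S; all other modes get zero coupling.  The
    returned gradient is in hartree/bohr, ready for ``vg_couplings``.
    """
    g_mw = np.zeros(modes.modes.shape[1])
    for j, s in s_by_mode.items():
        w = modes.frequencies[j]
        if w <= 0:
            raise ValidationError(f"mode {j} has non-positive frequency {w}")
        g_mw += mode_gradient_for_s(s, w) * modes.modes[j]
    return g_mw * np.repeat(np.sqrt(modes.masses), 3)
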