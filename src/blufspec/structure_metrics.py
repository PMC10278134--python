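"""Trajectory geometry metrics for dark/light structural comparison.

Implements the collective coordinates used to characterize the
light-induced state of a BLUF domain: hydrogen-bond occupancy with
distance/angle cutoffs, the interhelical angle between the two
alpha-helices, the beta-sheet twist dihedral over four C-alpha atoms,
and backbone RMSD after optimal superposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import DegenerateGeometryError, ValidationError
from .trajectory import TrajectoryView

__all__ = [
    "HBondSpec",
    "HelixVectorSpec",
    "DihedralSpec",
    "hbond_occupancy",
    "interhelical_angle",
    "sheet_dihedral",
    "backbone_rmsd",
    "metric_distributions",
]


@dataclass
class HBondSpec:
    """Donor/hydrogen/acceptor selectors plus geometric cutoffs.

    A frame counts as hydrogen-bonded when the donor-acceptor distance is
    at most ``distance_cutoff`` (default 3.2 A) and the angle at the
    configured vertex (default: donor-hydrogen...acceptor, vertex on the
    hydrogen) is at least ``angle_cutoff`` (default 135 deg).  The vertex
    is configurable because the cutoff pair is quoted in the literature
    with more than one angle convention.
    """

    donor: dict
    hydrogen: dict
    acceptor: dict
    distance_cutoff: float = 3.2
    angle_cutoff: float = 135.0
    angle_vertex: str = "hydrogen"  # hydrogen | acceptor

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValidationError("cutoffs must be positive")
        if self.angle_cutoff > 180.0:
            raise ValidationError("angle cutoff cannot exceed 180 degrees")
        if self.angle_vertex not in ("hydrogen", "acceptor"):
            raise ValidationError("angle_vertex must be 'hydrogen' or 'acceptor'")


@dataclass
class HelixVectorSpec:
    """Two helices, each given by 4 starting + 4 ending C-alpha residues."""

    helix1_start: list[int]
    helix1_end: list[int]
    helix2_start: list[int]
    helix2_end: list[int]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        for name in ("helix1_start", "helix1_end", "helix2_start", "helix2_end"):
            if len(getattr(self, name)) != 4:
                raise ValidationError(f"{name} must list exactly 4 residues")


@dataclass
class DihedralSpec:
    """Four ordered C-alpha atoms defining a signed torsion."""

    residues: list[int]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        if len(self.residues) != 4 or len(set(self.residues)) != 4:
            raise ValidationError("dihedral needs 4 distinct residues")


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Angle between vectors along the last axis, degrees in [0, 180]."""
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-10) or np.any(n2 < 1e-10):
        raise DegenerateGeometryError("zero-length vector in angle computation")
    cosang = np.clip(np.sum(v1 * v2, axis=-1) / (n1 * n2), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def hbond_occupancy(
    traj: TrajectoryView, spec: HBondSpec
) -> tuple[float, np.ndarray]:
    """Hydrogen-bond occupancy over the trajectory.

    Returns the bonded-frame fraction and the per-frame boolean series.
    """
    d = traj.select_one(**spec.donor)
    h = traj.select_one(**spec.hydrogen)
    a = traj.select_one(**spec.acceptor)
    rd = traj.coords[:, d]
    rh = traj.coords[:, h]
    ra = traj.coords[:, a]
    dist_da = np.linalg.norm(ra - rd, axis=1)
    if spec.angle_vertex == "hydrogen":
        angle = _angle_deg(rd - rh, ra - rh)
    else:
        angle = _angle_deg(rh - ra, rd - ra)
    bonded = (dist_da <= spec.distance_cutoff) & (angle >= spec.angle_cutoff)
    return float(bonded.mean()), bonded


def _window_centroid(traj: TrajectoryView, residues: list[int], atom_name: str):
    idx = [traj.select_one(atom_name=atom_name, res_id=r) for r in residues]
    return traj.coords[:, idx].mean(axis=1)


def interhelical_angle(traj: TrajectoryView, spec: HelixVectorSpec) -> np.ndarray:
    """Per-frame angle (degrees) between the two helix axis vectors.

    Each helix axis runs from the centroid of its 4 starting C-alpha
    atoms to the centroid of its 4 ending ones; the angle is the
    arccosine of the normalized dot product, in [0, 180].
    """
    v1 = _window_centroid(traj, spec.helix1_end, spec.atom_name) - _window_centroid(
        traj, spec.helix1_start, spec.atom_name
    )
    v2 = _window_centroid(traj, spec.helix2_end, spec.atom_name) - _window_centroid(
        traj, spec.helix2_start, spec.atom_name
    )
    return _angle_deg(v1, v2)


def sheet_dihedral(traj: TrajectoryView, spec: DihedralSpec) -> np.ndarray:
    """Per-frame signed torsion (degrees, (-180, 180]) of four C-alphas."""
    p = np.stack(
        [
            traj.coords[:, traj.select_one(atom_name=spec.atom_name, res_id=r)]
            for r in spec.residues
        ],
        axis=1,
    )  # (frames, 4, 3)
    b1 = p[:, 1] - p[:, 0]
    b2 = p[:, 2] - p[:, 1]
    b3 = p[:, 3] - p[:, 2]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.any(np.linalg.norm(n1, axis=1) < 1e-6) or np.any(
        np.linalg.norm(n2, axis=1) < 1e-6
    ):
        raise DegenerateGeometryError("three collinear atoms in dihedral")
    b2n = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
    x = np.sum(n1 * n2, axis=1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 to keep the (-180, 180] convention
    ang[np.isclose(ang, -180.0)] = 180.0
    return ang


def backbone_rmsd(
    traj: TrajectoryView,
    reference_frame: int = 0,
    selection: np.ndarray | None = None,
    exclude_residues: list[tuple[int, int]] | None = None,
    backbone_names: tuple[str, ...] = ("N", "CA", "C", "O"),
) -> np.ndarray:
    """Per-frame backbone RMSD (A) after least-squares superposition.

    ``selection`` gives explicit atom indices; otherwise all atoms whose
    names are in ``backbone_names`` are used, minus any residues falling
    inside the ``exclude_residues`` (start, end) ranges — the hook for
    dropping flexible spans from the comparison.
    """
    if selection is None:
        mask = np.array([a in backbone_names for a in traj.atom_names])
        if exclude_residues:
            for lo, hi in exclude_residues:
                mask &= ~((traj.res_ids >= lo) & (traj.res_ids <= hi))
        selection = np.nonzero(mask)[0]
    selection = np.asarray(selection, dtype=int)
    if len(selection) == 0:
        raise ValidationError("RMSD selection is empty")
    if not 0 <= reference_frame < traj.n_frames:
        raise ValidationError(f"reference frame {reference_frame} out of range")
    ref = traj.coords[reference_frame, selection]
    ref = ref - ref.mean(axis=0)
    n = len(selection)
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        mob = traj.coords[i, selection]
        mob = mob - mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref, mob)
        # residuals computed explicitly: the reported rssd loses precision
        # to cancellation for near-identical structures
        resid = rot.apply(mob) - ref
        out[i] = np.sqrt(np.sum(resid**2) / n)
    return out


@dataclass
class MetricDistribution:
    """Normalized histogram of one metric series."""

    label: str
    counts: np.ndarray
    edges: np.ndarray
    n: int
    mean: float = field(init=False)

    def __post_init__(self) -> None:
        centers = 0.5 * (self.edges[:-1] + self.edges[1:])
        width = np.diff(self.edges)
        total = float(np.sum(self.counts * width))
        self.mean = float(np.sum(centers * self.counts * width) / total)


def metric_distributions(
    series: dict[str, np.ndarray], bins: int | np.ndarray = 50
) -> dict[str, MetricDistribution]:
    """Density histograms with binning shared across all states/replicas."""
    if not series:
        raise ValidationError("no metric series given")
    arrays = {k: np.asarray(v, dtype=float).ravel() for k, v in series.items()}
    for k, v in arrays.items():
        if len(v) == 0:
            raise ValidationError(f"metric series {k!r} is empty")
    if np.isscalar(bins):
        lo = min(v.min() for v in arrays.values())
        hi = max(v.max() for v in arrays.values())
        if lo == hi:  # single-valued series: one occupied bin
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    out = {}
    for k, v in arrays.items():
        counts, _ = np.histogram(v, bins=edges, density=True)
        out[k] = MetricDistribution(label=k, counts=counts, edges=edges, n=len(v))
    return out
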