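"""Readers and writers for every interchange format.

Formats: single-frame PDB (topology + reference coordinates), multi-frame
XYZ trajectories, JSON records of per-frame QM output (frequencies in
cm^-1, mass-weighted modes, masses in amu, gradients in hartree/bohr,
energies in eV, dimensionless oscillator strengths), and CSV tables for
scalar series, ensembles and spectra.  All writers produce files the
corresponding readers round-trip.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble_spectra import FrameEnsemble
from .errors import ParseError, ValidationError
from .trajectory import TrajectoryView
from .vibronic import Spectrum

__all__ = [
    "read_pdb",
    "write_pdb",
    "read_xyz_traj",
    "write_xyz_traj",
    "read_qm_record",
    "write_qm_record",
    "read_series",
    "write_series",
    "read_ensemble",
    "write_ensemble",
    "read_spectrum",
    "write_spectrum",
]


# ---------------------------------------------------------------- PDB

def read_pdb(path: str | Path) -> TrajectoryView:
    """Parse ATOM/HETATM records of a standard fixed-width PDB file.

    Atom names, residue names/numbers, chain ids and coordinates are
    preserved.  Insertion codes are rejected; malformed records raise
    :class:`ParseError` with the offending line number.
    """
    path = Path(path)
    atom_names: list[str] = []
    res_names: list[str] = []
    res_ids: list[int] = []
    chain_ids: list[str] = []
    xyz: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("TER", "END", "ENDMDL", "MODEL", "REMARK", "CRYST1", ""):
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            if len(line.rstrip("\n")) < 54:
                raise ParseError(
                    "ATOM record shorter than the coordinate field",
                    path=str(path),
                    line=lineno,
                )
            icode = line[26]
            if icode != " ":
                raise ParseError(
                    f"insertion code {icode!r} not supported; renumber residues",
                    path=str(path),
                    line=lineno,
                )
            try:
                res_id = int(line[22:26])
                coords = [float(line[c : c + 8]) for c in (30, 38, 46)]
            except ValueError as exc:
                raise ParseError(
                    f"malformed fixed-width field: {exc}", path=str(path), line=lineno
                ) from None
            atom_names.append(line[12:16].strip())
            res_names.append(line[17:20].strip())
            chain_ids.append(line[21].strip())
            res_ids.append(res_id)
            xyz.append(coords)
    if not atom_names:
        raise ParseError("no ATOM/HETATM records found", path=str(path))
    return TrajectoryView(
        coords=np.array(xyz)[None],
        atom_names=atom_names,
        res_names=res_names,
        res_ids=np.array(res_ids),
        chain_ids=chain_ids,
    )


def write_pdb(traj: TrajectoryView, path: str | Path, frame: int = 0) -> None:
    """Write one frame as fixed-width ATOM records, TER at chain changes."""
    if not 0 <= frame < traj.n_frames:
        raise ValidationError(f"frame {frame} out of range")
    lines = []
    prev_chain = None
    for i in range(traj.n_atoms):
        chain = traj.chain_ids[i] or " "
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        name = traj.atom_names[i]
        name_field = name.ljust(4) if len(name) >= 4 else f" {name:<3}"
        x, y, z = traj.coords[frame, i]
        lines.append(
            f"ATOM  {i + 1:>5} {name_field} {traj.res_names[i]:<3}"
            f"{chain:>2}{traj.res_ids[i]:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------- XYZ

def read_xyz_traj(
    path: str | Path, topology: TrajectoryView | None = None
) -> TrajectoryView:
    """Read a multi-frame XYZ trajectory (constant atom count).

    Comment lines are ignored.  With a ``topology`` the PDB-style
    metadata is attached to the coordinates; otherwise atom symbols from
    the file serve as atom names.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    symbols: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    n_atoms = None
    frame_no = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        frame_no += 1
        try:
            count = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"expected atom count at start of frame {frame_no}",
                path=str(path),
                line=i + 1,
            ) from None
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise ParseError(
                f"frame {frame_no} has {count} atoms, expected {n_atoms}",
                path=str(path),
                line=i + 1,
            )
        block = lines[i + 2 : i + 2 + count]
        if len(block) < count:
            raise ParseError(
                f"frame {frame_no} truncated", path=str(path), line=i + 1
            )
        coords = np.empty((count, 3))
        for k, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise ParseError(
                    f"malformed atom line in frame {frame_no}",
                    path=str(path),
                    line=i + 3 + k,
                )
            if frame_no == 1:
                symbols.append(parts[0])
            try:
                coords[k] = [float(p) for p in parts[1:4]]
            except ValueError as exc:
                raise ParseError(
                    f"bad coordinate in frame {frame_no}: {exc}",
                    path=str(path),
                    line=i + 3 + k,
                ) from None
        frames.append(coords)
        i += 2 + count
    if not frames:
        raise ParseError("empty XYZ trajectory", path=str(path))
    coords = np.stack(frames)
    if topology is not None:
        if topology.n_atoms != coords.shape[1]:
            raise ValidationError(
                f"topology has {topology.n_atoms} atoms, trajectory {coords.shape[1]}"
            )
        return TrajectoryView(
            coords=coords,
            atom_names=topology.atom_names,
            res_names=topology.res_names,
            res_ids=topology.res_ids,
            chain_ids=topology.chain_ids,
        )
    return TrajectoryView(
        coords=coords,
        atom_names=symbols,
        res_names=["UNK"] * coords.shape[1],
        res_ids=np.arange(1, coords.shape[1] + 1),
    )


def write_xyz_traj(
    traj: TrajectoryView, path: str | Path, comment: str = "frame"
) -> None:
    lines = []
    for f in range(traj.n_frames):
        lines.append(str(traj.n_atoms))
        lines.append(f"{comment} {f}")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a]
            lines.append(f"{traj.atom_names[a]:<4s} {x:18.10f} {y:18.10f} {z:18.10f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------- QM JSON

_QM_ARRAY_KEYS = (
    "masses_amu",
    "coords_angstrom",
    "hessian_hartree_bohr2",
    "frequencies_cm1",
    "modes",
)


def write_qm_record(record: dict, path: str | Path) -> None:
    """Serialize a QM-output record (arrays become nested lists)."""
    out = {}
    for key, value in record.items():
        if isinstance(value, np.ndarray):
            out[key] = value.tolist()
        elif isinstance(value, dict):
            out[key] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in value.items()
            }
        else:
            out[key] = value
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


def read_qm_record(path: str | Path) -> dict:
    """Read a QM-output JSON record back into numpy arrays."""
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"invalid JSON: {exc}", path=str(path)) from None
    if "masses_amu" not in raw:
        raise ParseError("QM record lacks required key 'masses_amu'", path=str(path))
    out: dict = {}
    for key, value in raw.items():
        if key in _QM_ARRAY_KEYS:
            out[key] = np.asarray(value, dtype=float)
        elif isinstance(value, dict):
            out[key] = {
                k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
                for k, v in value.items()
            }
        else:
            out[key] = value
    return out


# ---------------------------------------------------------------- CSV

def write_series(values: np.ndarray, path: str | Path, label: str = "value") -> None:
    """Two-column CSV: frame index plus one scalar observable per frame."""
    df = pd.DataFrame({"frame": np.arange(len(values)), label: np.asarray(values)})
    df.to_csv(path, index=False, float_format="%.10g")


def read_series(path: str | Path) -> tuple[np.ndarray, str]:
    """Read a two-column (frame, value) CSV; returns (values, label)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(str(exc), path=str(path)) from None
    if df.shape[1] < 2:
        raise ParseError("series CSV needs (frame, value) columns", path=str(path))
    label = df.columns[1]
    return df[label].to_numpy(dtype=float), label


def write_ensemble(ensemble: FrameEnsemble, path: str | Path) -> None:
    """Long-format CSV: frame, state, replica, state_index, energy, strength."""
    rows = []
    for f in range(ensemble.n_frames):
        for s in range(ensemble.n_states):
            rows.append(
                {
                    "frame": f,
                    "state": ensemble.label,
                    "replica": int(ensemble.replica[f]),
                    "state_index": s + 1,
                    "energy_eV": ensemble.energies[f, s],
                    "osc_strength": ensemble.osc_strengths[f, s],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_ensemble(path: str | Path) -> FrameEnsemble:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(str(exc), path=str(path)) from None
    required = {"frame", "state", "replica", "state_index", "energy_eV", "osc_strength"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"ensemble CSV lacks columns {sorted(required - set(df.columns))}",
            path=str(path),
        )
    labels = df["state"].unique()
    if len(labels) != 1:
        raise ParseError("ensemble CSV must contain exactly one state label", path=str(path))
    piv_e = df.pivot(index="frame", columns="state_index", values="energy_eV")
    piv_f = df.pivot(index="frame", columns="state_index", values="osc_strength")
    replica = df.groupby("frame")["replica"].first().sort_index().to_numpy()
    return FrameEnsemble(
        label=str(labels[0]),
        replica=replica,
        energies=piv_e.sort_index().to_numpy(),
        osc_strengths=piv_f.sort_index().to_numpy(),
    )


def write_spectrum(spec: Spectrum, path: str | Path) -> None:
    pd.DataFrame(
        {"energy_eV": spec.energy_ev, "intensity": spec.intensity}
    ).to_csv(path, index=False, float_format="%.10g")


def read_spectrum(path: str | Path, kind: str = "homogeneous") -> Spectrum:
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(str(exc), path=str(path)) from None
    if not {"energy_eV", "intensity"}.issubset(df.columns):
        raise ParseError("spectrum CSV needs energy_eV,intensity", path=str(path))
    return Spectrum(
        df["energy_eV"].to_numpy(dtype=float),
        df["intensity"].to_numpy(dtype=float),
        kind=kind,
    )
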