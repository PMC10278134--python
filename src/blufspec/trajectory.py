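"""In-memory trajectory container with PDB-style atom indexing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import SelectionError, ValidationError


@dataclass
class TrajectoryView:
    """Cartesian coordinates over frames plus per-atom PDB metadata.

    Attributes
    ----------
    coords
        Array of shape ``(n_frames, n_atoms, 3)`` in angstrom.
    atom_names, res_names
        Per-atom PDB atom and residue names.
    res_ids
        Per-atom residue numbers (1-based, PDB convention).
    chain_ids
        Per-atom chain identifiers ('' when absent).
    """

    coords: np.ndarray
    atom_names: list[str]
    res_names: list[str]
    res_ids: np.ndarray
    chain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValidationError(
                f"coords must have shape (n_frames, n_atoms, 3), got {self.coords.shape}"
            )
        n_atoms = self.coords.shape[1]
        self.res_ids = np.asarray(self.res_ids, dtype=int)
        if not self.chain_ids:
            self.chain_ids = [""] * n_atoms
        for name, seq in (
            ("atom_names", self.atom_names),
            ("res_names", self.res_names),
            ("res_ids", self.res_ids),
            ("chain_ids", self.chain_ids),
        ):
            if len(seq) != n_atoms:
                raise ValidationError(
                    f"{name} has {len(seq)} entries for {n_atoms} atoms"
                )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def select(
        self,
        atom_name: str | None = None,
        res_name: str | None = None,
        res_id: int | None = None,
    ) -> np.ndarray:
        """Indices of atoms matching every given criterion."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_name is not None:
            mask &= np.array([a == atom_name for a in self.atom_names])
        if res_name is not None:
            mask &= np.array([r == res_name for r in self.res_names])
        if res_id is not None:
            mask &= self.res_ids == res_id
        return np.nonzero(mask)[0]

    def select_one(
        self,
        atom_name: str | None = None,
        res_name: str | None = None,
        res_id: int | None = None,
    ) -> int:
        """Index of the unique atom matching the criteria.

        Raises
        ------
        SelectionError
            If no atom or more than one atom matches.
        """
        idx = self.select(atom_name=atom_name, res_name=res_name, res_id=res_id)
        descr = f"atom_name={atom_name!r} res_name={res_name!r} res_id={res_id!r}"
        if len(idx) == 0:
            raise SelectionError(f"no atom matches selector ({descr})")
        if len(idx) > 1:
            raise SelectionError(
                f"selector ({descr}) matches {len(idx)} atoms; expected exactly one"
            )
        return int(idx[0])
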