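"""Atom-cloud structure container with PDB I/O and residue/column maps."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

#: van der Waals radii (Angstrom) for the elements that occur in the
#: hydrogenase models; selenium is larger than sulphur (1.9 vs 1.8 A).
VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "SE": 1.9}
DEFAULT_ATOM_RADIUS = 1.8


@dataclass
class Structure:
    """Atoms with coordinates, radii and residue assignment.

    ``residue_to_column`` optionally maps residue indices onto 1-based
    codon columns of a common alignment, which is what ties cavity
    linings to the selection profile.
    """

    coords: np.ndarray  # (n, 3) Angstrom
    radii: np.ndarray  # (n,)
    residue_indices: np.ndarray  # (n,) int
    elements: Optional[List[str]] = None
    chains: Optional[List[str]] = None
    residue_to_column: Optional[Dict[int, int]] = None
    name: str = "structure"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        n = len(self.coords)
        if self.coords.shape != (n, 3):
            raise ValueError("coords must be (n, 3)")
        if len(self.radii) != n or len(self.residue_indices) != n:
            raise ValueError("radii/residue_indices must match atom count")
        if np.any(self.radii <= 0):
            raise ValueError("atom radii must be positive")
        if self.elements is None:
            self.elements = ["C"] * n
        if self.chains is None:
            self.chains = ["A"] * n

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def residues(self) -> np.ndarray:
        return np.unique(self.residue_indices)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly transformed copy (used for isometry checks)."""
        return Structure(
            coords=self.coords @ np.asarray(rotation).T + np.asarray(translation),
            radii=self.radii.copy(),
            residue_indices=self.residue_indices.copy(),
            elements=list(self.elements),
            chains=list(self.chains),
            residue_to_column=dict(self.residue_to_column) if self.residue_to_column else None,
            name=self.name,
        )

    def columns_of(self, residues: Sequence[int]) -> frozenset:
        """Alignment columns for a residue set (requires the column map)."""
        if self.residue_to_column is None:
            raise ValueError(f"structure {self.name!r} has no residue-to-column map")
        return frozenset(
            self.residue_to_column[r] for r in residues if r in self.residue_to_column
        )

    # -- PDB I/O ------------------------------------------------------------

    def to_pdb(self, path: str | Path) -> None:
        n = self.n_atoms
        atoms = struc.AtomArray(n)
        atoms.coord = self.coords.astype(np.float32)
        atoms.chain_id = np.asarray(self.chains)
        atoms.res_id = self.residue_indices
        atoms.res_name = np.asarray(["GLY"] * n)
        atoms.atom_name = np.asarray(
            [el if len(el) > 1 else "CA" if el == "C" else el for el in self.elements]
        )
        atoms.element = np.asarray([el.upper() for el in self.elements])
        atoms.hetero = np.zeros(n, dtype=bool)
        atoms.set_annotation("occupancy", np.ones(n, dtype=np.float32))
        atoms.set_annotation("b_factor", np.zeros(n, dtype=np.float32))
        pdb = PDBFile()
        pdb.set_structure(atoms)
        pdb.write(str(path))

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        radii: str = "by_element",
        uniform_radius: float = DEFAULT_ATOM_RADIUS,
        residue_to_column: Optional[Dict[int, int]] = None,
    ) -> "Structure":
        """Read ATOM/HETATM records; first altloc kept; per-element radii.

        ``radii`` is "by_element" (van der Waals table, unknown elements
        fall back to the uniform default) or "uniform".
        """
        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="first")
        elements = [str(e).upper() for e in atoms.element]
        if radii == "by_element":
            r = np.array([VDW_RADII.get(e, uniform_radius) for e in elements])
        elif radii == "uniform":
            r = np.full(atoms.array_length(), uniform_radius)
        else:
            raise ValueError(f"unknown radii mode {radii!r}")
        return cls(
            coords=np.asarray(atoms.coord, dtype=float),
            radii=r,
            residue_indices=np.asarray(atoms.res_id, dtype=int),
            elements=elements,
            chains=[str(c) for c in atoms.chain_id],
            residue_to_column=residue_to_column,
            name=Path(path).stem,
        )


def read_column_map(path: str | Path) -> Dict[int, int]:
    """TSV with columns ``residue`` and ``column`` (1-based)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"residue", "column"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns 'residue' and 'column'")
    return dict(zip(df["residue"].astype(int), df["column"].astype(int)))


def write_column_map(mapping: Dict[int, int], path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"residue": list(mapping), "column": [mapping[k] for k in mapping]}
    ).to_csv(path, sep="\t", index=False)
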