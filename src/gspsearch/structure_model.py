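"""Domain types for parsed protein structures and contact computation.

A parsed structure holds one polypeptide chain (residues in sequence
order) plus the non-water hetero groups (ligands) assigned to that
chain.  Two relations are pre-computed from coordinates and shared by
both search backends:

* *contacts* — the minimum atom-pair distance between two residues, or
  between a ligand and a residue, kept only when it does not exceed a
  cutoff (7.0 Å by default; beyond that no interaction is assumed);
* *next pairs* — the sequential order of consecutive residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "LigandGroup",
    "StructureRecord",
    "ContactRecord",
    "DISTANCE_CUTOFF",
    "STANDARD_AMINO_NAMES",
    "UNDEFINED_AMINO",
    "WATER_CODES",
    "min_pair_distance",
    "build_contacts",
    "next_pairs",
]

#: Global contact cutoff in Å; larger separations are not stored.
DISTANCE_CUTOFF = 7.0

#: The twenty standard amino-acid 3-letter codes.
STANDARD_AMINO_NAMES = frozenset(
    {
        "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
        "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    }
)

#: Catch-all standard name for non-standard polymer residues (e.g. MSE).
UNDEFINED_AMINO = "UND"

#: Residue codes treated as water and never as ligands.
WATER_CODES = frozenset({"HOH", "DOD", "WAT"})


class InvalidInputError(ValueError):
    """Raised when an operation receives arguments outside its domain."""


@dataclass(frozen=True)
class Atom:
    """One atom with provenance id, element, file serial and coordinates (Å)."""

    atom_id: str
    element: str
    serial: int
    coords: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise InvalidInputError(f"atom serial must be >= 1, got {self.serial}")
        if not all(math.isfinite(c) for c in self.coords):
            raise InvalidInputError(f"non-finite coordinates for atom {self.atom_id}")


@dataclass
class Residue:
    """An amino-acid residue of the selected chain.

    ``seq_index`` is the 1-based position in order of appearance;
    ``std_name`` is one of the twenty standard codes or ``UND``.
    """

    amino_id: str
    seq_index: int
    code3: str
    std_name: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.seq_index < 1:
            raise InvalidInputError(f"seq_index must be >= 1, got {self.seq_index}")
        if not self.atoms:
            raise InvalidInputError(f"residue {self.amino_id} has no atoms")
        if self.code3 != self.code3.upper():
            raise InvalidInputError(f"residue code must be uppercase: {self.code3!r}")
        if self.std_name not in STANDARD_AMINO_NAMES and self.std_name != UNDEFINED_AMINO:
            raise InvalidInputError(f"unknown standard name {self.std_name!r}")


@dataclass
class LigandGroup:
    """A non-water hetero group (e.g. ZN, ATP) bound to the chain."""

    ligand_id: str
    code3: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if self.code3 in WATER_CODES:
            raise InvalidInputError(f"water group {self.code3} cannot be a ligand")
        if not self.atoms:
            raise InvalidInputError(f"ligand {self.ligand_id} has no atoms")


@dataclass
class StructureRecord:
    """One PDB entry restricted to its selected (largest) chain."""

    pdb_id: str
    chain_id: str
    residues: list[Residue]
    ligands: list[LigandGroup] = field(default_factory=list)
    classification: str = ""
    organism: str = ""
    cath_codes: list[str] | None = None

    def __post_init__(self) -> None:
        for i, res in enumerate(self.residues, start=1):
            if res.seq_index != i:
                raise InvalidInputError(
                    f"residues must be consecutively numbered from 1; "
                    f"position {i} has seq_index {res.seq_index}"
                )

    def residue_by_id(self, amino_id: str) -> Residue:
        for res in self.residues:
            if res.amino_id == amino_id:
                return res
        raise KeyError(amino_id)

    def ligand_by_id(self, ligand_id: str) -> LigandGroup:
        for lig in self.ligands:
            if lig.ligand_id == ligand_id:
                return lig
        raise KeyError(ligand_id)


@dataclass(frozen=True)
class ContactRecord:
    """A stored minimum atom-pair distance at or below the cutoff.

    ``kind`` is ``amino_amino`` or ``ligand_amino``.  Amino–amino pairs
    are stored once, with the lower ``seq_index`` entity first; the
    relation is undirected.
    """

    kind: str
    a_id: str
    b_id: str
    distance: float


def _coords_array(atoms: list[Atom]) -> np.ndarray:
    return np.asarray([a.coords for a in atoms], dtype=float)


def min_pair_distance(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    """Minimum Euclidean distance over all cross pairs of atoms, in Å.

    Symmetric in its arguments.  Raises :class:`InvalidInputError` on an
    empty atom list.
    """
    if not atoms_a or not atoms_b:
        raise InvalidInputError("min_pair_distance requires non-empty atom lists")
    xa = _coords_array(atoms_a)
    xb = _coords_array(atoms_b)
    diff = xa[:, None, :] - xb[None, :, :]
    return float(np.sqrt((diff * diff).sum(axis=2)).min())


def build_contacts(
    structure: StructureRecord, cutoff: float = DISTANCE_CUTOFF
) -> list[ContactRecord]:
    """All residue–residue and ligand–residue contacts within ``cutoff`` Å.

    A pair is stored iff its minimum atom-pair distance is <= cutoff.
    Amino–amino contacts appear once per unordered pair (lower seq_index
    first); there are no self pairs.
    """
    if cutoff <= 0:
        raise InvalidInputError(f"cutoff must be positive, got {cutoff}")
    contacts: list[ContactRecord] = []
    residues = structure.residues
    # residue coordinate arrays, computed once
    res_xyz = [_coords_array(r.atoms) for r in residues]
    for i in range(len(residues)):
        xi = res_xyz[i]
        for j in range(i + 1, len(residues)):
            diff = xi[:, None, :] - res_xyz[j][None, :, :]
            d = float(np.sqrt((diff * diff).sum(axis=2)).min())
            if d <= cutoff:
                contacts.append(
                    ContactRecord(
                        "amino_amino",
                        residues[i].amino_id,
                        residues[j].amino_id,
                        d,
                    )
                )
    for lig in structure.ligands:
        xl = _coords_array(lig.atoms)
        for j, res in enumerate(residues):
            diff = xl[:, None, :] - res_xyz[j][None, :, :]
            d = float(np.sqrt((diff * diff).sum(axis=2)).min())
            if d <= cutoff:
                contacts.append(
                    ContactRecord("ligand_amino", lig.ligand_id, res.amino_id, d)
                )
    return contacts


def next_pairs(structure: StructureRecord) -> list[tuple[str, str]]:
    """Ordered (amino_id, amino_id) pairs for consecutive residues."""
    residues = structure.residues
    return [
        (residues[i].amino_id, residues[i + 1].amino_id)
        for i in range(len(residues) - 1)
    ]
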