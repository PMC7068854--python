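"""PDB coordinate-file ingestion.

Parses ``*.pdb`` / ``*.ent`` (optionally gzipped) files with gemmi and
reduces each entry to a :class:`~gspsearch.structure_model.StructureRecord`:
the chain with the most amino acids, its residues renumbered 1..n in
order of appearance, and the non-water hetero groups on that chain as
ligands.  Entity ids encode provenance, e.g. ``1B38_A_1_4`` is atom 4 of
residue 1 of chain A of entry 1B38.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import gemmi

from .structure_model import (
    Atom,
    LigandGroup,
    Residue,
    STANDARD_AMINO_NAMES,
    StructureRecord,
    UNDEFINED_AMINO,
    WATER_CODES,
)

__all__ = [
    "ParseError",
    "EmptyStructureError",
    "IngestReport",
    "parse_pdb_file",
    "select_chain",
    "make_amino_id",
    "make_atom_id",
    "make_ligand_id",
    "discover_pdb_files",
]

PDB_SUFFIXES = (".pdb", ".ent", ".pdb.gz", ".ent.gz")


class ParseError(ValueError):
    """A file could not be parsed as a PDB entry."""


class EmptyStructureError(ParseError):
    """The file contains no amino-acid-bearing chain."""


@dataclass
class IngestReport:
    """Bookkeeping for a directory ingestion run."""

    files_seen: int = 0
    files_parsed: int = 0
    files_skipped: int = 0
    skip_reasons: dict[str, str] = field(default_factory=dict)
    chains: dict[str, str] = field(default_factory=dict)  # pdb_id -> chain chosen

    def skip(self, path: str, reason: str) -> None:
        self.files_skipped += 1
        self.skip_reasons[path] = reason

    def ok(self, pdb_id: str, chain_id: str) -> None:
        self.files_parsed += 1
        self.chains[pdb_id] = chain_id


# --- id provenance convention ------------------------------------------------

def make_amino_id(pdb_id: str, chain_id: str, seq_index: int) -> str:
    return f"{pdb_id}_{chain_id}_{seq_index}"


def make_atom_id(pdb_id: str, chain_id: str, seq_index: int, ordinal: int) -> str:
    return f"{pdb_id}_{chain_id}_{seq_index}_{ordinal}"


def make_ligand_id(pdb_id: str, chain_id: str, ordinal: int) -> str:
    return f"{pdb_id}_{chain_id}_L{ordinal}"


def select_chain(chains: list[tuple[str, int]]) -> str:
    """The chain id with the largest amino-acid count.

    Ties break to the lexicographically smallest id, so repeated runs
    are deterministic.
    """
    bearing = [(cid, n) for cid, n in chains if n >= 1]
    if not bearing:
        raise EmptyStructureError("no chain contains amino acids")
    return min(bearing, key=lambda cn: (-cn[1], cn[0]))[0]


def _is_amino(res: gemmi.Residue) -> bool:
    """ATOM-record residues and tabulated amino acids (e.g. MSE) count."""
    if res.is_water():
        return False
    if res.het_flag == "A":
        return True
    info = gemmi.find_tabulated_residue(res.name)
    return info is not None and info.is_amino_acid()


def _dedup_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the first-listed alternate location per atom name."""
    seen: set[str] = set()
    out = []
    for atom in res:
        if atom.name in seen:
            continue
        seen.add(atom.name)
        out.append(atom)
    return out


def _header_metadata(path: Path) -> tuple[str, str]:
    """Scan HEADER/SOURCE records for classification and organism."""
    opener = gzip.open if path.name.endswith(".gz") else open
    classification = ""
    organism = ""
    try:
        with opener(path, "rt", errors="replace") as fh:
            for line in fh:
                if line.startswith("HEADER"):
                    classification = line[10:50].strip()
                elif line.startswith("SOURCE") and "ORGANISM_SCIENTIFIC:" in line:
                    organism = (
                        line.split("ORGANISM_SCIENTIFIC:", 1)[1]
                        .strip()
                        .rstrip(";")
                        .strip()
                    )
                elif line.startswith(("ATOM", "HETATM", "MODEL")):
                    break
    except OSError:
        pass
    return classification, organism


def parse_pdb_file(path: str | Path) -> StructureRecord:
    """Parse one PDB file into a single-chain :class:`StructureRecord`.

    Only the first model of multi-model (NMR) files is read.  Raises
    :class:`ParseError` for unreadable files and
    :class:`EmptyStructureError` when no chain carries amino acids.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"{path}: no such file")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no coordinate model")
    st.setup_entities()
    model = st[0]

    info = dict(st.info)
    pdb_id = (info.get("_entry.id") or path.stem[:4]).upper()[:4]

    counts = [
        (chain.name, sum(1 for res in chain if _is_amino(res)))
        for chain in model
    ]
    chain_id = select_chain(counts)
    chain = model[chain_id]

    residues: list[Residue] = []
    ligands: list[LigandGroup] = []
    seq_index = 0
    lig_ordinal = 0
    for res in chain:
        if res.is_water() or res.name in WATER_CODES:
            continue
        atoms_raw = _dedup_altlocs(res)
        if not atoms_raw:
            continue
        if _is_amino(res):
            seq_index += 1
            amino_id = make_amino_id(pdb_id, chain_id, seq_index)
            atoms = [
                Atom(
                    atom_id=make_atom_id(pdb_id, chain_id, seq_index, k),
                    element=a.element.name.upper(),
                    serial=a.serial,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    name=a.name,
                )
                for k, a in enumerate(atoms_raw, start=1)
            ]
            code3 = res.name.upper()
            std = code3 if code3 in STANDARD_AMINO_NAMES else UNDEFINED_AMINO
            residues.append(
                Residue(
                    amino_id=amino_id,
                    seq_index=seq_index,
                    code3=code3,
                    std_name=std,
                    atoms=atoms,
                )
            )
        else:
            lig_ordinal += 1
            ligand_id = make_ligand_id(pdb_id, chain_id, lig_ordinal)
            atoms = [
                Atom(
                    atom_id=f"{ligand_id}_{k}",
                    element=a.element.name.upper(),
                    serial=a.serial,
                    coords=(a.pos.x, a.pos.y, a.pos.z),
                    name=a.name,
                )
                for k, a in enumerate(atoms_raw, start=1)
            ]
            ligands.append(
                LigandGroup(ligand_id=ligand_id, code3=res.name.upper(), atoms=atoms)
            )

    if not residues:
        raise EmptyStructureError(f"{path}: selected chain has no amino acids")

    classification, organism = _header_metadata(path)
    return StructureRecord(
        pdb_id=pdb_id,
        chain_id=chain_id,
        residues=residues,
        ligands=ligands,
        classification=classification,
        organism=organism,
    )


def discover_pdb_files(root: str | Path) -> list[Path]:
    """Recursively list PDB coordinate files under ``root``, sorted."""
    root = Path(root)
    if root.is_file():
        return [root]
    found = [
        p
        for p in sorted(root.rglob("*"))
        if p.is_file() and p.name.lower().endswith(PDB_SUFFIXES)
    ]
    return found
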