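"""Deterministic synthetic structures with known planted pattern instances.

Every other module is testable without downloading real PDB entries:
this module builds toy single-chain structures whose geometry is
controlled well enough that the exact hit set of a planted pattern is
known *by construction*, and writes them as standard PDB text that the
ingest module round-trips.

Layout model
------------
Residue anchors advance ~3.8 Å per residue along a gently jittered
path, so residues more than one position apart are farther than the
7.0 Å contact cutoff and the only amino–amino contacts are between
sequence neighbours.  A planted instance bends this rule locally: its
pattern residues are placed on a sphere around a dedicated ligand copy
so that each ligand–residue distance edge binds a value strictly inside
its [min+0.1, max−0.1] window, while all other residues stay > 7 Å from
that ligand.  Decoy residues draw their identities from codes disjoint
from the pattern's residue names, so they can never satisfy a node
predicate; decoy suppression is geometric and nominal, never
probabilistic, which keeps the ground truth exact.

Planted patterns must pin down their amino identities — named amino
nodes, or alternation wildcards with an explicit allowed set (whose
members are then withheld from the decoy pool).  An unrestricted
wildcard would match decoys and the hit set would no longer be known by
construction.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .gsp_model import (
    AMINO_KINDS,
    GspEdge,
    GspGraph,
    GspNode,
    UNBOUNDED,
    validate,
)
from .structure_model import (
    Atom,
    LigandGroup,
    Residue,
    STANDARD_AMINO_NAMES,
    StructureRecord,
    UNDEFINED_AMINO,
)
from .pdb_ingest import make_amino_id, make_atom_id, make_ligand_id

__all__ = [
    "FixtureSpec",
    "GroundTruthHit",
    "FixtureError",
    "generate_structure",
    "required_residues",
    "write_pdb",
    "random_structure",
    "random_pattern",
]

#: Codes used for decoy residues; kept disjoint from planted node names
#: at generation time by filtering.
_DECOY_POOL = sorted(STANDARD_AMINO_NAMES)

#: One plausible heavy atom element per amino acid (first atom).
_FIRST_ELEMENT = "C"

_CONSECUTIVE_SPACING = 3.8  # Å, approximate Cα-Cα distance
_CUTOFF = 7.0
_LIGAND_CLEARANCE = 10.0  # decoy anchors keep at least this from any ligand


class FixtureError(ValueError):
    """The fixture spec is inconsistent or geometrically infeasible."""


@dataclass(frozen=True)
class GroundTruthHit:
    """One planted assignment: node_id -> entity id."""

    assignment: tuple[tuple[str, str], ...]


@dataclass
class FixtureSpec:
    """Recipe for one synthetic structure.

    ``pattern`` is planted ``n_planted`` times at non-overlapping chain
    positions; ``seed`` fully determines the output.
    """

    n_residues: int = 30
    pattern: GspGraph | None = None
    n_planted: int = 0
    pdb_id: str = "SYN1"
    chain_id: str = "A"
    seed: int = 0
    noise_scale: float = 0.25  # Å, perpendicular jitter of the walk
    classification: str = "SYNTHETIC PATTERN TEST"
    organism: str = "SYNTHETIC CONSTRUCT"


#: gap sizes drawn per site stay within min..min+_GAP_SLACK (and max)
_GAP_SLACK = 3


def _pattern_chain_layout(
    pattern: GspGraph,
) -> tuple[list[str], list[tuple[int, int]]]:
    """Amino nodes in sequence order and the step range between them.

    Follows the next/gap chain.  Each step is (min, max) positions to
    the successor: exactly 1 for a next edge, gap+1 for a gap edge,
    where the plantable gap sizes span the edge's minimum up to
    ``min + _GAP_SLACK`` (bounded by the edge's own maximum), so
    different sites can realize different gap tuples while the chain
    footprint stays bounded.
    """
    succ: dict[str, tuple[str, GspEdge]] = {}
    has_pred = set()
    for e in pattern.edges:
        if e.kind in ("next", "gap"):
            succ[e.a] = (e.b, e)
            has_pred.add(e.b)
    aminos = [n.node_id for n in pattern.amino_nodes]
    starts = [a for a in aminos if a not in has_pred]
    if len(aminos) == 1:
        return aminos, []
    if len(starts) != 1:
        raise FixtureError(
            "planted pattern must chain its amino nodes with next/gap edges"
        )
    order = [starts[0]]
    steps: list[tuple[int, int]] = []
    cur = starts[0]
    while cur in succ:
        nxt, edge = succ[cur]
        if edge.kind == "next":
            steps.append((1, 1))
        else:
            g_lo = int(edge.min)
            g_hi = g_lo + _GAP_SLACK
            if edge.max != UNBOUNDED:
                g_hi = min(g_hi, int(edge.max))
            steps.append((g_lo + 1, g_hi + 1))
        order.append(nxt)
        cur = nxt
    if len(order) != len(aminos):
        raise FixtureError(
            "planted pattern must chain all amino nodes with next/gap edges"
        )
    return order, steps


def _min_stride(pattern: GspGraph) -> int:
    _, steps = _pattern_chain_layout(pattern)
    span_max = sum(hi for _, hi in steps) + 1
    if pattern.ligand_nodes:
        return max(span_max + 2, 5)
    return span_max + 2


def required_residues(pattern: GspGraph, n_planted: int = 1) -> int:
    """Smallest ``n_residues`` a spec needs for this pattern and count."""
    return max(n_planted, 1) * _min_stride(pattern)


def _sphere_point(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_structure(
    spec: FixtureSpec,
) -> tuple[StructureRecord, list[GroundTruthHit]]:
    """Build one structure and the exact hit list of the planted pattern.

    The ground truth enumerates, per planted site, every assignment of
    pattern nodes to that site's entities that satisfies the pattern
    constraints (mirror assignments included); sites are spaced so no
    cross-site assignment can satisfy the ligand distance edges.
    """
    rng = np.random.default_rng(spec.seed)
    pattern = spec.pattern
    if spec.n_planted > 0 and pattern is None:
        raise FixtureError("n_planted > 0 requires a pattern")

    planted_names: set[str] = set()
    lig_node: GspNode | None = None
    if pattern is not None:
        bad = validate(pattern)
        if bad:
            raise FixtureError(f"planted pattern invalid: {'; '.join(bad)}")
        for n in pattern.amino_nodes:
            if n.kind == "amino":
                planted_names.add(n.name)
            elif n.allowed:
                # alternation wildcards are plantable: one member is
                # planted, all members are withheld from the decoy pool
                planted_names.update(n.allowed)
            else:
                raise FixtureError(
                    "planted patterns must use named amino nodes or "
                    "alternations with an explicit allowed set"
                )
        ligs = pattern.ligand_nodes
        if ligs:
            lig_node = ligs[0]
            if lig_node.kind != "ligand":
                raise FixtureError("planted patterns must name their ligand code")
            connected = {
                (e.b if pattern.node(e.a).kind in ("ligand", "any_ligand") else e.a)
                for _, e in pattern.ligand_distance_edges()
            }
            if spec.n_planted > 0 and connected < {
                n.node_id for n in pattern.amino_nodes
            }:
                raise FixtureError(
                    "planted ligand patterns must connect the ligand to every "
                    "amino node by a distance edge (site confinement)"
                )
        elif spec.n_planted > 1:
            raise FixtureError(
                "ligand-less patterns can be planted at most once per structure "
                "(no geometric confinement between sites)"
            )

    decoys = [c for c in _DECOY_POOL if c not in planted_names]

    order: list[str] = []
    sites: list[int] = []
    site_offsets: list[list[int]] = []  # per-site cumulative node offsets
    if spec.n_planted > 0:
        order, steps = _pattern_chain_layout(pattern)
        # sites at fixed stride; >= 5 keeps neighbouring ligand sites
        # > 13.9 Å apart so cross-site distance edges cannot bind
        min_stride = _min_stride(pattern)
        stride = spec.n_residues // spec.n_planted
        if stride < min_stride:
            raise FixtureError(
                f"{spec.n_planted} instances of this pattern need at least "
                f"{required_residues(pattern, spec.n_planted)} residues, "
                f"have {spec.n_residues}"
            )
        sites = [k * stride + 1 for k in range(spec.n_planted)]
        for _ in sites:
            offs = [0]
            for lo, hi in steps:
                offs.append(offs[-1] + int(rng.integers(lo, hi + 1)))
            site_offsets.append(offs)

    # assign residue codes: planted names at site offsets, decoys elsewhere
    code_at: dict[int, str] = {}
    node_at: dict[int, str] = {}  # seq_index -> pattern node_id
    site_of: dict[int, int] = {}
    for si, start in enumerate(sites):
        for node_id, off in zip(order, site_offsets[si]):
            seq = start + off
            node = pattern.node(node_id)
            if node.kind == "amino":
                code_at[seq] = node.name
            else:  # alternation: plant a seeded member of the allowed set
                members = sorted(node.allowed)
                code_at[seq] = members[int(rng.integers(0, len(members)))]
            node_at[seq] = node_id
            site_of[seq] = si
    for seq in range(1, spec.n_residues + 1):
        if seq not in code_at:
            code_at[seq] = decoys[int(rng.integers(0, len(decoys)))]

    # --- geometry -----------------------------------------------------------
    # jittered extended chain: guarantees non-neighbours are > cutoff apart
    anchors = np.zeros((spec.n_residues + 1, 3))
    direction = np.array([1.0, 0.0, 0.0])
    for i in range(1, spec.n_residues + 1):
        jitter = rng.normal(scale=spec.noise_scale, size=3)
        jitter[0] = 0.0
        anchors[i] = anchors[i - 1] + direction * _CONSECUTIVE_SPACING + jitter

    # ligand sites: place the ligand near its instance's residues, then pull
    # each pattern residue to its target distance from the ligand
    ligand_centers: list[np.ndarray] = []
    target_dist: dict[tuple[int, str], float] = {}  # (site, node_id) -> Å
    if spec.n_planted > 0 and lig_node is not None:
        for si, start in enumerate(sites):
            seqs = [start + off for off in site_offsets[si]]
            center = anchors[seqs].mean(axis=0) + np.array([0.0, 8.0, 0.0])
            ligand_centers.append(center)
            for idx, e in pattern.ligand_distance_edges():
                amino_node = e.b if pattern.node(e.a).kind in ("ligand", "any_ligand") else e.a
                lo = float(e.min) + 0.1
                hi = float(e.max) - 0.1
                if lo >= hi:
                    raise FixtureError(
                        f"distance edge {idx}: window [{e.min},{e.max}] too narrow "
                        "to plant strictly inside"
                    )
                target_dist[(si, amino_node)] = float(rng.uniform(lo, hi))
        for seq, node_id in node_at.items():
            si = site_of[seq]
            key = (si, node_id)
            if key in target_dist:
                u = _sphere_point(rng)
                anchors[seq] = ligand_centers[si] + u * target_dist[key]

    # keep decoy/unconstrained anchors clear of every ligand
    for seq in range(1, spec.n_residues + 1):
        if (site_of.get(seq), node_at.get(seq)) in target_dist:
            continue
        for center in ligand_centers:
            v = anchors[seq] - center
            d = float(np.linalg.norm(v))
            if d < _LIGAND_CLEARANCE:
                if d < 1e-9:
                    v = np.array([0.0, -1.0, 0.0])
                    d = 1.0
                anchors[seq] = center + v / d * _LIGAND_CLEARANCE

    # --- build entities -----------------------------------------------------
    residues: list[Residue] = []
    serial = 0
    for seq in range(1, spec.n_residues + 1):
        si = site_of.get(seq)
        node_id = node_at.get(seq)
        constrained = (si, node_id) in target_dist
        n_atoms = int(rng.integers(1, 6))
        atoms: list[Atom] = []
        for k in range(1, n_atoms + 1):
            serial += 1
            if k == 1:
                pos = anchors[seq]
            else:
                off = rng.uniform(0.3, 2.0) * _sphere_point(rng)
                if constrained:
                    # extra atoms drift away from the ligand so the first
                    # atom realizes the planted minimum distance exactly
                    away = anchors[seq] - ligand_centers[si]
                    away = away / np.linalg.norm(away)
                    off = np.abs(np.dot(off, away)) * away + 0.05 * away
                pos = anchors[seq] + off
            atoms.append(
                Atom(
                    atom_id=make_atom_id(spec.pdb_id, spec.chain_id, seq, k),
                    element=_FIRST_ELEMENT,
                    serial=serial,
                    coords=tuple(round(float(c), 3) for c in pos),
                    name="CA" if k == 1 else f"C{k}",
                )
            )
        residues.append(
            Residue(
                amino_id=make_amino_id(spec.pdb_id, spec.chain_id, seq),
                seq_index=seq,
                code3=code_at[seq],
                std_name=code_at[seq]
                if code_at[seq] in STANDARD_AMINO_NAMES
                else UNDEFINED_AMINO,
                atoms=atoms,
            )
        )

    ligands: list[LigandGroup] = []
    for si, center in enumerate(ligand_centers):
        serial += 1
        lid = make_ligand_id(spec.pdb_id, spec.chain_id, si + 1)
        ligands.append(
            LigandGroup(
                ligand_id=lid,
                code3=lig_node.code,
                atoms=[
                    Atom(
                        atom_id=f"{lid}_1",
                        element=lig_node.code[:2],
                        serial=serial,
                        coords=tuple(round(float(c), 3) for c in center),
                        name=lig_node.code[:2],
                    )
                ],
            )
        )

    structure = StructureRecord(
        pdb_id=spec.pdb_id,
        chain_id=spec.chain_id,
        residues=residues,
        ligands=ligands,
        classification=spec.classification,
        organism=spec.organism,
    )

    truth = _enumerate_ground_truth(
        spec, pattern, structure, sites, order, site_offsets, ligands
    )
    return structure, truth


def _enumerate_ground_truth(
    spec: FixtureSpec,
    pattern: GspGraph | None,
    structure: StructureRecord,
    sites: list[int],
    order: list[str],
    site_offsets: list[list[int]],
    ligands: list[LigandGroup],
) -> list[GroundTruthHit]:
    """Construction-time enumeration of the planted hit set.

    Considers only each site's own residues and ligand (geometry makes
    cross-site and decoy participation impossible) and checks the
    pattern constraints directly from coordinates and sequence indexes —
    an independent, local re-statement of the matching semantics.
    """
    if pattern is None or spec.n_planted == 0:
        return []
    truth: list[GroundTruthHit] = []
    res_by_seq = {r.seq_index: r for r in structure.residues}
    amino_nodes = pattern.amino_nodes
    for si, start in enumerate(sites):
        site_seqs = [start + off for off in site_offsets[si]]
        site_res = [res_by_seq[s] for s in site_seqs]
        lig = ligands[si] if ligands else None
        # injective name-respecting assignments (names prune the
        # factorial early; constraints are still checked exhaustively)
        cand = [
            [
                r for r in site_res
                if (r.code3 == n.name if n.kind == "amino"
                    else r.code3 in n.allowed)
            ]
            for n in amino_nodes
        ]
        perms: list[tuple] = []

        def _assign(i: int, chosen: tuple) -> None:
            if i == len(amino_nodes):
                perms.append(chosen)
                return
            for r in cand[i]:
                if all(r.amino_id != c.amino_id for c in chosen):
                    _assign(i + 1, chosen + (r,))

        _assign(0, ())
        for perm in perms:
            assign: dict[str, str] = {
                n.node_id: r.amino_id for n, r in zip(amino_nodes, perm)
            }
            seq_of = {n.node_id: r.seq_index for n, r in zip(amino_nodes, perm)}
            for lnode in pattern.ligand_nodes:
                assign[lnode.node_id] = lig.ligand_id
            ok = True
            for e in pattern.edges:
                if e.kind == "next":
                    ok = seq_of[e.b] == seq_of[e.a] + 1
                elif e.kind == "gap":
                    g = seq_of[e.b] - seq_of[e.a] - 1
                    ok = g >= e.min and (e.max == UNBOUNDED or g <= e.max)
                else:
                    res_by_id = {r.amino_id: r for r in site_res}
                    ents = [
                        res_by_id[assign[nid]].atoms
                        if assign[nid] in res_by_id
                        else lig.atoms
                        for nid in (e.a, e.b)
                    ]
                    d = min(
                        math.dist(a.coords, b.coords)
                        for a in ents[0]
                        for b in ents[1]
                    )
                    ok = float(e.min) <= d <= float(e.max)
                if not ok:
                    break
            if ok:
                truth.append(
                    GroundTruthHit(assignment=tuple(sorted(assign.items())))
                )
    return truth


# ---------------------------------------------------------------------------
# PDB text output

def write_pdb(structure: StructureRecord, path: str | Path) -> None:
    """Write standard PDB ATOM/HETATM text (optionally gzipped by suffix).

    Emits HEADER (classification) and SOURCE (organism) records so the
    ingest module recovers the metadata; coordinates keep the format's
    3-decimal precision.
    """
    path = Path(path)
    lines: list[str] = []
    cls = (structure.classification or "UNCLASSIFIED")[:40]
    lines.append(f"HEADER    {cls:<40}{'01-JAN-00':>9}   {structure.pdb_id:<4}")
    if structure.organism:
        lines.append("SOURCE    MOL_ID: 1;")
        lines.append(f"SOURCE   2 ORGANISM_SCIENTIFIC: {structure.organism};")

    def atom_line(record: str, atom: Atom, res_name: str, res_seq: int) -> str:
        name = atom.name or atom.element
        # columns per the PDB format: name left-padded for 1-2 char names
        name_f = f" {name:<3}" if len(name) < 4 else name
        x, y, z = atom.coords
        return (
            f"{record:<6}{atom.serial:>5} {name_f:<4} {res_name:>3} "
            f"{structure.chain_id}{res_seq:>4}    "
            f"{x:>8.3f}{y:>8.3f}{z:>8.3f}{1.00:>6.2f}{0.00:>6.2f}"
            f"          {atom.element[:2]:>2}"
        )

    for res in structure.residues:
        for atom in res.atoms:
            lines.append(atom_line("ATOM", atom, res.code3, res.seq_index))
    het_seq = len(structure.residues)
    for lig in structure.ligands:
        het_seq += 1
        for atom in lig.atoms:
            lines.append(atom_line("HETATM", atom, lig.code3, het_seq))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path.name.endswith(".gz"):
        with gzip.open(path, "wt") as fh:
            fh.write(text)
    else:
        path.write_text(text)


# ---------------------------------------------------------------------------
# Randomized (non-planted) structures and patterns for property testing

def random_structure(
    rng: np.random.Generator,
    pdb_id: str = "RND1",
    max_residues: int = 25,
    max_ligands: int = 2,
    box: float = 14.0,
) -> StructureRecord:
    """A compact random structure with abundant contacts.

    Residues and ligands are thrown into a small box so many pairs fall
    under the 7 Å cutoff; used to exercise both backends on dense,
    unstructured contact graphs.
    """
    n_res = int(rng.integers(5, max_residues + 1))
    n_lig = int(rng.integers(0, max_ligands + 1))
    codes = ["CYS", "HIS", "GLY", "ALA", "LYS", "ASP", "SER", "TRP"]
    lig_codes = ["ZN", "ATP", "MG"]
    residues = []
    serial = 0
    for seq in range(1, n_res + 1):
        n_atoms = int(rng.integers(1, 4))
        center = rng.uniform(0, box, size=3)
        atoms = []
        for k in range(1, n_atoms + 1):
            serial += 1
            pos = center + rng.normal(scale=0.8, size=3)
            atoms.append(
                Atom(
                    atom_id=make_atom_id(pdb_id, "A", seq, k),
                    element="C",
                    serial=serial,
                    coords=tuple(round(float(c), 3) for c in pos),
                    name="CA" if k == 1 else f"C{k}",
                )
            )
        code = codes[int(rng.integers(0, len(codes)))]
        residues.append(
            Residue(
                amino_id=make_amino_id(pdb_id, "A", seq),
                seq_index=seq,
                code3=code,
                std_name=code,
                atoms=atoms,
            )
        )
    ligands = []
    for li in range(1, n_lig + 1):
        serial += 1
        code = lig_codes[int(rng.integers(0, len(lig_codes)))]
        lid = make_ligand_id(pdb_id, "A", li)
        ligands.append(
            LigandGroup(
                ligand_id=lid,
                code3=code,
                atoms=[
                    Atom(
                        atom_id=f"{lid}_1",
                        element=code[:2],
                        serial=serial,
                        coords=tuple(
                            round(float(c), 3) for c in rng.uniform(0, box, size=3)
                        ),
                        name=code[:2],
                    )
                ],
            )
        )
    return StructureRecord(
        pdb_id=pdb_id,
        chain_id="A",
        residues=residues,
        ligands=ligands,
        classification="RANDOM TEST",
        organism="SYNTHETIC CONSTRUCT",
    )


def random_pattern(
    rng: np.random.Generator,
    max_nodes: int = 5,
    with_ligand: bool | None = None,
) -> GspGraph:
    """A small random valid pattern mixing node kinds and edge kinds.

    The pattern is connected by construction (edges are added along a
    random spanning order) and always validates.
    """
    n_amino = int(rng.integers(1, max_nodes))
    if with_ligand is None:
        with_ligand = bool(rng.integers(0, 2))
    codes = ["CYS", "HIS", "GLY", "ALA", "LYS", "ASP", "SER", "TRP"]
    polarities = ["any", "non-polar", "polar uncharged", "positively charged",
                  "negatively charged"]
    nodes: list[GspNode] = []
    for i in range(n_amino):
        if rng.random() < 0.6:
            nodes.append(
                GspNode(
                    node_id=f"a{i}",
                    kind="amino",
                    name=codes[int(rng.integers(0, len(codes)))],
                )
            )
        else:
            nodes.append(
                GspNode(
                    node_id=f"a{i}",
                    kind="any_amino",
                    polarity=polarities[int(rng.integers(0, len(polarities)))],
                )
            )
    edges: list[GspEdge] = []
    for i in range(1, n_amino):
        j = int(rng.integers(0, i))
        kind = ("distance", "next", "gap")[int(rng.integers(0, 3))]
        a, b = f"a{j}", f"a{i}"
        if kind == "distance":
            lo = round(float(rng.uniform(0.5, 5.0)), 2)
            hi = round(float(rng.uniform(lo, 7.0)), 2)
            edges.append(GspEdge("distance", a, b, min=lo, max=hi))
        elif kind == "next":
            edges.append(GspEdge("next", a, b))
        else:
            lo_g = int(rng.integers(1, 5))
            hi_g = (
                UNBOUNDED if rng.random() < 0.3 else int(lo_g + rng.integers(0, 5))
            )
            edges.append(GspEdge("gap", a, b, min=lo_g, max=hi_g))
    if with_ligand:
        kind = "ligand" if rng.random() < 0.7 else "any_ligand"
        code = ["ZN", "ATP", "MG"][int(rng.integers(0, 3))] if kind == "ligand" else None
        nodes.append(GspNode(node_id="lig", kind=kind, code=code))
        # connect the ligand to a random subset (>=1) of amino nodes
        k = int(rng.integers(1, n_amino + 1))
        for i in rng.choice(n_amino, size=k, replace=False):
            lo = round(float(rng.uniform(0.5, 5.0)), 2)
            hi = round(float(rng.uniform(lo, 7.0)), 2)
            edges.append(GspEdge("distance", "lig", f"a{int(i)}", min=lo, max=hi))
    return GspGraph(nodes=nodes, edges=edges)
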