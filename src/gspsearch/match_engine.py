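"""Reference in-memory pattern matcher.

Defines the ground-truth semantics of pattern search: a *hit* is one
injective assignment of the pattern's amino nodes to residues (and its
ligand node, if any, to a ligand group) such that every node predicate
and every edge constraint holds.  Assignments that differ only by
permuting equivalent nodes are distinct hits ("mirror" hits), which is
why an unordered pattern of k identical residues yields k! hits per
site.  The SQL backend must agree with this engine exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gsp_model import (
    AMINO_KINDS,
    GspEdge,
    GspGraph,
    GspNode,
    LIGAND_KINDS,
    POLARITY_CLASSES,
    UNBOUNDED,
    validate,
)
from .structure_model import (
    ContactRecord,
    InvalidInputError,
    LigandGroup,
    Residue,
    StructureRecord,
    build_contacts,
)

__all__ = [
    "MatchHit",
    "SearchResult",
    "PatternValidationError",
    "node_matches",
    "edge_satisfied",
    "search",
    "search_structure",
]


class PatternValidationError(ValueError):
    """Raised when a search is attempted with an invalid pattern."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class MatchHit:
    """One satisfying assignment of pattern nodes to structure entities.

    ``distances`` maps distance-edge index -> bound Å value and ``gaps``
    maps gap-edge index -> bound gap size (residues strictly between).
    """

    pdb_id: str
    assignment: tuple[tuple[str, str], ...]  # (node_id, entity_id), sorted
    distances: tuple[tuple[int, float], ...]
    gaps: tuple[tuple[int, int], ...]

    @property
    def assignment_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def distance_dict(self) -> dict[int, float]:
        return dict(self.distances)

    @property
    def gap_dict(self) -> dict[int, int]:
        return dict(self.gaps)

    def sort_key(self) -> tuple:
        return (self.pdb_id, self.assignment)


@dataclass
class SearchResult:
    """Hits plus the two headline counts (hits, distinct proteins)."""

    hits: list[MatchHit] = field(default_factory=list)

    @property
    def n_hits(self) -> int:
        return len(self.hits)

    @property
    def n_proteins(self) -> int:
        return len({h.pdb_id for h in self.hits})

    def canonical(self) -> "SearchResult":
        return SearchResult(sorted(self.hits, key=MatchHit.sort_key))


def node_matches(node: GspNode, entity: Residue | LigandGroup) -> bool:
    """Does a structure entity satisfy a pattern node's predicate?"""
    if node.kind in AMINO_KINDS:
        if not isinstance(entity, Residue):
            raise InvalidInputError(
                f"node {node.node_id} ({node.kind}) requires a residue"
            )
        if node.kind == "amino":
            return entity.code3 == node.name
        if node.allowed is not None:
            return entity.code3 in node.allowed
        if node.polarity == "any":
            return True
        return entity.std_name in POLARITY_CLASSES[node.polarity]
    if not isinstance(entity, LigandGroup):
        raise InvalidInputError(
            f"node {node.node_id} ({node.kind}) requires a ligand group"
        )
    if node.kind == "ligand":
        return entity.code3 == node.code
    return True  # any_ligand: any non-water hetero group


class _ContactIndex:
    """Symmetric lookup of stored contacts by entity-id pair."""

    def __init__(self, contacts: list[ContactRecord]):
        self._d: dict[tuple[str, str], float] = {}
        for c in contacts:
            self._d[(c.a_id, c.b_id)] = c.distance
            self._d[(c.b_id, c.a_id)] = c.distance

    def get(self, a_id: str, b_id: str) -> float | None:
        return self._d.get((a_id, b_id))


def edge_satisfied(
    edge: GspEdge,
    assignment: dict[str, str],
    structure: StructureRecord,
    contacts: _ContactIndex | list[ContactRecord],
) -> bool:
    """Check one edge constraint under a (partial) assignment.

    Both endpoints must already be assigned.  Distance edges are
    symmetric lookups into the contact set; next/gap edges compare the
    1-based sequence indexes of the two residues.
    """
    if isinstance(contacts, list):
        contacts = _ContactIndex(contacts)
    ea, eb = assignment[edge.a], assignment[edge.b]
    if edge.kind == "distance":
        d = contacts.get(ea, eb)
        return d is not None and edge.min <= d <= edge.max
    sa = structure.residue_by_id(ea).seq_index
    sb = structure.residue_by_id(eb).seq_index
    if edge.kind == "next":
        return sb == sa + 1
    g = sb - sa - 1
    if g < edge.min:
        return False
    return edge.max == UNBOUNDED or g <= edge.max


def _bound_values(
    gsp: GspGraph,
    assignment: dict[str, str],
    structure: StructureRecord,
    contacts: _ContactIndex,
) -> tuple[tuple[tuple[int, float], ...], tuple[tuple[int, int], ...]]:
    dists = []
    gaps = []
    for i, e in enumerate(gsp.edges):
        if e.kind == "distance":
            dists.append((i, contacts.get(assignment[e.a], assignment[e.b])))
        elif e.kind == "gap":
            sa = structure.residue_by_id(assignment[e.a]).seq_index
            sb = structure.residue_by_id(assignment[e.b]).seq_index
            gaps.append((i, sb - sa - 1))
    return tuple(dists), tuple(gaps)


def search_structure(
    gsp: GspGraph,
    structure: StructureRecord,
    contacts: list[ContactRecord] | None = None,
) -> list[MatchHit]:
    """All hits of a (pre-validated) pattern in one structure.

    Backtracking over pattern nodes with constraint checks as soon as
    both endpoints of an edge are assigned; prunes but never changes the
    result relative to exhaustive enumeration.
    """
    if contacts is None:
        contacts = build_contacts(structure)
    index = _ContactIndex(contacts)

    # candidate entities per node
    candidates: dict[str, list[str]] = {}
    for node in gsp.nodes:
        pool = structure.residues if node.kind in AMINO_KINDS else structure.ligands
        ids = [
            (e.amino_id if isinstance(e, Residue) else e.ligand_id)
            for e in pool
            if node_matches(node, e)
        ]
        if not ids:
            return []
        candidates[node.node_id] = ids

    amino_ids = {n.node_id for n in gsp.amino_nodes}
    # order nodes: most constrained (fewest candidates) first
    order = sorted(gsp.nodes, key=lambda n: len(candidates[n.node_id]))
    edges_ready: list[list[GspEdge]] = []
    assigned_so_far: set[str] = set()
    for node in order:
        assigned_so_far.add(node.node_id)
        edges_ready.append(
            [
                e
                for e in gsp.edges
                if {e.a, e.b} <= assigned_so_far
                and node.node_id in (e.a, e.b)
            ]
        )

    hits: list[MatchHit] = []
    assignment: dict[str, str] = {}
    used_aminos: set[str] = set()

    def extend(depth: int) -> None:
        if depth == len(order):
            dists, gaps = _bound_values(gsp, assignment, structure, index)
            hits.append(
                MatchHit(
                    pdb_id=structure.pdb_id,
                    assignment=tuple(sorted(assignment.items())),
                    distances=dists,
                    gaps=gaps,
                )
            )
            return
        node = order[depth]
        is_amino = node.node_id in amino_ids
        for ent in candidates[node.node_id]:
            if is_amino and ent in used_aminos:
                continue
            assignment[node.node_id] = ent
            if all(
                edge_satisfied(e, assignment, structure, index)
                for e in edges_ready[depth]
            ):
                if is_amino:
                    used_aminos.add(ent)
                extend(depth + 1)
                if is_amino:
                    used_aminos.discard(ent)
            del assignment[node.node_id]

    extend(0)
    return hits


def search(
    gsp: GspGraph,
    structures: list[StructureRecord],
    contacts_by_pdb: dict[str, list[ContactRecord]] | None = None,
) -> SearchResult:
    """Search a pattern across structures; hits in canonical order.

    Raises :class:`PatternValidationError` when the pattern is invalid.
    ``contacts_by_pdb`` may supply pre-built contact sets keyed by
    pdb_id; missing entries are computed on the fly.
    """
    violations = validate(gsp)
    if violations:
        raise PatternValidationError(violations)
    all_hits: list[MatchHit] = []
    for st in structures:
        contacts = None
        if contacts_by_pdb is not None:
            contacts = contacts_by_pdb.get(st.pdb_id)
        all_hits.extend(search_structure(gsp, st, contacts))
    return SearchResult(all_hits).canonical()
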