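"""Shared fixtures: zinc-finger patterns and an independent search oracle.

The oracle enumerates every injective assignment of pattern nodes to
structure entities and checks each constraint straight from atom
coordinates and sequence indexes.  It shares only the polarity
membership table with the package, never its matching or contact code,
so agreement between the two is a real cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from gspsearch.gsp_model import (
    GspGraph,
    POLARITY_CLASSES,
    UNBOUNDED,
    parse_prosite_linear,
)
from gspsearch.structure_model import StructureRecord

#: PROSITE-style expressions for six classic zinc-finger families.
ZINC_FINGER_PATTERNS = {
    "C2H2-classic": "C-x(2,4)-C-x(12)-H-x(2,6)-H",
    "C2H2-variant": "C-x(2,4)-C-x(3)-[LIVMFYWC]-x(8)-H-x(3,5)-H",
    "THAP": "C-x(2,4)-C-x(35,50)-C-x(2)-H",
    "C2HC": "C-x(5)-C-x(n)-H-x(6)-C",
    "fungal": "C-x(2)-C-x(6)-C-x(5,12)-C-x(2)-C-x(6,8)-C",
    "CCHHC": "C-P-x(1)-P-G-C-x(1)-G-x(1)-G-H-x(7)-H-R-x(4)-C",
}


@pytest.fixture(scope="session")
def zinc_finger_graphs() -> dict[str, GspGraph]:
    return {
        name: parse_prosite_linear(expr, ligand_code="ZN")
        for name, expr in ZINC_FINGER_PATTERNS.items()
    }


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


# ---------------------------------------------------------------------------
# Independent exhaustive oracle

def _min_dist(atoms_a, atoms_b) -> float:
    return min(
        math.dist(a.coords, b.coords) for a in atoms_a for b in atoms_b
    )


def _node_ok(node, residue=None, ligand=None) -> bool:
    if node.kind == "amino":
        return residue.code3 == node.name
    if node.kind == "any_amino":
        if node.allowed is not None:
            return residue.code3 in node.allowed
        if node.polarity == "any":
            return True
        return residue.std_name in POLARITY_CLASSES[node.polarity]
    if node.kind == "ligand":
        return ligand.code3 == node.code
    return True  # any_ligand


def oracle_search(gsp: GspGraph, structure: StructureRecord) -> set[tuple]:
    """All satisfying injective assignments, as sorted (node, entity) tuples.

    Distances are recomputed from coordinates (contact cutoff 7.0 Å is
    implied by the 7.0 Å distance-range envelope); gaps and adjacency
    from sequence indexes.  Pure enumeration — no pruning shared with
    the engine under test.
    """
    amino_nodes = [n for n in gsp.nodes if n.kind in ("amino", "any_amino")]
    ligand_nodes = [n for n in gsp.nodes if n.kind in ("ligand", "any_ligand")]

    res_cands = {
        n.node_id: [r for r in structure.residues if _node_ok(n, residue=r)]
        for n in amino_nodes
    }
    lig_cands = {
        n.node_id: [l for l in structure.ligands if _node_ok(n, ligand=l)]
        for n in ligand_nodes
    }

    seq_of = {r.amino_id: r.seq_index for r in structure.residues}
    atoms_of = {r.amino_id: r.atoms for r in structure.residues}
    atoms_of.update({l.ligand_id: l.atoms for l in structure.ligands})

    dist_cache: dict[frozenset, float] = {}

    def pair_dist(ea: str, eb: str) -> float:
        key = frozenset((ea, eb))
        if key not in dist_cache:
            dist_cache[key] = _min_dist(atoms_of[ea], atoms_of[eb])
        return dist_cache[key]

    found: set[tuple] = set()
    amino_ids = [n.node_id for n in amino_nodes]
    lig_ids = [n.node_id for n in ligand_nodes]
    for res_choice in itertools.product(
        *(res_cands[nid] for nid in amino_ids)
    ):
        chosen = [r.amino_id for r in res_choice]
        if len(set(chosen)) != len(chosen):  # injectivity over amino nodes
            continue
        for lig_choice in itertools.product(
            *(lig_cands[nid] for nid in lig_ids)
        ):
            assign = dict(zip(amino_ids, chosen))
            assign.update(
                {nid: l.ligand_id for nid, l in zip(lig_ids, lig_choice)}
            )
            ok = True
            for e in gsp.edges:
                ea, eb = assign[e.a], assign[e.b]
                if e.kind == "distance":
                    d = pair_dist(ea, eb)
                    ok = float(e.min) <= d <= float(e.max)
                elif e.kind == "next":
                    ok = seq_of[eb] == seq_of[ea] + 1
                else:
                    g = seq_of[eb] - seq_of[ea] - 1
                    ok = g >= e.min and (e.max == UNBOUNDED or g <= e.max)
                if not ok:
                    break
            if ok:
                found.add(tuple(sorted(assign.items())))
    return found


def assignments(result) -> set[tuple]:
    """The hit set of a SearchResult as comparable assignment tuples."""
    return {h.assignment for h in result.hits}
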