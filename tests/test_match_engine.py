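"""Reference matcher semantics: predicates, edges, enumeration, symmetry."""

import numpy as np
import pytest

from conftest import assignments, oracle_search
from gspsearch.gsp_model import GspEdge, GspGraph, GspNode, UNBOUNDED
from gspsearch.match_engine import (
    PatternValidationError,
    edge_satisfied,
    node_matches,
    search,
    search_structure,
)
from gspsearch.structure_model import (
    Atom,
    InvalidInputError,
    LigandGroup,
    Residue,
    build_contacts,
)
from gspsearch.synthetic_fixtures import (
    FixtureSpec,
    generate_structure,
    random_pattern,
    random_structure,
)


def residue(seq, code, std=None):
    return Residue(
        amino_id=f"T_A_{seq}", seq_index=seq, code3=code,
        std_name=std or code,
        atoms=[Atom(atom_id=f"T_A_{seq}_1", element="C", serial=seq,
                    coords=(seq * 3.8, 0, 0))],
    )


def amino(nid, name):
    return GspNode(node_id=nid, kind="amino", name=name)


class TestNodeMatches:
    def test_exact_amino_code(self):
        assert node_matches(amino("a", "CYS"), residue(1, "CYS"))
        assert not node_matches(amino("a", "CYS"), residue(1, "HIS"))

    def test_polarity_membership(self):
        pos = GspNode(node_id="x", kind="any_amino",
                      polarity="positively charged")
        assert node_matches(pos, residue(1, "LYS"))
        assert not node_matches(pos, residue(1, "GLU"))

    def test_any_amino_matches_everything(self):
        node = GspNode(node_id="x", kind="any_amino")
        assert node_matches(node, residue(1, "TRP"))
        assert node_matches(node, residue(1, "MSE", std="UND"))

    def test_allowed_set_overrides_polarity(self):
        node = GspNode(node_id="x", kind="any_amino",
                       allowed=frozenset({"LEU", "CYS"}))
        assert node_matches(node, residue(1, "CYS"))
        assert not node_matches(node, residue(1, "GLY"))

    def test_any_ligand_matches_any_group(self):
        zn = LigandGroup(
            ligand_id="T_A_L1", code3="ZN",
            atoms=[Atom(atom_id="T_A_L1_1", element="ZN", serial=99,
                        coords=(0, 0, 0))],
        )
        assert node_matches(GspNode(node_id="l", kind="any_ligand"), zn)
        assert node_matches(
            GspNode(node_id="l", kind="ligand", code="ZN"), zn
        )
        assert not node_matches(
            GspNode(node_id="l", kind="ligand", code="ATP"), zn
        )

    def test_kind_entity_mismatch_raises(self):
        with pytest.raises(InvalidInputError):
            node_matches(amino("a", "CYS"), LigandGroup(
                ligand_id="T_A_L1", code3="ZN",
                atoms=[Atom(atom_id="T_A_L1_1", element="ZN", serial=1,
                            coords=(0, 0, 0))],
            ))


class TestEdgeSatisfied:
    @pytest.fixture
    def chain(self):
        from gspsearch.structure_model import StructureRecord

        st = StructureRecord(
            pdb_id="T", chain_id="A",
            residues=[residue(i, "GLY") for i in range(1, 9)],
        )
        return st, build_contacts(st)

    def test_gap_arithmetic(self, chain):
        st, contacts = chain
        edge = GspEdge("gap", "a", "b", min=2, max=4)
        assign = {"a": "T_A_3", "b": "T_A_7"}  # g = 3
        assert edge_satisfied(edge, assign, st, contacts)

    def test_next_requires_adjacency(self, chain):
        st, contacts = chain
        edge = GspEdge("next", "a", "b")
        assert not edge_satisfied(edge, {"a": "T_A_5", "b": "T_A_7"}, st, contacts)
        assert edge_satisfied(edge, {"a": "T_A_5", "b": "T_A_6"}, st, contacts)

    def test_unbounded_gap(self, chain):
        st, contacts = chain
        edge = GspEdge("gap", "a", "b", min=1, max=UNBOUNDED)
        assert edge_satisfied(edge, {"a": "T_A_1", "b": "T_A_8"}, st, contacts)
        assert not edge_satisfied(edge, {"a": "T_A_1", "b": "T_A_2"}, st, contacts)

    def test_distance_interval_on_stored_contact(self, chain):
        st, contacts = chain
        # consecutive residues are 3.8 apart by construction
        edge = GspEdge("distance", "a", "b", min=3.5, max=4.0)
        assert edge_satisfied(edge, {"a": "T_A_1", "b": "T_A_2"}, st, contacts)
        narrow = GspEdge("distance", "a", "b", min=2.0, max=2.5)
        assert not edge_satisfied(narrow, {"a": "T_A_1", "b": "T_A_2"}, st, contacts)

    def test_distance_is_symmetric(self, chain):
        st, contacts = chain
        edge = GspEdge("distance", "a", "b", min=3.5, max=4.0)
        fwd = edge_satisfied(edge, {"a": "T_A_1", "b": "T_A_2"}, st, contacts)
        rev = edge_satisfied(edge, {"a": "T_A_2", "b": "T_A_1"}, st, contacts)
        assert fwd and rev


class TestSearch:
    def test_mirror_hits_for_symmetric_pattern(self, rng):
        """Two CYS within range of the only ZN -> exactly 2 mirror hits."""
        gsp = GspGraph(
            nodes=[amino("c1", "CYS"), amino("c2", "CYS"),
                   GspNode(node_id="l", kind="ligand", code="ZN")],
            edges=[GspEdge("distance", "l", "c1", min=0.5, max=7.0),
                   GspEdge("distance", "l", "c2", min=0.5, max=7.0)],
        )
        spec = FixtureSpec(n_residues=12, pattern=GspGraph(
            nodes=gsp.nodes,
            edges=gsp.edges + [GspEdge("gap", "c1", "c2", min=2, max=2)],
        ), n_planted=1, seed=11)
        st, _ = generate_structure(spec)
        result = search(gsp, [st])
        assert result.n_hits == 2
        assert result.n_proteins == 1

    def test_absent_residue_type_gives_zero(self, rng):
        st = random_structure(rng)
        gsp = GspGraph(nodes=[amino("a", "PRO")])  # PRO not in random pool
        assert search(gsp, [st]).n_hits == 0

    def test_invalid_pattern_raises_with_violations(self, rng):
        st = random_structure(rng)
        gsp = GspGraph(
            nodes=[amino("a", "CYS"), amino("b", "CYS")],
            edges=[GspEdge("distance", "a", "b", min=0.1, max=9.0)],
        )
        with pytest.raises(PatternValidationError) as err:
            search(gsp, [st])
        assert err.value.violations

    def test_planted_instances_found_exactly(self):
        from gspsearch.gsp_model import parse_prosite_linear

        gsp = parse_prosite_linear("C-x(2)-C", ligand_code="ZN")
        spec = FixtureSpec(n_residues=30, pattern=gsp, n_planted=3, seed=5)
        st, truth = generate_structure(spec)
        result = search(gsp, [st])
        assert assignments(result) == {t.assignment for t in truth}
        assert result.n_hits == 3

    @pytest.mark.parametrize("trial", range(25))
    def test_equals_exhaustive_enumeration(self, trial):
        """Backtracking may prune, but the hit set equals brute force."""
        rng = np.random.default_rng(1000 + trial)
        st = random_structure(rng, max_residues=14, max_ligands=2)
        gsp = random_pattern(rng, max_nodes=4)
        got = {h.assignment for h in search_structure(gsp, st)}
        assert got == oracle_search(gsp, st)

    def test_bound_values_recorded(self):
        from gspsearch.gsp_model import parse_prosite_linear

        gsp = parse_prosite_linear("C-x(2,4)-C", ligand_code="ZN")
        spec = FixtureSpec(n_residues=20, pattern=gsp, n_planted=1, seed=2)
        st, _ = generate_structure(spec)
        (hit,) = search(gsp, [st]).hits
        gap_idx = [i for i, e in enumerate(gsp.edges) if e.kind == "gap"]
        assert set(hit.gap_dict) == set(gap_idx)
        assert 2 <= hit.gap_dict[gap_idx[0]] <= 4
        for i, e in enumerate(gsp.edges):
            if e.kind == "distance":
                assert e.min <= hit.distance_dict[i] <= e.max


class TestMonotonicity:
    @pytest.mark.parametrize("trial", range(10))
    def test_widening_and_deleting_never_lose_hits(self, trial):
        rng = np.random.default_rng(7000 + trial)
        st = random_structure(rng, max_residues=16, max_ligands=1)
        gsp = random_pattern(rng, max_nodes=4)
        base = len(search_structure(gsp, st))
        # widening every range
        import copy

        wide = copy.deepcopy(gsp)
        for e in wide.edges:
            if e.kind == "distance":
                e.min, e.max = 0.5, 7.0
            elif e.kind == "gap":
                e.min, e.max = 1, UNBOUNDED
        assert len(search_structure(wide, st)) >= base
        # deleting any single edge
        for i in range(len(gsp.edges)):
            pruned = copy.deepcopy(gsp)
            del pruned.edges[i]
            assert len(search_structure(pruned, st)) >= base

    def test_order_edges_never_add_hits(self, rng):
        """Gap edges restrict unordered patterns (the mirror-cut direction)."""
        from gspsearch.gsp_model import parse_prosite_linear

        unordered = parse_prosite_linear("C-x(2,4)-C", ligand_code="ZN")
        gap_edges = [e for e in unordered.edges if e.kind == "gap"]
        free = GspGraph(
            nodes=unordered.nodes,
            edges=[e for e in unordered.edges if e.kind != "gap"],
        )
        spec = FixtureSpec(n_residues=25, pattern=unordered, n_planted=2, seed=9)
        st, _ = generate_structure(spec)
        n_free = len(search_structure(free, st))
        n_ordered = len(search_structure(unordered, st))
        assert n_ordered <= n_free
        # the symmetric free pattern counts both mirrors of each site
        assert n_free == 2 * n_ordered
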