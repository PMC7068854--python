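"""Relational backend: schema, loading, compilation, executor equivalence."""

import sqlite3

import numpy as np
import pytest

from conftest import ZINC_FINGER_PATTERNS
from gspsearch.gsp_model import (
    GspEdge,
    GspGraph,
    GspNode,
    parse_prosite_linear,
)
from gspsearch.match_engine import PatternValidationError, search
from gspsearch.sql_backend import (
    SchemaConflictError,
    TABLES,
    compile,
    connect,
    create_schema,
    execute,
    load_cath,
    load_structure,
    loaded_pdb_ids,
)
from gspsearch.structure_model import build_contacts, next_pairs
from gspsearch.synthetic_fixtures import (
    FixtureSpec,
    generate_structure,
    random_pattern,
    random_structure,
)


@pytest.fixture
def db():
    conn = connect(":memory:")
    create_schema(conn)
    return conn


def load(conn, st):
    return load_structure(conn, st, build_contacts(st), next_pairs(st))


class TestSchema:
    def test_fresh_db_has_all_tables(self, db):
        names = {
            r[0] for r in db.execute(
                "SELECT name FROM sqlite_master WHERE type='table'"
            )
        }
        assert set(TABLES) <= names
        assert len(TABLES) == 10

    def test_rerun_fails_cleanly(self, db):
        with pytest.raises(SchemaConflictError):
            create_schema(db)

    def test_foreign_key_enforced(self, db):
        with pytest.raises(sqlite3.IntegrityError):
            db.execute(
                "INSERT INTO amino VALUES ('X_A_1', 'NOPE', 1, 'GLY', 'GLY')"
            )

    def test_standard_amino_has_21_names(self, db):
        (n,) = db.execute("SELECT COUNT(*) FROM standard_amino").fetchone()
        assert n == 21


class TestLoad:
    def test_next_rows_are_n_minus_1(self, db, rng):
        st = random_structure(rng, max_residues=10)
        counts = load(db, st)
        assert counts["next_amino_amino"] == len(st.residues) - 1

    def test_distance_rows_match_contacts(self, db, rng):
        st = random_structure(rng)
        contacts = build_contacts(st)
        load_structure(db, st, contacts, next_pairs(st))
        n_aa = sum(1 for c in contacts if c.kind == "amino_amino")
        n_la = sum(1 for c in contacts if c.kind == "ligand_amino")
        assert db.execute(
            "SELECT COUNT(*) FROM distance_amino_amino"
        ).fetchone()[0] == n_aa
        assert db.execute(
            "SELECT COUNT(*) FROM distance_ligand_amino"
        ).fetchone()[0] == n_la

    def test_select_back_distances_exact(self, db, rng):
        """Load fidelity: stored distances equal build_contacts output."""
        st = random_structure(rng)
        contacts = build_contacts(st)
        load_structure(db, st, contacts, next_pairs(st))
        stored = {
            (a, b): d
            for a, b, d in db.execute(
                "SELECT amino1_id, amino2_id, distance FROM distance_amino_amino"
            )
        }
        stored.update({
            (a, b): d
            for a, b, d in db.execute(
                "SELECT ligand_id, amino_id, distance FROM distance_ligand_amino"
            )
        })
        expected = {(c.a_id, c.b_id): c.distance for c in contacts}
        assert stored.keys() == expected.keys()
        for k in stored:
            assert stored[k] == pytest.approx(expected[k], abs=1e-6)

    def test_duplicate_load_inserts_nothing(self, db, rng):
        st = random_structure(rng)
        load(db, st)
        counts = load(db, st)
        assert all(v == 0 for v in counts.values())
        assert loaded_pdb_ids(db) == {st.pdb_id}

    def test_atomicity_on_midload_failure(self, rng):
        """A failing bulk load leaves no partial rows behind."""
        conn = connect(":memory:")
        create_schema(conn)
        st = random_structure(rng)
        # duplicate atom id -> primary-key violation mid-bulk, after the
        # protein and amino rows have been sent
        st.residues[-1].atoms[0] = st.residues[0].atoms[0]
        with pytest.raises(sqlite3.IntegrityError):
            load_structure(conn, st, build_contacts(st), next_pairs(st))
        for table in ("protein", "amino", "ligand", "distance_amino_amino"):
            assert conn.execute(
                f"SELECT COUNT(*) FROM {table}"
            ).fetchone()[0] == 0


class TestCompile:
    def test_single_ligand_distance_edge_uses_dla_table(self):
        gsp = GspGraph(
            nodes=[
                GspNode(node_id="a", kind="amino", name="CYS"),
                GspNode(node_id="l", kind="ligand", code="ZN"),
            ],
            edges=[GspEdge("distance", "l", "a", min=1.0, max=3.0)],
        )
        cq = compile(gsp)
        assert "distance_ligand_amino" in cq.sql_text
        assert "BETWEEN" in cq.sql_text
        assert "ZN" in cq.params.values() and "CYS" in cq.params.values()

    def test_single_node_pattern_queries_amino_only(self):
        gsp = GspGraph(nodes=[GspNode(node_id="a", kind="amino", name="HIS")])
        cq = compile(gsp)
        assert "FROM amino a0" in cq.sql_text
        assert "distance_" not in cq.sql_text

    def test_amino_amino_distance_probes_both_orientations(self):
        gsp = GspGraph(
            nodes=[GspNode(node_id="a", kind="amino", name="CYS"),
                   GspNode(node_id="b", kind="amino", name="HIS")],
            edges=[GspEdge("distance", "a", "b", min=0.5, max=7.0)],
        )
        sql = compile(gsp).sql_text
        assert "amino1_id = a0.id AND" in sql and "amino1_id = a1.id AND" in sql

    def test_invalid_pattern_rejected(self):
        gsp = GspGraph(nodes=[], edges=[])
        with pytest.raises(PatternValidationError):
            compile(gsp)

    @pytest.mark.parametrize("name,expr", list(ZINC_FINGER_PATTERNS.items()))
    def test_zinc_patterns_compile_and_execute(self, db, rng, name, expr):
        """Every zinc-finger class compiles and runs on a fixture db."""
        st = random_structure(rng)
        load(db, st)
        gsp = parse_prosite_linear(expr, ligand_code="ZN")
        result = execute(db, compile(gsp))
        assert result.n_hits >= 0  # executes without error


class TestExecute:
    def test_empty_db_zero_hits(self, db):
        gsp = parse_prosite_linear("C-x(2)-C", ligand_code="ZN")
        result = execute(db, compile(gsp))
        assert result.n_hits == 0 and result.n_proteins == 0

    def test_planted_db_matches_memory_engine(self, db):
        gsp = parse_prosite_linear("C-x(2)-C-x(3)-H", ligand_code="ZN")
        spec = FixtureSpec(n_residues=36, pattern=gsp, n_planted=2, seed=4)
        st, truth = generate_structure(spec)
        load(db, st)
        got = execute(db, compile(gsp))
        mem = search(gsp, [st])
        assert got.hits == mem.hits
        assert {h.assignment for h in got.hits} == {t.assignment for t in truth}

    def test_widened_range_is_superset(self, db, rng):
        st = random_structure(rng)
        load(db, st)
        narrow = GspGraph(
            nodes=[GspNode(node_id="a", kind="amino", name="CYS"),
                   GspNode(node_id="l", kind="any_ligand")],
            edges=[GspEdge("distance", "l", "a", min=2.0, max=4.0)],
        )
        wide = GspGraph(
            nodes=narrow.nodes,
            edges=[GspEdge("distance", "l", "a", min=0.5, max=7.0)],
        )
        n_hits = {h.assignment for h in execute(db, compile(narrow)).hits}
        w_hits = {h.assignment for h in execute(db, compile(wide)).hits}
        assert n_hits <= w_hits

    @pytest.mark.parametrize("trial", range(30))
    def test_backend_equivalence_randomized(self, trial):
        """SQL and in-memory engines return identical hit lists."""
        rng = np.random.default_rng(3000 + trial)
        structures = [
            random_structure(rng, pdb_id=f"R{k:03d}")
            for k in range(int(rng.integers(1, 4)))
        ]
        gsp = random_pattern(rng)
        conn = connect(":memory:")
        create_schema(conn)
        for st in structures:
            load_structure(conn, st, build_contacts(st), next_pairs(st))
        sql_result = execute(conn, compile(gsp))
        mem_result = search(gsp, structures)
        assert sql_result.hits == mem_result.hits


def test_load_cath_annotations(db, rng):
    st = random_structure(rng)
    load(db, st)
    n = load_cath(db, {st.pdb_id: ["3.30.160.60"], "ABSENT": ["1.10.10.10"]})
    assert n == 1
    rows = db.execute("SELECT protein_id, cath_code FROM protein_cath").fetchall()
    assert rows == [(st.pdb_id, "3.30.160.60")]
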