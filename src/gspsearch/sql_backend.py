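"""Relational backend: schema, bulk loader, and the pattern→SQL compiler.

The schema mirrors the pre-processing products: per-protein tables of
residues, ligands and atoms, plus the pre-computed relations
``distance_amino_amino``, ``distance_ligand_amino`` (minimum atom-pair
distances at or below 7.0 Å) and ``next_amino_amino`` (chain order).
Distance tables are denormalized — they repeat residue names, ligand
codes and sequence indexes — so pattern queries avoid extra joins, and
the hot columns are indexed.

The compiler turns a validated pattern graph into one SQL query by
emitting a sub-expression per node-edge-node structure and composing
them: each amino node becomes an ``amino`` alias, the ligand node a
``ligand`` alias, each distance edge joins a distance table, each next
edge joins ``next_amino_amino``, and gap edges become sequence-index
arithmetic.  One result row corresponds to one hit of the in-memory
reference engine.

The engine is embedded SQLite; the DDL and the generated queries stay
within the common SQL subset so a server backend remains possible.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass, field
from pathlib import Path

from .gsp_model import (
    AMINO_KINDS,
    GspGraph,
    LIGAND_KINDS,
    POLARITY_CLASSES,
    UNBOUNDED,
    validate,
)
from .match_engine import MatchHit, PatternValidationError, SearchResult
from .structure_model import ContactRecord, StructureRecord

__all__ = [
    "SchemaConflictError",
    "SqlExecutionError",
    "CompiledQuery",
    "TABLES",
    "connect",
    "create_schema",
    "load_structure",
    "load_cath",
    "loaded_pdb_ids",
    "compile",
    "execute",
]

#: Polarity of each standard residue, loaded into standard_amino.
_POLARITY_OF = {
    name: pol for pol, names in POLARITY_CLASSES.items() for name in names
}

TABLES = (
    "protein",
    "standard_amino",
    "amino",
    "ligand",
    "atom_amino",
    "atom_ligand",
    "distance_amino_amino",
    "distance_ligand_amino",
    "next_amino_amino",
    "protein_cath",
)

_DDL = """
CREATE TABLE protein (
    id             TEXT PRIMARY KEY,
    chain          TEXT NOT NULL,
    classification TEXT NOT NULL DEFAULT '',
    organism       TEXT NOT NULL DEFAULT ''
);
CREATE TABLE standard_amino (
    name     TEXT PRIMARY KEY,
    letter   TEXT NOT NULL,
    polarity TEXT NOT NULL
);
CREATE TABLE amino (
    id         TEXT PRIMARY KEY,
    protein_id TEXT NOT NULL REFERENCES protein(id),
    seq_index  INTEGER NOT NULL,
    code3      TEXT NOT NULL,
    name       TEXT NOT NULL REFERENCES standard_amino(name)
);
CREATE TABLE ligand (
    id         TEXT PRIMARY KEY,
    protein_id TEXT NOT NULL REFERENCES protein(id),
    code       TEXT NOT NULL
);
CREATE TABLE atom_amino (
    id       TEXT PRIMARY KEY,
    amino_id TEXT NOT NULL REFERENCES amino(id),
    element  TEXT NOT NULL,
    serial   INTEGER NOT NULL,
    x REAL NOT NULL, y REAL NOT NULL, z REAL NOT NULL
);
CREATE TABLE atom_ligand (
    id        TEXT PRIMARY KEY,
    ligand_id TEXT NOT NULL REFERENCES ligand(id),
    element   TEXT NOT NULL,
    serial    INTEGER NOT NULL,
    x REAL NOT NULL, y REAL NOT NULL, z REAL NOT NULL
);
CREATE TABLE distance_amino_amino (
    protein_id  TEXT NOT NULL REFERENCES protein(id),
    amino1_id   TEXT NOT NULL REFERENCES amino(id),
    amino2_id   TEXT NOT NULL REFERENCES amino(id),
    amino1_code TEXT NOT NULL,
    amino2_code TEXT NOT NULL,
    seq1        INTEGER NOT NULL,
    seq2        INTEGER NOT NULL,
    distance    REAL NOT NULL,
    PRIMARY KEY (amino1_id, amino2_id)
);
CREATE TABLE distance_ligand_amino (
    protein_id  TEXT NOT NULL REFERENCES protein(id),
    ligand_id   TEXT NOT NULL REFERENCES ligand(id),
    amino_id    TEXT NOT NULL REFERENCES amino(id),
    ligand_code TEXT NOT NULL,
    amino_code  TEXT NOT NULL,
    seq_index   INTEGER NOT NULL,
    distance    REAL NOT NULL,
    PRIMARY KEY (ligand_id, amino_id)
);
CREATE TABLE next_amino_amino (
    protein_id TEXT NOT NULL REFERENCES protein(id),
    amino1_id  TEXT NOT NULL REFERENCES amino(id),
    amino2_id  TEXT NOT NULL REFERENCES amino(id),
    PRIMARY KEY (amino1_id)
);
CREATE TABLE protein_cath (
    protein_id TEXT NOT NULL REFERENCES protein(id),
    cath_code  TEXT NOT NULL,
    PRIMARY KEY (protein_id, cath_code)
);
CREATE INDEX idx_amino_protein_code ON amino(protein_id, code3);
CREATE INDEX idx_amino_protein_seq ON amino(protein_id, seq_index);
CREATE INDEX idx_ligand_protein_code ON ligand(protein_id, code);
CREATE INDEX idx_daa_a1 ON distance_amino_amino(amino1_id);
CREATE INDEX idx_daa_a2 ON distance_amino_amino(amino2_id);
CREATE INDEX idx_daa_protein ON distance_amino_amino(protein_id, amino1_code, amino2_code);
CREATE INDEX idx_dla_lig ON distance_ligand_amino(ligand_id);
CREATE INDEX idx_dla_amino ON distance_ligand_amino(amino_id);
CREATE INDEX idx_dla_protein ON distance_ligand_amino(protein_id, ligand_code, amino_code);
CREATE INDEX idx_naa_a2 ON next_amino_amino(amino2_id);
CREATE INDEX idx_atom_amino ON atom_amino(amino_id);
CREATE INDEX idx_atom_ligand ON atom_ligand(ligand_id);
"""

# the 20 standard names + the catch-all
_STANDARD_ROWS = [
    ("ALA", "A"), ("ARG", "R"), ("ASN", "N"), ("ASP", "D"), ("CYS", "C"),
    ("GLN", "Q"), ("GLU", "E"), ("GLY", "G"), ("HIS", "H"), ("ILE", "I"),
    ("LEU", "L"), ("LYS", "K"), ("MET", "M"), ("PHE", "F"), ("PRO", "P"),
    ("SER", "S"), ("THR", "T"), ("TRP", "W"), ("TYR", "Y"), ("VAL", "V"),
    ("UND", "X"),
]


class SchemaConflictError(RuntimeError):
    """The database already contains a (possibly different) schema."""


class SqlExecutionError(RuntimeError):
    """A compiled query failed; carries the SQL text for debugging."""

    def __init__(self, message: str, sql_text: str):
        super().__init__(f"{message}\n--- compiled SQL ---\n{sql_text}")
        self.sql_text = sql_text


def connect(db_path: str | Path) -> sqlite3.Connection:
    """Open a database connection with foreign keys enforced."""
    conn = sqlite3.connect(str(db_path))
    conn.execute("PRAGMA foreign_keys = ON")
    return conn


def _existing_tables(conn: sqlite3.Connection) -> set[str]:
    rows = conn.execute(
        "SELECT name FROM sqlite_master WHERE type = 'table'"
    ).fetchall()
    return {r[0] for r in rows}


def create_schema(conn: sqlite3.Connection) -> None:
    """Create all tables and indexes in an empty database.

    Raises :class:`SchemaConflictError` if any schema table already
    exists; re-running on the same database fails cleanly.
    """
    existing = _existing_tables(conn)
    clash = existing & set(TABLES)
    if clash:
        raise SchemaConflictError(
            f"database already contains tables: {', '.join(sorted(clash))}"
        )
    with conn:
        conn.executescript(_DDL)
        conn.executemany(
            "INSERT INTO standard_amino (name, letter, polarity) VALUES (?, ?, ?)",
            [(n, l, _POLARITY_OF.get(n, "none")) for n, l in _STANDARD_ROWS],
        )


def loaded_pdb_ids(conn: sqlite3.Connection) -> set[str]:
    return {r[0] for r in conn.execute("SELECT id FROM protein")}


def load_structure(
    conn: sqlite3.Connection,
    structure: StructureRecord,
    contacts: list[ContactRecord],
    next_pairs: list[tuple[str, str]],
) -> dict[str, int]:
    """Bulk-load one structure atomically; returns per-table row counts.

    A pdb_id already present is skipped (all counts zero), so directory
    re-ingestion never duplicates rows.
    """
    if structure.pdb_id in loaded_pdb_ids(conn):
        return {t: 0 for t in TABLES if t not in ("standard_amino",)}

    seq_of = {r.amino_id: r.seq_index for r in structure.residues}
    code_of = {r.amino_id: r.code3 for r in structure.residues}
    lig_code_of = {l.ligand_id: l.code3 for l in structure.ligands}
    counts = {t: 0 for t in TABLES if t not in ("standard_amino",)}
    pid = structure.pdb_id
    with conn:  # single transaction: all or none
        conn.execute(
            "INSERT INTO protein (id, chain, classification, organism) VALUES (?,?,?,?)",
            (pid, structure.chain_id, structure.classification, structure.organism),
        )
        counts["protein"] = 1
        amino_rows = [
            (r.amino_id, pid, r.seq_index, r.code3, r.std_name)
            for r in structure.residues
        ]
        conn.executemany("INSERT INTO amino VALUES (?,?,?,?,?)", amino_rows)
        counts["amino"] = len(amino_rows)
        atom_rows = [
            (a.atom_id, r.amino_id, a.element, a.serial, *a.coords)
            for r in structure.residues
            for a in r.atoms
        ]
        conn.executemany("INSERT INTO atom_amino VALUES (?,?,?,?,?,?,?)", atom_rows)
        counts["atom_amino"] = len(atom_rows)
        lig_rows = [(l.ligand_id, pid, l.code3) for l in structure.ligands]
        conn.executemany("INSERT INTO ligand VALUES (?,?,?)", lig_rows)
        counts["ligand"] = len(lig_rows)
        latom_rows = [
            (a.atom_id, l.ligand_id, a.element, a.serial, *a.coords)
            for l in structure.ligands
            for a in l.atoms
        ]
        conn.executemany("INSERT INTO atom_ligand VALUES (?,?,?,?,?,?,?)", latom_rows)
        counts["atom_ligand"] = len(latom_rows)

        daa, dla = [], []
        for c in contacts:
            if c.kind == "amino_amino":
                daa.append(
                    (pid, c.a_id, c.b_id, code_of[c.a_id], code_of[c.b_id],
                     seq_of[c.a_id], seq_of[c.b_id], c.distance)
                )
            else:
                dla.append(
                    (pid, c.a_id, c.b_id, lig_code_of[c.a_id], code_of[c.b_id],
                     seq_of[c.b_id], c.distance)
                )
        conn.executemany(
            "INSERT INTO distance_amino_amino VALUES (?,?,?,?,?,?,?,?)", daa
        )
        counts["distance_amino_amino"] = len(daa)
        conn.executemany(
            "INSERT INTO distance_ligand_amino VALUES (?,?,?,?,?,?,?)", dla
        )
        counts["distance_ligand_amino"] = len(dla)
        naa = [(pid, a, b) for a, b in next_pairs]
        conn.executemany("INSERT INTO next_amino_amino VALUES (?,?,?)", naa)
        counts["next_amino_amino"] = len(naa)
    return counts


def load_cath(conn: sqlite3.Connection, cath_map: dict[str, list[str]]) -> int:
    """Load protein→CATH annotations for already-loaded proteins."""
    known = loaded_pdb_ids(conn)
    rows = [
        (pid, code)
        for pid, codes in cath_map.items()
        if pid in known
        for code in codes
    ]
    with conn:
        conn.executemany(
            "INSERT OR IGNORE INTO protein_cath VALUES (?,?)", rows
        )
    return len(rows)


# ---------------------------------------------------------------------------
# Pattern-graph -> SQL compilation

@dataclass
class CompiledQuery:
    """A pattern compiled to one SQL statement.

    ``columns`` records how result columns map back onto pattern
    entities so rows can be decoded into hits.
    """

    sql_text: str
    params: dict[str, object] = field(default_factory=dict)
    node_alias: dict[str, str] = field(default_factory=dict)
    # decode metadata
    node_order: list[str] = field(default_factory=list)
    amino_node_ids: list[str] = field(default_factory=list)
    distance_edge_indexes: list[int] = field(default_factory=list)
    gap_edge_indexes: list[tuple[int, str, str]] = field(default_factory=list)


def compile(gsp: GspGraph) -> CompiledQuery:  # noqa: A001 - domain verb
    """Compile a validated pattern graph into a single SQL query.

    Node predicates become WHERE equality/IN conditions, distance ranges
    BETWEEN conditions, next edges joins on ``next_amino_amino``, gap
    ranges sequence-index arithmetic, and injectivity pairwise
    inequalities between amino aliases.  Amino–amino distance edges
    probe both stored orientations of the unordered pair.
    """
    violations = validate(gsp)
    if violations:
        raise PatternValidationError(violations)

    params: dict[str, object] = {}
    node_alias: dict[str, str] = {}
    from_items: list[str] = []
    where: list[str] = []

    def bind(value: object) -> str:
        key = f"p{len(params)}"
        params[key] = value
        return f":{key}"

    amino_ids = [n.node_id for n in gsp.amino_nodes]
    for i, n in enumerate(gsp.amino_nodes):
        node_alias[n.node_id] = f"a{i}"
        from_items.append(f"amino a{i}")
    for n in gsp.ligand_nodes:
        node_alias[n.node_id] = "l0"
        from_items.append("ligand l0")

    aliases = list(node_alias.values())
    anchor = aliases[0]
    for al in aliases[1:]:
        where.append(f"{al}.protein_id = {anchor}.protein_id")

    # node predicates
    for n in gsp.nodes:
        al = node_alias[n.node_id]
        if n.kind == "amino":
            where.append(f"{al}.code3 = {bind(n.name)}")
        elif n.kind == "any_amino":
            if n.allowed is not None:
                marks = ", ".join(bind(c) for c in sorted(n.allowed))
                where.append(f"{al}.code3 IN ({marks})")
            elif n.polarity != "any":
                names = sorted(POLARITY_CLASSES[n.polarity])
                marks = ", ".join(bind(c) for c in names)
                where.append(f"{al}.name IN ({marks})")
        elif n.kind == "ligand":
            where.append(f"{al}.code = {bind(n.code)}")
        # any_ligand: membership in the ligand table is the predicate

    # injectivity over amino nodes
    for i in range(len(amino_ids)):
        for j in range(i + 1, len(amino_ids)):
            where.append(
                f"{node_alias[amino_ids[i]]}.id <> {node_alias[amino_ids[j]]}.id"
            )

    # edges: one sub-expression per node-edge-node structure
    dist_edges: list[int] = []
    gap_edges: list[tuple[int, str, str]] = []
    select_cols: list[str] = [f"{anchor}.protein_id AS pdb_id"]
    for n in gsp.nodes:
        select_cols.append(f"{node_alias[n.node_id]}.id AS id_{node_alias[n.node_id]}")
    for n in gsp.amino_nodes:
        al = node_alias[n.node_id]
        select_cols.append(f"{al}.seq_index AS seq_{al}")

    n_d = 0
    n_n = 0
    for idx, e in enumerate(gsp.edges):
        na, nb = gsp.node(e.a), gsp.node(e.b)
        ala, alb = node_alias[e.a], node_alias[e.b]
        if e.kind == "distance":
            dal = f"d{n_d}"
            n_d += 1
            if na.kind in LIGAND_KINDS or nb.kind in LIGAND_KINDS:
                lig_al, am_al = (ala, alb) if na.kind in LIGAND_KINDS else (alb, ala)
                from_items.append(f"distance_ligand_amino {dal}")
                where.append(f"{dal}.ligand_id = {lig_al}.id")
                where.append(f"{dal}.amino_id = {am_al}.id")
            else:
                from_items.append(f"distance_amino_amino {dal}")
                where.append(
                    f"(({dal}.amino1_id = {ala}.id AND {dal}.amino2_id = {alb}.id)"
                    f" OR ({dal}.amino1_id = {alb}.id AND {dal}.amino2_id = {ala}.id))"
                )
            where.append(
                f"{dal}.distance BETWEEN {bind(float(e.min))} AND {bind(float(e.max))}"
            )
            select_cols.append(f"{dal}.distance AS dist_{idx}")
            dist_edges.append(idx)
        elif e.kind == "next":
            nal = f"n{n_n}"
            n_n += 1
            from_items.append(f"next_amino_amino {nal}")
            where.append(f"{nal}.amino1_id = {ala}.id")
            where.append(f"{nal}.amino2_id = {alb}.id")
        else:  # gap: sequence-index arithmetic
            g = f"{alb}.seq_index - {ala}.seq_index - 1"
            where.append(f"{g} >= {bind(int(e.min))}")
            if e.max != UNBOUNDED:
                where.append(f"{g} <= {bind(int(e.max))}")
            gap_edges.append((idx, e.a, e.b))

    sql_text = (
        "SELECT "
        + ",\n       ".join(select_cols)
        + "\nFROM "
        + ",\n     ".join(from_items)
        + ("\nWHERE " + "\n  AND ".join(where) if where else "")
    )
    return CompiledQuery(
        sql_text=sql_text,
        params=params,
        node_alias=node_alias,
        node_order=[n.node_id for n in gsp.nodes],
        amino_node_ids=amino_ids,
        distance_edge_indexes=dist_edges,
        gap_edge_indexes=gap_edges,
    )


def execute(conn: sqlite3.Connection, cq: CompiledQuery) -> SearchResult:
    """Run a compiled query and decode rows into a canonical SearchResult."""
    try:
        cur = conn.execute(cq.sql_text, cq.params)
    except sqlite3.Error as exc:
        raise SqlExecutionError(str(exc), cq.sql_text) from exc
    cols = [d[0] for d in cur.description]
    hits: list[MatchHit] = []
    for row in cur:
        rec = dict(zip(cols, row))
        assignment = tuple(
            sorted(
                (nid, rec[f"id_{cq.node_alias[nid]}"]) for nid in cq.node_order
            )
        )
        dists = tuple((i, float(rec[f"dist_{i}"])) for i in cq.distance_edge_indexes)
        gaps = tuple(
            (
                i,
                int(rec[f"seq_{cq.node_alias[b]}"])
                - int(rec[f"seq_{cq.node_alias[a]}"])
                - 1,
            )
            for i, a, b in cq.gap_edge_indexes
        )
        hits.append(
            MatchHit(
                pdb_id=rec["pdb_id"],
                assignment=assignment,
                distances=dists,
                gaps=gaps,
            )
        )
    return SearchResult(hits).canonical()
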