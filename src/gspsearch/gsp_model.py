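"""The pattern language: graph-based structural patterns (GSPs).

A GSP is a labeled property graph describing a protein–ligand motif.
Nodes stand for amino acids (a specific residue, or a wildcard with an
optional polarity class) and ligands (a specific 3-letter hetero code,
or any ligand).  Edges impose structural constraints:

* ``distance`` — undirected; the minimum atom-pair distance between the
  two entities lies in ``[min, max]`` Å, within the global envelope
  0.5–7.0 Å;
* ``next`` — directed; the second residue immediately follows the first
  in the chain;
* ``gap`` — directed; the number of residues strictly between the two
  lies in ``[min, max]`` with ``min > 0`` (``max`` may be unbounded,
  written ``*``).

Patterns serialize to a small JSON dialect and can be imported from
PROSITE-style linear expressions such as ``C-x(2,4)-C-x(12)-H-x(2,6)-H``.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "GspNode",
    "GspEdge",
    "GspGraph",
    "PatternError",
    "UNBOUNDED",
    "NODE_KINDS",
    "EDGE_KINDS",
    "POLARITY_CLASSES",
    "DEFAULT_DISTANCE_RANGE",
    "validate",
    "to_json",
    "from_json",
    "parse_prosite_linear",
    "render_prosite_linear",
]

#: Sentinel for an unbounded gap maximum, serialized as "*".
UNBOUNDED = "*"

NODE_KINDS = ("amino", "any_amino", "ligand", "any_ligand")
EDGE_KINDS = ("distance", "next", "gap")
AMINO_KINDS = ("amino", "any_amino")
LIGAND_KINDS = ("ligand", "any_ligand")

#: Global distance-edge envelope in Å.
DISTANCE_ENVELOPE = (0.5, 7.0)
#: Default range assigned to a distance edge when none is given.
DEFAULT_DISTANCE_RANGE = (0.5, 7.0)

#: Polarity classes for any-amino nodes (standard textbook classification).
POLARITY_CLASSES: dict[str, frozenset[str]] = {
    "non-polar": frozenset(
        {"GLY", "ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "TRP"}
    ),
    "polar uncharged": frozenset({"SER", "THR", "CYS", "TYR", "ASN", "GLN"}),
    "positively charged": frozenset({"LYS", "ARG", "HIS"}),
    "negatively charged": frozenset({"ASP", "GLU"}),
}
POLARITY_VALUES = ("any",) + tuple(POLARITY_CLASSES)

#: 1-letter -> 3-letter amino-acid codes (PROSITE import).
ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


class PatternError(ValueError):
    """Raised for unparseable pattern text or JSON."""


@dataclass
class GspNode:
    """A pattern node.

    Exactly the fields relevant to ``kind`` are set: ``name`` for a
    specific amino acid, ``code`` for a specific ligand, ``polarity``
    (default ``any``) or an explicit ``allowed`` name set for an
    any-amino wildcard.
    """

    node_id: str
    kind: str
    name: str | None = None
    code: str | None = None
    polarity: str = "any"
    allowed: frozenset[str] | None = None


@dataclass
class GspEdge:
    """A pattern edge.

    ``a``/``b`` are node ids; for ``next`` and ``gap`` edges ``a``
    precedes ``b`` in sequence, ``distance`` edges are undirected.
    ``min``/``max`` are Å for distance, integers for gap; a gap max of
    :data:`UNBOUNDED` means no upper limit.
    """

    kind: str
    a: str
    b: str
    min: float | int | None = None
    max: float | int | str | None = None


@dataclass
class GspGraph:
    """A validated-on-demand pattern graph."""

    nodes: list[GspNode] = field(default_factory=list)
    edges: list[GspEdge] = field(default_factory=list)

    def node(self, node_id: str) -> GspNode:
        for n in self.nodes:
            if n.node_id == node_id:
                return n
        raise KeyError(node_id)

    @property
    def amino_nodes(self) -> list[GspNode]:
        return [n for n in self.nodes if n.kind in AMINO_KINDS]

    @property
    def ligand_nodes(self) -> list[GspNode]:
        return [n for n in self.nodes if n.kind in LIGAND_KINDS]

    def gap_edges(self) -> list[tuple[int, GspEdge]]:
        return [(i, e) for i, e in enumerate(self.edges) if e.kind == "gap"]

    def distance_edges(self) -> list[tuple[int, GspEdge]]:
        return [(i, e) for i, e in enumerate(self.edges) if e.kind == "distance"]

    def ligand_distance_edges(self) -> list[tuple[int, GspEdge]]:
        """Distance edges with exactly one ligand-kind endpoint."""
        out = []
        for i, e in enumerate(self.edges):
            if e.kind != "distance":
                continue
            kinds = {self.node(e.a).kind in LIGAND_KINDS,
                     self.node(e.b).kind in LIGAND_KINDS}
            if kinds == {True, False}:
                out.append((i, e))
        return out


def validate(gsp: GspGraph) -> list[str]:
    """Return all invariant violations (empty list means valid).

    Never raises on malformed data; every problem is reported as a
    human-readable string naming the offending node or edge.
    """
    violations: list[str] = []
    ids = [n.node_id for n in gsp.nodes]
    if not ids:
        violations.append("graph has no nodes")
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        violations.append(f"duplicate node ids: {', '.join(dupes)}")
    by_id = {n.node_id: n for n in gsp.nodes}

    n_ligand = 0
    for n in gsp.nodes:
        if n.kind not in NODE_KINDS:
            violations.append(f"node {n.node_id}: unknown kind {n.kind!r}")
            continue
        if n.kind in LIGAND_KINDS:
            n_ligand += 1
        if n.kind == "amino" and not n.name:
            violations.append(f"node {n.node_id}: amino node requires a name")
        if n.kind != "amino" and n.name:
            violations.append(f"node {n.node_id}: name is only valid on amino nodes")
        if n.kind == "ligand" and not n.code:
            violations.append(f"node {n.node_id}: ligand node requires a code")
        if n.kind != "ligand" and n.code:
            violations.append(f"node {n.node_id}: code is only valid on ligand nodes")
        if n.kind == "any_amino":
            if n.polarity not in POLARITY_VALUES:
                violations.append(
                    f"node {n.node_id}: unknown polarity {n.polarity!r}"
                )
        elif n.polarity != "any":
            violations.append(
                f"node {n.node_id}: polarity is only valid on any_amino nodes"
            )
        if n.allowed is not None and n.kind != "any_amino":
            violations.append(
                f"node {n.node_id}: allowed set is only valid on any_amino nodes"
            )
    if n_ligand > 1:
        violations.append(f"at most one ligand-kind node allowed, found {n_ligand}")

    for i, e in enumerate(gsp.edges):
        tag = f"edge {i} ({e.kind} {e.a}-{e.b})"
        if e.kind not in EDGE_KINDS:
            violations.append(f"edge {i}: unknown kind {e.kind!r}")
            continue
        endpoints = []
        for end in (e.a, e.b):
            if end not in by_id:
                violations.append(f"{tag}: endpoint {end!r} is not a node")
            else:
                endpoints.append(by_id[end])
        if len(endpoints) != 2:
            continue
        if e.a == e.b:
            violations.append(f"{tag}: self loops are not allowed")
            continue
        na, nb = endpoints
        if e.kind == "distance":
            if sum(n.kind in LIGAND_KINDS for n in (na, nb)) > 1:
                violations.append(
                    f"{tag}: distance edges join at most one ligand node"
                )
            lo, hi = e.min, e.max
            if not isinstance(lo, (int, float)) or not isinstance(hi, (int, float)):
                violations.append(f"{tag}: distance edge requires numeric min/max")
            elif not (DISTANCE_ENVELOPE[0] <= lo <= hi <= DISTANCE_ENVELOPE[1]):
                violations.append(
                    f"{tag}: distance range [{lo}, {hi}] outside "
                    f"{DISTANCE_ENVELOPE[0]}-{DISTANCE_ENVELOPE[1]} Å envelope"
                )
        else:  # next / gap: amino endpoints only
            for n in (na, nb):
                if n.kind not in AMINO_KINDS:
                    violations.append(
                        f"{tag}: {e.kind} edges join amino nodes only "
                        f"({n.node_id} is {n.kind})"
                    )
            if e.kind == "next":
                if e.min is not None or e.max is not None:
                    violations.append(f"{tag}: next edges take no min/max")
            else:  # gap
                lo, hi = e.min, e.max
                if not isinstance(lo, int) or isinstance(lo, bool) or lo <= 0:
                    violations.append(f"{tag}: gap min must be an integer > 0")
                elif hi != UNBOUNDED and (
                    not isinstance(hi, int) or isinstance(hi, bool) or hi < lo
                ):
                    violations.append(
                        f"{tag}: gap max must be >= min or '{UNBOUNDED}'"
                    )

    # connectivity (edges read as undirected), only meaningful if ids resolve
    if ids and not violations:
        seen = {ids[0]}
        frontier = [ids[0]]
        adj: dict[str, set[str]] = {i: set() for i in ids}
        for e in gsp.edges:
            adj[e.a].add(e.b)
            adj[e.b].add(e.a)
        while frontier:
            cur = frontier.pop()
            for nxt in adj[cur]:
                if nxt not in seen:
                    seen.add(nxt)
                    frontier.append(nxt)
        if len(seen) != len(ids):
            missing = sorted(set(ids) - seen)
            violations.append(f"graph is not connected; unreachable: {', '.join(missing)}")
    return violations


# ---------------------------------------------------------------------------
# JSON serialization

_NODE_KEYS = {"id", "kind", "name", "code", "polarity", "allowed"}
_EDGE_KEYS = {"kind", "a", "b", "min", "max"}


def to_json(gsp: GspGraph, indent: int | None = 2) -> str:
    """Serialize a pattern to its JSON dialect."""
    nodes = []
    for n in gsp.nodes:
        d: dict = {"id": n.node_id, "kind": n.kind}
        if n.name is not None:
            d["name"] = n.name
        if n.code is not None:
            d["code"] = n.code
        if n.kind == "any_amino" and n.polarity != "any":
            d["polarity"] = n.polarity
        if n.allowed is not None:
            d["allowed"] = sorted(n.allowed)
        nodes.append(d)
    edges = []
    for e in gsp.edges:
        d = {"kind": e.kind, "a": e.a, "b": e.b}
        if e.min is not None:
            d["min"] = e.min
        if e.max is not None:
            d["max"] = e.max
        edges.append(d)
    return json.dumps({"nodes": nodes, "edges": edges}, indent=indent)


def from_json(text: str) -> GspGraph:
    """Parse the JSON dialect back into a :class:`GspGraph`.

    Unknown keys and out-of-vocabulary kinds are rejected with the JSON
    path of the offence.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise PatternError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or set(doc) - {"nodes", "edges"}:
        extra = set(doc) - {"nodes", "edges"} if isinstance(doc, dict) else set()
        raise PatternError(f"top level must have keys nodes/edges only; got {sorted(extra)}")
    nodes = []
    for i, nd in enumerate(doc.get("nodes", [])):
        path = f"nodes[{i}]"
        if not isinstance(nd, dict):
            raise PatternError(f"{path}: expected object")
        if unknown := set(nd) - _NODE_KEYS:
            raise PatternError(f"{path}: unknown keys {sorted(unknown)}")
        if "id" not in nd or "kind" not in nd:
            raise PatternError(f"{path}: 'id' and 'kind' are required")
        if nd["kind"] not in NODE_KINDS:
            raise PatternError(f"{path}.kind: {nd['kind']!r} not in {NODE_KINDS}")
        allowed = nd.get("allowed")
        nodes.append(
            GspNode(
                node_id=str(nd["id"]),
                kind=nd["kind"],
                name=nd.get("name"),
                code=nd.get("code"),
                polarity=nd.get("polarity", "any"),
                allowed=frozenset(allowed) if allowed is not None else None,
            )
        )
    edges = []
    for i, ed in enumerate(doc.get("edges", [])):
        path = f"edges[{i}]"
        if not isinstance(ed, dict):
            raise PatternError(f"{path}: expected object")
        if unknown := set(ed) - _EDGE_KEYS:
            raise PatternError(f"{path}: unknown keys {sorted(unknown)}")
        for key in ("kind", "a", "b"):
            if key not in ed:
                raise PatternError(f"{path}: {key!r} is required")
        if ed["kind"] not in EDGE_KINDS:
            raise PatternError(f"{path}.kind: {ed['kind']!r} not in {EDGE_KINDS}")
        edges.append(
            GspEdge(
                kind=ed["kind"], a=str(ed["a"]), b=str(ed["b"]),
                min=ed.get("min"), max=ed.get("max"),
            )
        )
    return GspGraph(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# PROSITE-style linear expressions

_GAP_RE = re.compile(r"^x\((?P<lo>\d+|n)(?:,(?P<hi>\d+|\*))?\)$", re.IGNORECASE)
_ALT_RE = re.compile(r"^\[(?P<codes>[A-Z]+)\]$")


def parse_prosite_linear(expr: str, ligand_code: str | None = None) -> GspGraph:
    """Import a PROSITE-style linear expression as a pattern graph.

    Supported terms, dash-separated: 1-letter residue codes (``C``),
    alternations (``[LIVMFYWC]``, imported as an any-amino node with an
    explicit allowed-name set), and gap terms ``x(n)`` / ``x(n,m)`` /
    ``x(n,*)``; ``x(n)`` with a literal ``n`` means an unbounded gap of
    at least one residue.  Adjacent residue terms are joined by a
    ``next`` edge.  Leading/trailing gap terms constrain nothing and are
    dropped with a warning.

    When ``ligand_code`` is given, a ligand node is added with a
    default-range (0.5–7.0 Å) distance edge to every amino node.
    """
    tokens = [t.strip() for t in expr.strip().split("-")]
    if not tokens or tokens == [""]:
        raise PatternError("empty expression")

    nodes: list[GspNode] = []
    edges: list[GspEdge] = []
    pending_gap: tuple[int, int | str] | None = None
    n_amino = 0
    n_any = 0

    for pos, tok in enumerate(tokens):
        if not tok:
            raise PatternError(f"empty term at position {pos} in {expr!r}")
        if m := _GAP_RE.match(tok):
            if not nodes:
                warnings.warn(
                    f"leading gap term {tok!r} constrains nothing; ignored",
                    stacklevel=2,
                )
                continue
            lo_s, hi_s = m.group("lo"), m.group("hi")
            if lo_s.lower() == "n":
                lo, hi = 1, UNBOUNDED
            else:
                lo = int(lo_s)
                hi = (
                    lo if hi_s is None
                    else UNBOUNDED if hi_s == UNBOUNDED
                    else int(hi_s)
                )
            if pending_gap is not None:
                raise PatternError(
                    f"consecutive gap terms at position {pos} in {expr!r}"
                )
            pending_gap = (lo, hi)
            continue
        if m := _ALT_RE.match(tok):
            codes = m.group("codes")
            bad = [c for c in codes if c not in ONE_TO_THREE]
            if bad:
                raise PatternError(
                    f"unknown residue letter(s) {bad} at position {pos} in {expr!r}"
                )
            n_any += 1
            node = GspNode(
                node_id=f"x{n_any}",
                kind="any_amino",
                allowed=frozenset(ONE_TO_THREE[c] for c in codes),
            )
        elif tok.upper() in ONE_TO_THREE:
            n_amino += 1
            node = GspNode(
                node_id=f"a{n_amino}", kind="amino", name=ONE_TO_THREE[tok.upper()]
            )
        else:
            raise PatternError(f"unparseable term {tok!r} at position {pos} in {expr!r}")

        if nodes:
            prev = nodes[-1].node_id
            if pending_gap is not None:
                lo, hi = pending_gap
                edges.append(GspEdge("gap", prev, node.node_id, min=lo, max=hi))
            else:
                edges.append(GspEdge("next", prev, node.node_id))
        nodes.append(node)
        pending_gap = None

    if pending_gap is not None:
        warnings.warn(
            "trailing gap term constrains nothing; ignored", stacklevel=2
        )
    if not nodes:
        raise PatternError(f"no residue terms in {expr!r}")

    if ligand_code is not None:
        lig = GspNode(node_id="lig", kind="ligand", code=ligand_code.upper())
        for n in list(nodes):
            edges.append(
                GspEdge(
                    "distance", lig.node_id, n.node_id,
                    min=DEFAULT_DISTANCE_RANGE[0], max=DEFAULT_DISTANCE_RANGE[1],
                )
            )
        nodes.append(lig)

    return GspGraph(nodes=nodes, edges=edges)


def render_prosite_linear(gsp: GspGraph) -> str:
    """Render an expression-shaped pattern back to linear text.

    Inverse of :func:`parse_prosite_linear` for expressions without
    alternations; the ligand node and its distance edges are omitted.
    Raises :class:`PatternError` if the amino nodes do not form a single
    next/gap chain.
    """
    aminos = gsp.amino_nodes
    succ: dict[str, tuple[str, GspEdge]] = {}
    has_pred: set[str] = set()
    for e in gsp.edges:
        if e.kind in ("next", "gap"):
            if e.a in succ:
                raise PatternError(f"node {e.a} has two successors; not a chain")
            succ[e.a] = (e.b, e)
            has_pred.add(e.b)
    starts = [n for n in aminos if n.node_id not in has_pred]
    if len(aminos) > 1 and len(starts) != 1:
        raise PatternError("pattern is not a single sequence chain")
    cur = starts[0] if starts else aminos[0]
    parts: list[str] = []
    visited = 0
    while True:
        if cur.kind == "amino":
            parts.append(THREE_TO_ONE[cur.name])
        else:
            raise PatternError("alternation nodes have no canonical linear form")
        visited += 1
        nxt = succ.get(cur.node_id)
        if nxt is None:
            break
        to_id, edge = nxt
        if edge.kind == "gap":
            lo, hi = edge.min, edge.max
            parts.append(f"x({lo})" if lo == hi else f"x({lo},{hi})")
        cur = gsp.node(to_id)
    if visited != len(aminos):
        raise PatternError("pattern is not a single sequence chain")
    return "-".join(parts)
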