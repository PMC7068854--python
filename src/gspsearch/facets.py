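"""Post-search analytics: filtering, grouping and export of hit sets.

After a pattern search, hits can be sliced the way the result filters
of a motif-search front end would: by bound gap sizes, bound distances,
protein metadata (id, classification, organism), the identity a
wildcard node resolved to, or the ligand code.  Grouping summarizes the
hit set per keyword stem, per CATH level, or per realized gap-size
tuple, with per-edge mean ligand–amino distances — the sub-pattern
enumeration view of a motif family.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import pandas as pd

from .gsp_model import GspGraph
from .match_engine import MatchHit, SearchResult

__all__ = [
    "FacetError",
    "FacetSummary",
    "ProteinInfo",
    "filter_hits",
    "group_by_gap_sizes",
    "group_by_keywords",
    "group_by_cath",
    "mean_distances_by_group",
    "export",
    "import_result",
    "keyword_stem",
    "parse_cath_file",
]

CATH_LEVELS = ("class", "architecture", "topology", "homologous_superfamily")
NO_VALUE = "No value"
UNKNOWN_KEYWORD = "UNKNOWN"

_CATH_RE = re.compile(r"^\d+(\.\d+){0,3}$")


class FacetError(ValueError):
    """A filter or grouping referenced something that does not exist."""


@dataclass(frozen=True)
class ProteinInfo:
    """Per-protein metadata consulted by filters and keyword grouping."""

    classification: str = ""
    organism: str = ""


@dataclass
class FacetSummary:
    """One group of hits with its headline counts.

    ``mean_distances`` maps distance-edge index -> arithmetic mean of the
    bound value over the group's hits (unweighted).
    """

    key: object
    n_hits: int
    n_proteins: int
    mean_distances: dict[int, float] | None = None


def _summary(key: object, hits: list[MatchHit],
             dist_edges: Iterable[int] | None = None) -> FacetSummary:
    means = None
    if dist_edges is not None:
        means = {}
        for i in dist_edges:
            vals = [h.distance_dict[i] for h in hits if i in h.distance_dict]
            if vals:
                means[i] = sum(vals) / len(vals)
    return FacetSummary(
        key=key,
        n_hits=len(hits),
        n_proteins=len({h.pdb_id for h in hits}),
        mean_distances=means,
    )


# ---------------------------------------------------------------------------
# Filtering

def filter_hits(
    result: SearchResult,
    predicate: dict,
    protein_info: dict[str, ProteinInfo] | None = None,
) -> SearchResult:
    """Subset of hits satisfying every predicate; counts recompute.

    ``predicate`` keys (all optional, combined with AND):

    * ``"gaps"``: {gap-edge index: (min, max)} on the bound gap size;
    * ``"distances"``: {distance-edge index: (lo, hi)} on the bound Å;
    * ``"pdb_ids"``: iterable of admissible protein ids;
    * ``"classification_contains"`` / ``"organism_contains"``: substring
      match (case-insensitive; requires ``protein_info``);
    * ``"node_is"``: {node_id: entity id} exact resolution;
    * ``"ligand_code"``: 3-letter code the ligand-node entity id must
      reference (matched against the assignment of ``"ligand_node"``,
      default the single ligand node id in the assignment).

    An empty predicate is the identity.  Unknown predicate keys and
    references to edges a hit does not bind raise :class:`FacetError`.
    """
    known = {
        "gaps", "distances", "pdb_ids", "classification_contains",
        "organism_contains", "node_is",
    }
    if unknown := set(predicate) - known:
        raise FacetError(f"unknown predicate keys: {sorted(unknown)}")

    pdb_ids = set(predicate["pdb_ids"]) if "pdb_ids" in predicate else None

    def _meta(pdb_id: str) -> ProteinInfo:
        if protein_info is None:
            raise FacetError(
                "classification/organism filters require protein_info"
            )
        return protein_info.get(pdb_id, ProteinInfo())

    def keep(h: MatchHit) -> bool:
        if pdb_ids is not None and h.pdb_id not in pdb_ids:
            return False
        for idx, (lo, hi) in predicate.get("gaps", {}).items():
            if idx not in h.gap_dict:
                raise FacetError(f"hit binds no gap edge {idx}")
            if not lo <= h.gap_dict[idx] <= hi:
                return False
        for idx, (lo, hi) in predicate.get("distances", {}).items():
            if idx not in h.distance_dict:
                raise FacetError(f"hit binds no distance edge {idx}")
            if not lo <= h.distance_dict[idx] <= hi:
                return False
        if "classification_contains" in predicate:
            if (
                predicate["classification_contains"].upper()
                not in _meta(h.pdb_id).classification.upper()
            ):
                return False
        if "organism_contains" in predicate:
            if (
                predicate["organism_contains"].upper()
                not in _meta(h.pdb_id).organism.upper()
            ):
                return False
        for node_id, entity in predicate.get("node_is", {}).items():
            ad = h.assignment_dict
            if node_id not in ad:
                raise FacetError(f"hit assigns no node {node_id!r}")
            if ad[node_id] != entity:
                return False
        return True

    return SearchResult([h for h in result.hits if keep(h)])


# ---------------------------------------------------------------------------
# Grouping

def group_by_gap_sizes(
    result: SearchResult, gsp: GspGraph | None = None
) -> list[FacetSummary]:
    """One group per realized gap-size tuple (ordered by gap-edge index).

    Groups partition the hits, so their ``n_hits`` sum to the total.
    Mean distances are reported per ligand–amino distance edge when the
    pattern is given, else per every distance edge.
    """
    if gsp is not None:
        dist_edges = [i for i, _ in gsp.ligand_distance_edges()]
    else:
        dist_edges = sorted({i for h in result.hits for i in h.distance_dict})
    groups: dict[tuple, list[MatchHit]] = {}
    for h in result.hits:
        key = tuple(v for _, v in sorted(h.gaps))
        groups.setdefault(key, []).append(h)
    return [
        _summary(key, hits, dist_edges) for key, hits in sorted(groups.items())
    ]


def keyword_stem(classification: str) -> str:
    """Normalize a classification string to its keyword stem.

    The stem is the leading token sequence before any ``/`` or ``,``,
    uppercased; an empty classification maps to ``UNKNOWN``.
    """
    stem = re.split(r"[/,]", classification, maxsplit=1)[0].strip().upper()
    return stem or UNKNOWN_KEYWORD


def group_by_keywords(
    result: SearchResult, protein_info: dict[str, ProteinInfo]
) -> list[FacetSummary]:
    """Hit counts per normalized classification keyword stem.

    Sorted by descending hit count, then stem.
    """
    groups: dict[str, list[MatchHit]] = {}
    for h in result.hits:
        info = protein_info.get(h.pdb_id, ProteinInfo())
        groups.setdefault(keyword_stem(info.classification), []).append(h)
    return sorted(
        (_summary(stem, hits) for stem, hits in groups.items()),
        key=lambda s: (-s.n_hits, s.key),
    )


def group_by_cath(
    result: SearchResult,
    cath_map: dict[str, list[str]] | None = None,
    warn: Callable[[str], None] | None = None,
) -> list[FacetSummary]:
    """Hierarchical hit counts at each of the four CATH levels.

    A protein annotated ``3.30.160.60`` contributes to the groups
    ``3``, ``3.30``, ``3.30.160`` and ``3.30.160.60``; a protein with no
    (or malformed) annotation falls into the ``No value`` bucket.  A
    hit with several annotations counts once under each.  Summaries are
    ordered by code depth then code.
    """
    cath_map = cath_map or {}
    groups: dict[str, list[MatchHit]] = {}
    no_value: list[MatchHit] = []
    for h in result.hits:
        codes = cath_map.get(h.pdb_id, [])
        valid = []
        for code in codes:
            if not _CATH_RE.match(code):
                if warn is not None:
                    warn(f"malformed CATH code {code!r} for {h.pdb_id}")
                continue
            valid.append(code)
        if not valid:
            no_value.append(h)
            continue
        prefixes = set()
        for code in valid:
            parts = code.split(".")
            for depth in range(1, len(parts) + 1):
                prefixes.add(".".join(parts[:depth]))
        for p in prefixes:
            groups.setdefault(p, []).append(h)
    out = [
        _summary(code, hits)
        for code, hits in sorted(
            groups.items(), key=lambda kv: (kv[0].count("."), kv[0])
        )
    ]
    if no_value:
        out.append(_summary(NO_VALUE, no_value))
    return out


def mean_distances_by_group(
    result: SearchResult,
    gsp: GspGraph,
    key: Callable[[MatchHit], object],
) -> pd.DataFrame:
    """Mean bound distance per ligand–amino edge, per group.

    ``key`` maps a hit to its group label (e.g. the protein's deepest
    CATH code).  Returns a table with one row per group, one column per
    ligand–amino distance edge, plus ``n_hits``.
    """
    dist_edges = [i for i, _ in gsp.ligand_distance_edges()]
    groups: dict[object, list[MatchHit]] = {}
    for h in result.hits:
        groups.setdefault(key(h), []).append(h)
    rows = []
    for gkey, hits in sorted(groups.items(), key=lambda kv: str(kv[0])):
        row: dict[str, object] = {"group": gkey, "n_hits": len(hits)}
        for i in dist_edges:
            vals = [h.distance_dict[i] for h in hits if i in h.distance_dict]
            row[f"edge_{i}"] = sum(vals) / len(vals) if vals else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def parse_cath_file(path: str | Path) -> dict[str, list[str]]:
    """Read a tab-separated ``pdb_id<TAB>cath_code`` annotation file."""
    out: dict[str, list[str]] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t")
        if len(parts) < 2:
            continue
        out.setdefault(parts[0].upper(), []).append(parts[1])
    return out


# ---------------------------------------------------------------------------
# Export / import

def export(
    result: SearchResult,
    mode: str,
    path: str | Path,
    protein_info: dict[str, ProteinInfo] | None = None,
) -> None:
    """Write results to disk.

    ``mode="ids"`` writes the distinct protein ids, one per line and
    sorted; ``mode="json"`` writes the full hit list (assignments and
    bound values) plus protein metadata, re-importable with
    :func:`import_result`.
    """
    path = Path(path)
    if mode == "ids":
        ids = sorted({h.pdb_id for h in result.hits})
        path.write_text("".join(f"{i}\n" for i in ids))
        return
    if mode != "json":
        raise FacetError(f"unknown export mode {mode!r}")
    doc = {
        "hits": [
            {
                "pdb_id": h.pdb_id,
                "assignment": dict(h.assignment),
                "distances": {str(i): v for i, v in h.distances},
                "gaps": {str(i): v for i, v in h.gaps},
            }
            for h in result.hits
        ],
        "proteins": {
            pid: {"classification": info.classification, "organism": info.organism}
            for pid, info in sorted((protein_info or {}).items())
        },
    }
    path.write_text(json.dumps(doc, indent=2))


def import_result(
    path: str | Path,
) -> tuple[SearchResult, dict[str, ProteinInfo]]:
    """Inverse of :func:`export` in json mode."""
    doc = json.loads(Path(path).read_text())
    hits = [
        MatchHit(
            pdb_id=h["pdb_id"],
            assignment=tuple(sorted(h["assignment"].items())),
            distances=tuple(
                sorted((int(i), float(v)) for i, v in h["distances"].items())
            ),
            gaps=tuple(sorted((int(i), int(v)) for i, v in h["gaps"].items())),
        )
        for h in doc["hits"]
    ]
    info = {
        pid: ProteinInfo(
            classification=m.get("classification", ""),
            organism=m.get("organism", ""),
        )
        for pid, m in doc.get("proteins", {}).items()
    }
    return SearchResult(hits).canonical(), info
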