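# Methods

## The pattern model

A structural pattern is a connected labeled property graph.  Node
kinds: `amino` (a specific residue, property `name`), `any_amino` (a
wildcard with property `polarity` ∈ {any, non-polar, polar uncharged,
positively charged, negatively charged}, or an explicit allowed-name
set imported from a PROSITE alternation such as `[LIVMFYWC]`), `ligand`
(a specific 3-letter hetero code) and `any_ligand` (any non-water
hetero group).  At most one ligand-kind node is allowed per pattern;
multi-ligand patterns are out of scope.  Edge kinds and semantics:

| kind     | directed | constraint                                          |
|----------|----------|-----------------------------------------------------|
| distance | no       | min atom-pair distance ∈ [min, max] Å, 0.5 ≤ min ≤ max ≤ 7.0 |
| next     | yes      | seq(b) = seq(a) + 1                                 |
| gap      | yes      | g = seq(b) − seq(a) − 1 with min ≤ g (≤ max unless `*`), min > 0 |

`next` means *immediate* adjacency (gap of zero); "one or more residues
between" is expressed as a gap edge `x(1,*)`.  Distance edges are
undirected: the contact is stored once per unordered residue pair and
looked up symmetrically.

Polarity classes follow the standard textbook grouping: non-polar
{GLY, ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP}; polar uncharged {SER,
THR, CYS, TYR, ASN, GLN}; positively charged {LYS, ARG, HIS};
negatively charged {ASP, GLU}.  Non-standard polymer residues (e.g.
MSE) carry the standard name `UND` and match only wildcard nodes with
polarity `any`.

A hit is an injective assignment over the pattern's amino nodes (two
distinct amino nodes may not bind the same residue; without this the
mirror-count arithmetic of symmetric patterns breaks) together with an
assignment of the ligand node to one ligand group.  Each copy of a
ligand is a separate candidate, so a site with two equivalent Zn ions
yields one hit per ion; hits are not deduplicated across ligand copies.

## Pre-processing

PDB coordinate files (`*.pdb`, `*.ent`, optionally gzipped) are parsed
with gemmi.  Only the chain with the largest number of amino acids is
kept (ties break to the lexicographically smallest chain id; only
model 1 of multi-model files is read).  Residues are renumbered 1..n in
order of appearance, ignoring author numbering and insertion codes, so
gap arithmetic is well defined.  Hetero groups on the selected chain
that are not water (HOH/DOD/WAT) become ligands.  For alternate
locations, the first-listed atom per atom name is kept; all atoms
present in the file (hydrogens included, when deposited) enter the
distance computation.  Classification and organism are read from the
HEADER and SOURCE records directly, since gemmi does not surface the
SOURCE organism for PDB-format input.

Two relations are pre-computed per structure: the contact relation
(minimum Euclidean distance over all cross pairs of atoms, kept iff
≤ 7.0 Å — beyond that no interaction is assumed) and the next relation
(consecutive residue pairs).  Entity ids encode provenance
(`1B38_A_1_4` = atom 4 of residue 1 of chain A of entry 1B38) and are
unique within a database.

## The two backends

The **in-memory matcher** is the reference semantics: backtracking over
pattern nodes ordered by candidate count, checking each edge as soon as
both endpoints are assigned.  Pruning never changes the result: the
test suite holds it equal to exhaustive injective-assignment
enumeration recomputed from raw coordinates.

The **SQL backend** loads structures into a 10-table relational schema
(protein, standard_amino, amino, ligand, atom_amino, atom_ligand,
distance_amino_amino, distance_ligand_amino, next_amino_amino,
protein_cath).  The distance tables are denormalized — they repeat
residue codes, ligand codes and sequence indexes — so pattern queries
avoid joins against the atom tables, and the hot columns carry
composite indexes.  Loading is one transaction per structure (all rows
or none) and already-loaded pdb_ids are skipped, so re-ingesting a
directory is idempotent.

The compiler emits one sub-expression per node-edge-node structure of
the pattern graph and composes them into a single SELECT: each amino
node becomes an `amino` alias, the ligand node a `ligand` alias, each
distance edge joins its distance table (probing both stored
orientations of the unordered amino–amino pair), each next edge joins
`next_amino_amino`, and gap edges compile to sequence-index arithmetic
on the amino aliases rather than to chains of next-joins — equivalent
semantics with bounded join depth even for wide gaps such as
`x(35,50)`.  Node predicates become equality/IN conditions (polarity
classes expand to IN lists over standard names), distance ranges become
BETWEEN conditions, and injectivity becomes pairwise `<>` conditions
between amino aliases.  One result row decodes to one hit, including
the bound distance and gap values.  The engine is embedded SQLite; DDL
and generated queries stay within the common SQL subset, so a
client–server deployment remains a configuration change rather than a
rewrite.  Backend equivalence — identical hit lists from both engines
on randomized corpora and patterns — is the central correctness
property of the package and is enforced by the test suite and the
acceptance script; the 14 query templates that a published description
does not spell out are constrained by this property rather than by
reference SQL text.

## Result analytics

Filters restrict a hit set by bound gap sizes, bound distances, protein
id, classification/organism substring, wildcard-node resolution or
ligand code; counts are recomputed after filtering.  Grouping
summarizes hits per classification keyword stem (the leading token
sequence before any `/` or `,`, uppercased; empty → `UNKNOWN` — a
deliberately simple normalization, since deposited classification
strings are heterogeneous and incomplete), per CATH level (a protein
annotated `3.30.160.60` counts under `3`, `3.30`, `3.30.160` and
`3.30.160.60`; unannotated or malformed codes fall into a `No value`
bucket), and per realized gap-size tuple, with unweighted arithmetic
means of each ligand–amino bound distance per group.  Results export as
a protein-id list or as JSON from which every facet is recomputable.

## Synthetic fixtures

The generator builds single-chain toy structures whose planted-pattern
hit set is known exactly by construction, so recovery tests have a
ground truth that does not depend on the engines under test.

Geometry: residue anchors advance ~3.8 Å per residue (the typical
Cα–Cα spacing) along a mildly jittered extended path, so residues more
than one sequence position apart lie beyond the 7 Å cutoff and the only
amino–amino contacts are sequence neighbours.  Planted sites are placed
at a fixed stride along the chain; each site's pattern residues are
pulled onto a sphere around a dedicated ligand copy such that every
ligand-distance edge binds a value strictly inside `[min+0.1,
max−0.1]` (the 0.1 Å margin avoids boundary float ambiguity), with the
residue's remaining atoms displaced away from the ligand so the first
atom realizes the minimum distance exactly.  Gap sizes are drawn per
site from the edge's minimum up to `min+3` (bounded by the edge
maximum), so a multi-site fixture realizes several sub-pattern gap
tuples.

Exactness rests on three construction rules rather than on
probability: decoy residues never share a code with any planted name
(they fail every node predicate); decoy anchors keep ≥ 10 Å from every
ligand; and sites are spaced so that a residue within 7 Å of its own
ligand is > 7 Å from every other site's ligand.  To guarantee the last
two rules suffice, planted patterns must connect the ligand to *every*
amino node by a distance edge, and ligand-less patterns may be planted
at most once per structure — specs violating this are rejected rather
than silently approximated.  The ground truth is then enumerated
site-locally (name-filtered injective assignments, constraints checked
directly from coordinates and sequence indexes), independent of the
search engines.

What the fixtures do **not** emulate: real backbone geometry and
side-chain chemistry, crystallographic artifacts (altlocs, partial
occupancy, symmetry mates), multi-chain contacts, and realistic
residue-composition statistics.  Passing recovery tests therefore
demonstrates correctness of the matching semantics and of the
relational pipeline, not biological sensitivity/specificity on real
binding sites.

A second generator family (`random_structure` / `random_pattern`)
throws residues and ligands into a compact box to produce dense,
unstructured contact graphs with no known ground truth; these exercise
backend equivalence and enumeration equivalence, where the oracle is
exhaustive search rather than construction.

## Numerical and design choices

* Contact cutoff 7.0 Å and distance-edge envelope 0.5–7.0 Å are fixed
  model constants; the ingestion cutoff is configurable but defaults to
  the envelope maximum, and stored distances never exceed it.
* Distances are stored as IEEE doubles; SQLite REAL round-trips them
  bit-exactly, so the backend-equivalence tests compare hit distance
  bindings with exact equality.
* Hits are canonically ordered by (pdb_id, assignment) before any
  comparison or export.
* PROSITE import: `x(n)` with a literal `n` denotes an indeterminate
  gap and is read as `x(1,*)`; leading/trailing gap terms constrain
  nothing and are dropped with a warning; adjacent residue letters
  (`C-P`) become next edges.  The full PROSITE grammar (repeated
  alternations, terminal anchors) is out of scope.
* Pattern JSON is this package's own documented dialect (closed
  vocabulary, unknown keys rejected); no interoperability with other
  tools' pattern files is claimed.
* The synthetic corpora used by the test suite and the acceptance
  script are sized at desk scale — structures of ≤ 25–60 residues,
  corpora of 1–3 structures, 30–200 randomized repetitions per
  property — which keeps every property check exact (exhaustive
  oracles included) while the whole verification run completes in
  seconds.

## Known limitations

* One chain per entry; inter-chain binding sites and symmetry-related
  contacts are invisible.
* Hit counts on real archives are snapshot-dependent by nature; this
  package verifies invariants, not published archive-wide tallies.
* The keyword-stem normalization is intentionally crude; curated
  keyword taxonomies would group classifications differently.
* Approximate or geometry-superposition matching (RMSD) is not
  offered; all constraints are exact interval tests.
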