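# Methods

## Data model

A dataset is a named table: an ordered list of columns, one designated the
identifier ("touch point") column, and ordered rows of uninterpreted string
cells. Duplicate identifiers across rows are legal — one gene may carry
several annotation rows — and empty identifier cells are not. Cell values
are never typed or parsed: the algebra operates on identifiers only, and
attributes are payload carried through merges verbatim. TSV is the
canonical dialect (CSV accepted with RFC-4180 quoting); reading strips
surrounding whitespace from cells, and writing quotes delimiter-bearing
cells so that write-then-read is the identity on content.

## Identity by fingerprint hashing

Aliases are resolved without a reference nomenclature. An identifier is
registered with a fingerprint: a sequence, a chemical formula, a URI, or
opaque content. Canonicalization makes fingerprint comparison
representation-independent — sequences lose all internal whitespace and are
upper-cased; other kinds are trimmed. The key is a 160-bit digest of the
canonical text's UTF-8 bytes, rendered as 40 lower-case hex characters.

* **Digest choice.** The default is SHA-1, the standard 160-bit digest
  (`sha160-standard`); a SHA-256 digest truncated to 160 bits
  (`sha2-truncated`) is available and fixed per registry. Collision
  resistance in the cryptographic sense is irrelevant here; the key only
  needs to be a practically injective content address, which both choices
  provide (the suite checks zero collisions over 10^5 random fingerprints).
* The fingerprint *kind* is deliberately not mixed into the digest: equal
  canonical texts are the same identity assertion however they were
  labelled.
* The registry is a many-to-many relation. A gene parent registered once
  per variant sequence maps to several keys; one key maps back to every
  identifier that shares the fingerprint. Unregistered identifiers resolve
  to the empty key set and are still matched by exact string downstream.

## Consolidation

Identifiers appearing in the participating datasets are grouped into
entity groups: nodes are identifiers (exact string matches collapse to one
node; an optional global case-insensitive mode collapses spellings), and an
edge joins two identifiers whose key sets intersect. Groups are the
connected components — transitive closure of pairwise links, **not**
cliques. The clique reading would keep two protein variants apart even when
their gene parent carries a key of each; only the transitive reading merges
the whole family through the parent, which is the intended semantics of the
alias network.

Two further choices were genuinely open:

* **Registry-only identifiers never bridge.** Only identifiers present in
  some participating dataset are graph nodes. Otherwise a registry parent
  would merge its variants even in analyses where it appears in no dataset,
  and the "variants alone stay separate" behaviour would be unobtainable.
* **Alias members are attached after grouping.** A registry identifier
  whose keys all fall inside one group's key set is added to that group's
  member list, so the reported `aliases` column carries the complete alias
  neighbourhood (parent, variants, external accessions). Because distinct
  groups never share keys, the nonempty-subset rule attaches each alias to
  at most one group, preserving the partition invariants. A registry parent
  whose keys straddle two groups is attached to neither.

## Query evaluation

Queries are parsed by a recursive-descent parser with the precedence
parentheses > `-` > `+` > `U`, each level left-associative; unknown names,
unbalanced parentheses and dangling operators are rejected with character
positions. Evaluation consolidates **once, globally**, over every dataset
the query references, then folds the AST over group-sets: a dataset
reference denotes the groups with at least one row in that dataset; AND
intersects, OR unites, and `-` is the left-relative complement (no
universal set exists over open-ended gene lists). A pairwise
merge-then-merge-again procedure that re-resolves aliases at each step
reaches the same fixed point; the global formulation guarantees it
directly, and makes intersection and union commutative by construction
rather than by parse shape.

The output table has one row per surviving group: `id` (the group's
first-appearing member), `aliases` (all members, `;`-joined, sorted), then
every source dataset's attribute columns prefixed `<dataset>.<column>`.
Multi-row groups aggregate cells with `"; "` in row order; sources absent
from a group leave empty cells. Row order is group first-appearance
(dataset order, then row order), making output deterministic.

Touch-point switching re-keys a table on another column, dropping (and
counting) rows whose new identifier cell is empty; this chains complex
comparisons, e.g. drug → target tables re-keyed on targets and intersected
with gene lists.

## Synthetic fixtures

The generator emulates the two structures the engine must handle, and its
defaults are the study conditions used throughout the tests:

* **Benchmark shape** — `n_datasets` tables of `ids_per_dataset` rows; a
  fraction `overlap_fraction` of each is drawn from a pool present in every
  dataset, the rest are seed-specific unique tokens. The reference scale is
  10 datasets of 20,000 identifiers (200,000 combined) at full overlap,
  whose 10-way chained intersection must contain exactly 20,000 groups.
* **Alias families** — each family is a gene parent with `variant_count`
  protein variants; each variant and one external accession are registered
  with the variant's random sequence, and the parent with every variant's
  sequence. Variants are placed in dataset 1 and parents in dataset 2
  (inside the non-shared identifier slots, so row counts stay exact), which
  forces consolidation to merge the family *across* datasets through the
  parent's keys. Consequently families require at least two datasets and
  spare non-shared slots, and a family survives the full chained
  intersection only when there are exactly two datasets; the manifest's
  expected-intersection count accounts for this.

Generation is deterministic: identical specs (seed included) yield
byte-identical files. What the generator does **not** emulate: realistic
sequence content, biologically plausible identifier nomenclatures,
asymmetric pairwise overlaps, or noisy/incorrect alias links. Passing
tests therefore demonstrate the algebra and alias resolution are correct
under controlled overlap and clean alias networks, not that any curated
alias database is accurate.

## Verification strategy

Two independent oracles back the suite. Grouping is cross-checked against
a repeated-pass transitive-closure oracle; query evaluation against a
canonicalize-then-naive-set-algebra oracle (replace each identifier by its
closure-class label, then apply plain set operations). Both are brute
force and share no code with the engine's graph/consolidation path. The
frozen reference digest in the hash tests was computed beforehand with two
independent SHA-1 implementations. Hash-key and round-trip invariants are
exercised property-based (seeded/derandomized). Oracle comparisons use the
query's own consolidation universe (the datasets it references), since
group membership — and hence group identity — is defined relative to that
universe; for the same reason, algebraic identities are asserted with both
sides phrased over one universe (within {A, B}, `A + (A U B)` denotes A's
own group-set).

## Problem sizes and numerical choices

The random-instance suites use up to 5 datasets over pools of up to 50
identifiers with random alias links — small enough for the quadratic
brute-force oracles, large enough to hit chained merges, duplicate rows
and empty results; 1,000 instances for oracle agreement and 100 for the
identity suite. The scaling check runs the full 10 × 20,000 benchmark
shape in-process (a few seconds on one CPU; absolute runtimes are
hardware-dependent and are not asserted beyond completion and the correct
intersection size). There are no tolerances anywhere: every comparison in
the engine is exact string or exact set equality.

## Limitations

* Alias links are taken at face value; there is no probabilistic or
  fuzzy matching, and one wrong fingerprint can chain two large families
  into one group (transitive closure is unforgiving by design).
* Consolidation is per query over the referenced datasets; group
  membership is not comparable across queries with different universes.
* Whole tables are held in memory; multi-GB streaming is out of scope.
* Case-insensitivity is a single global switch, not per-dataset.
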