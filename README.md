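# boolmerge

Boolean set algebra over heterogeneous tabular datasets, with identifier
reconciliation through fingerprint hashing.

## The problem

Biologists routinely need to combine gene, protein or drug lists that come
from different sources: a microarray hit list keyed by gene symbols, a
proteomics table keyed by Ensembl protein IDs, an annotation table keyed by
RefSeq accessions. Two obstacles make this tedious:

1. **The algebra.** The questions are set-theoretic — "genes in A and B but
   not C" — but spreadsheets have no intersection, union or subtraction.
2. **The aliasing problem.** The same entity carries different names across
   sources, so a naive string join silently misses most of the real overlap.

`boolmerge` addresses both. Datasets are plain tables with one designated
identifier column (the *touch point*). Queries combine named datasets with
three operators:

| operator | meaning |
|---|---|
| `A + B` | intersection (AND): entities with rows in both |
| `A U B` | union (OR): entities with rows in either |
| `A - B` | subtraction (NOT): entities in A with no row in B |

Precedence, highest first: parentheses, `-`, `+`, `U`; repeated operators
bind left to right. `U` is a reserved word; names containing spaces or
operators are double-quoted.

Aliasing is resolved without any central nomenclature: an identifier is
registered with a *fingerprint* — content that defines the entity
independent of naming, such as a sequence, a chemical formula or a URI —
and the 160-bit digest of the canonicalized fingerprint (40 hex characters,
SHA-1 by default) is its non-semantic *hash key*. Identifiers are grouped
into entities by exact string match or by sharing a key, closed
transitively (connected components). A gene parent registered with each of
its protein variants' sequences therefore merges the whole family into one
entity, while the variants alone — distinct sequences, distinct keys — stay
separate. Boolean operations act on these consolidated entity groups, not
on raw strings.

## Worked example

Two lists that share no identifier string, plus an alias table asserting
that gene `CG6995`'s sequence fingerprints point to its protein variants
`CG6995-PA` / `CG6995-PC` (which in turn share fingerprints with the
accessions `FPpp00084077` / `NP_001034066`):

```console
$ boolmerge -q import variants.tsv       # id: CG6995-PA, CG6995-PC
variants: 2 rows, id column 'id'
$ boolmerge -q import parents.tsv        # id: CG6995, sna
parents: 2 rows, id column 'id'
$ boolmerge -q alias-load aliases.tsv
alias table: 6 entries
$ boolmerge -q query "variants + parents" --out merged.tsv
surviving groups: 1
$ cat merged.tsv
id	aliases	variants.note	parents.source
CG6995-PA	CG6995;CG6995-PA;CG6995-PC;FPpp00084077;NP_001034066	proteomics hit; proteomics hit	microarray up
```

One entity group survives the intersection: the alias network merged all
five names into a single entity with rows in both tables. The output keeps
every source's attribute columns (prefixed by dataset name), aggregates
multi-row groups with `"; "`, and lists the full membership in `aliases`.
Without alias resolution the same query finds nothing, since the tables
share no literal string:

```console
$ boolmerge -q query "variants + parents" --no-alias
surviving groups: 0
```

A result can be re-keyed on another column (`boolmerge switch`) to chain
further comparisons — e.g. re-key a drug → target table on "target" and
intersect it with a gene list.

The same operations are available as a library:

```python
from boolmerge import read_table, load_alias_table, evaluate

datasets = {name: read_table(f"{name}.tsv") for name in ("variants", "parents")}
registry = load_alias_table("aliases.tsv")
result = evaluate("variants + parents", datasets, registry=registry)
print(result.group_count)          # 1
print(result.groups[0].members)    # the five merged names
```

`boolmerge simulate` generates seeded synthetic dataset collections with
controlled overlap and gene/variant alias families for testing and
benchmarking (see `boolmerge.synth_fixtures`).

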