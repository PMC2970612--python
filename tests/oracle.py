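"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the engine's graph/consolidation code paths:
grouping is done by repeated-pass transitive closure over the pairwise
match relation, and Boolean queries are evaluated as naive set algebra
over closure-class labels. Slow but obviously correct at small n.
"""

from __future__ import annotations

import random

from boolmerge.aliasing import AliasRegistry, canonicalize
from boolmerge.datamodel import Dataset
from boolmerge.query_engine import And, DatasetRef, Node, Not, Or


def brute_force_classes(
    identifiers: list[str], registry: AliasRegistry | None
) -> list[frozenset[str]]:
    """Transitive closure of the pairwise match relation, by repeated passes.

    Two identifiers match when their strings are equal or their registered
    key sets intersect. Registry-only identifiers are not grouped.
    """
    groups: list[set[str]] = [{i} for i in set(identifiers)]

    def keys_of(group: set[str]) -> set[str]:
        out: set[str] = set()
        if registry is not None:
            for ident in group:
                out |= registry.resolve_keys(ident)
        return out

    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if groups[a] and groups[b] and keys_of(groups[a]) & keys_of(groups[b]):
                    groups[a] |= groups[b]
                    groups[b] = set()
                    changed = True
    return [frozenset(g) for g in groups if g]


def brute_force_query(
    root: Node,
    datasets: dict[str, Dataset],
    registry: AliasRegistry | None,
) -> set[frozenset[str]]:
    """Canonicalize-then-set-algebra evaluation of a query AST.

    Every dataset identifier is first replaced by its closure-class label;
    the AST is then evaluated as naive set operations on label sets. The
    result is the set of surviving classes, each as the frozenset of
    dataset identifiers it contains. Classes are built over the datasets
    the query references (the evaluation universe), matching the engine's
    contract that consolidation runs over the datasets named in the query.
    """
    datasets = referenced_datasets(root, datasets)
    all_ids = [i for ds in datasets.values() for i in ds.identifiers()]
    classes = brute_force_classes(all_ids, registry)
    label_of = {ident: cls for cls in classes for ident in cls}

    def fold(node: Node) -> set[frozenset[str]]:
        if isinstance(node, DatasetRef):
            return {label_of[i] for i in datasets[node.name].identifiers()}
        left, right = fold(node.left), fold(node.right)
        if isinstance(node, And):
            return left & right
        if isinstance(node, Or):
            return left | right
        return left - right

    return fold(root)


def referenced_datasets(root: Node, datasets: dict[str, Dataset]) -> dict[str, Dataset]:
    """The subset of datasets a query AST references: its evaluation universe."""
    names: list[str] = []

    def collect(node: Node) -> None:
        if isinstance(node, DatasetRef):
            if node.name not in names:
                names.append(node.name)
        else:
            collect(node.left)
            collect(node.right)

    collect(root)
    return {name: datasets[name] for name in names}


def engine_groups_as_sets(result_groups, datasets) -> set[frozenset[str]]:
    """Engine groups restricted to dataset identifiers, for oracle comparison."""
    dataset_ids = {i for ds in datasets.values() for i in ds.identifiers()}
    return {frozenset(g.members & dataset_ids) for g in result_groups}


def random_instance(
    rng: random.Random,
    max_datasets: int = 5,
    max_identifiers: int = 50,
) -> tuple[dict[str, Dataset], AliasRegistry]:
    """A random small multi-dataset instance with random alias links."""
    n_ids = rng.randint(4, max_identifiers)
    pool = [f"id{i:03d}" for i in range(n_ids)]
    registry = AliasRegistry()
    n_fps = rng.randint(1, max(2, n_ids // 3))
    fingerprints = [
        canonicalize("sequence", "".join(rng.choice("ACGT") for _ in range(12)))
        for _ in range(n_fps)
    ]
    for _ in range(rng.randint(0, n_ids)):
        registry.register(rng.choice(pool), rng.choice(fingerprints))
    n_datasets = rng.randint(2, max_datasets)
    datasets: dict[str, Dataset] = {}
    for d in range(n_datasets):
        name = f"D{d}"
        size = rng.randint(1, n_ids)
        ids = rng.sample(pool, size)
        datasets[name] = Dataset.from_records(
            name, [[i, str(rng.randint(0, 9))] for i in ids], ["id", "val"]
        )
    return datasets, registry


def random_ast(rng: random.Random, names: list[str], depth: int = 3) -> Node:
    """A random query AST over the given dataset names."""
    if depth == 0 or rng.random() < 0.3:
        return DatasetRef(rng.choice(names))
    op = rng.choice([And, Or, Not])
    return op(
        random_ast(rng, names, depth - 1),
        random_ast(rng, names, depth - 1),
    )
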