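"""Grouping of identifiers across datasets into entity groups.

Two identifiers denote the same entity when their strings match exactly
(under the configured case rule) or when they were registered with at least
one common fingerprint hash key. The relation is closed transitively:
entity groups are the connected components of the identifier graph. This is
deliberately *not* a clique criterion — two protein variants that share no
key with each other still merge when a gene parent carries a key of each,
so the entire gene/variant family collapses into one group.

Identifiers that occur only in the alias registry never create links on
their own (a registry gene parent must actually appear in a dataset to
bridge its variants), but once groups are formed, registry identifiers
whose keys all fall inside one group are attached to it as members, so the
group carries its complete alias neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .aliasing import AliasRegistry
from .datamodel import Dataset, Row

__all__ = ["EntityGroup", "build_entity_graph", "consolidate"]


@dataclass
class EntityGroup:
    """One consolidated cluster of identifiers, the unit of row matching.

    ``group_id`` is a presentation-only integer assigned by first appearance
    (dataset order, then row order); group identity across operations is
    carried by the member and key sets.
    """

    group_id: int
    members: set[str]
    keys: set[str]
    per_dataset_rows: dict[str, list[Row]] = field(default_factory=dict)

    def rows_in(self, dataset_name: str) -> list[Row]:
        return self.per_dataset_rows.get(dataset_name, [])

    def source_names(self) -> set[str]:
        """Names of datasets contributing at least one row."""
        return {name for name, rows in self.per_dataset_rows.items() if rows}


def _canon(identifier: str, case_insensitive: bool) -> str:
    return identifier.casefold() if case_insensitive else identifier


def build_entity_graph(
    datasets: list[Dataset],
    registry: AliasRegistry | None = None,
    case_insensitive: bool = False,
) -> nx.Graph:
    """Graph over the identifiers appearing in the given datasets.

    Nodes are identifiers (collapsed under the case rule, so exact string
    matches across datasets are a single node; original spellings are kept
    in the ``spellings`` node attribute). An edge joins two identifiers iff
    their resolved key sets share at least one hash key.
    """
    if len({d.name for d in datasets}) != len(datasets):
        raise ValueError("dataset names must be unique")
    graph = nx.Graph()
    key_to_nodes: dict[str, list[str]] = {}
    for ds in datasets:
        for row in ds.rows:
            node = _canon(row.identifier, case_insensitive)
            if not graph.has_node(node):
                graph.add_node(node, spellings=set())
                if registry is not None:
                    for key in registry.resolve_keys(row.identifier):
                        key_to_nodes.setdefault(key, []).append(node)
            spellings = graph.nodes[node]["spellings"]
            if row.identifier not in spellings:
                spellings.add(row.identifier)
                if registry is not None and len(spellings) > 1:
                    # a new spelling may resolve to keys the node lacked
                    for key in registry.resolve_keys(row.identifier):
                        nodes = key_to_nodes.setdefault(key, [])
                        if node not in nodes:
                            nodes.append(node)
    for nodes in key_to_nodes.values():
        anchor = nodes[0]
        for other in nodes[1:]:
            graph.add_edge(anchor, other)  # star closure ≡ pairwise closure
    return graph


def consolidate(
    datasets: list[Dataset],
    registry: AliasRegistry | None = None,
    case_insensitive: bool = False,
) -> list[EntityGroup]:
    """Partition all dataset identifiers into entity groups.

    Groups are the connected components of :func:`build_entity_graph`,
    ordered and numbered by first appearance (dataset order, then row
    order). Each group's key set is the union of its dataset members'
    resolved keys; registry identifiers whose entire key set lies within a
    group are attached as members (they belong to exactly one group because
    groups never share keys). ``per_dataset_rows`` collects every row whose
    identifier is a member.
    """
    graph = build_entity_graph(datasets, registry, case_insensitive)
    node_component: dict[str, int] = {}
    for comp_idx, component in enumerate(nx.connected_components(graph)):
        for node in component:
            node_component[node] = comp_idx

    # first-appearance order over components
    order: list[int] = []
    seen: set[int] = set()
    for ds in datasets:
        for row in ds.rows:
            comp = node_component[_canon(row.identifier, case_insensitive)]
            if comp not in seen:
                seen.add(comp)
                order.append(comp)

    groups: dict[int, EntityGroup] = {}
    for gid, comp in enumerate(order):
        groups[comp] = EntityGroup(group_id=gid, members=set(), keys=set())
    for node, comp in node_component.items():
        group = groups[comp]
        spellings = graph.nodes[node]["spellings"]
        group.members.update(spellings)
        if registry is not None:
            for spelling in spellings:
                group.keys.update(registry.resolve_keys(spelling))
    for ds in datasets:
        for row in ds.rows:
            comp = node_component[_canon(row.identifier, case_insensitive)]
            groups[comp].per_dataset_rows.setdefault(ds.name, []).append(row)

    if registry is not None:
        _attach_registry_aliases(groups.values(), registry)
    return [groups[comp] for comp in order]


def _attach_registry_aliases(groups, registry: AliasRegistry) -> None:
    # Attach registry-only identifiers whose keys all fall inside one group.
    # A parent identifier whose keys straddle two groups (its variants were
    # never co-linked by any dataset) is attached to neither, preserving
    # group disjointness.
    for group in groups:
        candidates: set[str] = set()
        for key in group.keys:
            candidates.update(registry.identifiers_for_key(key))
        for candidate in candidates - group.members:
            if registry.resolve_keys(candidate) <= group.keys:
                group.members.add(candidate)


def groups_to_debug_rows(groups: list[EntityGroup]) -> list[list[str]]:
    """Debug export: one [group_id, members, keys] row per group."""
    return [
        [str(g.group_id), ";".join(sorted(g.members)), ";".join(sorted(g.keys))]
        for g in groups
    ]
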