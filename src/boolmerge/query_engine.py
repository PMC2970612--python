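"""Boolean query parsing and evaluation over consolidated entity groups.

Queries combine named datasets with three operators::

    A - B     subtraction / NOT: entities in A with no row in B
    A + B     intersection / AND: entities with rows in both
    A U B     union / OR: entities with rows in either

Precedence, highest first: parentheses, then ``-``, then ``+``, then ``U``;
repeated instances of one operator bind left to right, i.e. in the order
they appear in the query. ``U`` is a reserved word; a dataset whose name is
``U`` or contains spaces, operators, parentheses or quotes must be written
double-quoted.

Evaluation consolidates identifiers once, globally, over every dataset the
query names; each AST node then just filters the resulting group-set. The
subtraction operator is the *left-relative* complement — no universal set
exists over open-ended gene lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Union

from .aliasing import AliasRegistry
from .consolidation import EntityGroup, consolidate
from .datamodel import Dataset, Row

__all__ = [
    "DatasetRef",
    "Not",
    "And",
    "Or",
    "QueryExpression",
    "QueryError",
    "MergeResult",
    "SwitchResult",
    "parse_query",
    "evaluate",
    "switch_touch_point",
    "assemble_output",
]


class QueryError(ValueError):
    """Parse or evaluation failure; carries the offending query position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class DatasetRef:
    name: str


@dataclass(frozen=True)
class Not:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


Node = Union[DatasetRef, Not, And, Or]


@dataclass(frozen=True)
class QueryExpression:
    """Parsed query: AST root plus the original query text."""

    root: Node
    source_text: str

    def dataset_names(self) -> list[str]:
        """Referenced dataset names, in first-appearance order."""
        names: list[str] = []

        def walk(node: Node) -> None:
            if isinstance(node, DatasetRef):
                if node.name not in names:
                    names.append(node.name)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return names


# --- tokenizer -------------------------------------------------------------

_OPERATORS = {"-", "+"}
_SPECIAL = set('()+-"')


@dataclass(frozen=True)
class _Token:
    kind: str  # "name" | "op" | "lparen" | "rparen"
    text: str
    pos: int


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch == "(":
            tokens.append(_Token("lparen", ch, i))
            i += 1
        elif ch == ")":
            tokens.append(_Token("rparen", ch, i))
            i += 1
        elif ch in _OPERATORS:
            tokens.append(_Token("op", ch, i))
            i += 1
        elif ch == '"':
            j = text.find('"', i + 1)
            if j == -1:
                raise QueryError("unterminated quoted name", i)
            name = text[i + 1 : j]
            if not name:
                raise QueryError("empty quoted name", i)
            tokens.append(_Token("name", name, i))
            i = j + 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in _SPECIAL:
                j += 1
            word = text[i:j]
            if word == "U":  # reserved union keyword, case-sensitive
                tokens.append(_Token("op", "U", i))
            else:
                tokens.append(_Token("name", word, i))
            i = j
    return tokens


# --- recursive-descent parser ---------------------------------------------


class _Parser:
    # precedence, loosest first: U, then +, then -; all left-associative
    def __init__(self, tokens: list[_Token], known: set[str], text: str):
        self.tokens = tokens
        self.known = known
        self.text = text
        self.i = 0

    def peek(self) -> _Token | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def advance(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise QueryError("unexpected end of query", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.or_expr()
        tok = self.peek()
        if tok is not None:
            if tok.kind == "rparen":
                raise QueryError("unbalanced parentheses: unexpected ')'", tok.pos)
            raise QueryError(f"unexpected token {tok.text!r}", tok.pos)
        return node

    def or_expr(self) -> Node:
        node = self.and_expr()
        while (tok := self.peek()) is not None and tok.text == "U":
            self.advance()
            node = Or(node, self.and_expr())
        return node

    def and_expr(self) -> Node:
        node = self.not_expr()
        while (tok := self.peek()) is not None and tok.text == "+":
            self.advance()
            node = And(node, self.not_expr())
        return node

    def not_expr(self) -> Node:
        node = self.atom()
        while (tok := self.peek()) is not None and tok.text == "-":
            self.advance()
            node = Not(node, self.atom())
        return node

    def atom(self) -> Node:
        tok = self.advance()
        if tok.kind == "lparen":
            node = self.or_expr()
            closing = self.peek()
            if closing is None or closing.kind != "rparen":
                raise QueryError("unbalanced parentheses: missing ')'", tok.pos)
            self.advance()
            return node
        if tok.kind == "name":
            if tok.text not in self.known:
                raise QueryError(f"unknown dataset name {tok.text!r}", tok.pos)
            return DatasetRef(tok.text)
        if tok.kind == "rparen":
            raise QueryError("unbalanced parentheses: unexpected ')'", tok.pos)
        raise QueryError(f"dangling operator {tok.text!r}", tok.pos)


def parse_query(text: str, known_datasets: set[str]) -> QueryExpression:
    """Parse a Boolean query string into a :class:`QueryExpression`.

    Unknown dataset names, unbalanced parentheses and dangling operators are
    rejected with the offending position. Names may be bare (no whitespace,
    operators, parentheses or quotes, and not the reserved word ``U``) or
    double-quoted.
    """
    if not text or not text.strip():
        raise QueryError("empty query")
    tokens = _tokenize(text)
    if not tokens:
        raise QueryError("empty query")
    root = _Parser(tokens, set(known_datasets), text).parse()
    return QueryExpression(root=root, source_text=text)


# --- evaluation ------------------------------------------------------------


@dataclass
class MergeResult:
    """Outcome of evaluating a query: the merged table plus its groups.

    The table has one row per surviving entity group: an ``id`` column (the
    group's first-appearing member), an ``aliases`` provenance column
    listing every member, and each source dataset's attribute columns
    prefixed ``<dataset>.<column>``.
    """

    dataset: Dataset
    groups: list[EntityGroup]

    @property
    def group_count(self) -> int:
        return len(self.groups)

    def to_envelope(self) -> dict:
        """JSON-serializable result envelope with group membership."""
        return {
            "group_count": len(self.groups),
            "columns": list(self.dataset.columns),
            "groups": [
                {
                    "id": g.group_id,
                    "members": sorted(g.members),
                    "keys": sorted(g.keys),
                    "sources": sorted(g.source_names()),
                }
                for g in self.groups
            ],
        }


def evaluate(
    expr: QueryExpression | str,
    datasets: Mapping[str, Dataset],
    registry: AliasRegistry | None = None,
    use_aliases: bool = True,
    case_insensitive: bool = False,
    aggregate_delimiter: str = "; ",
    result_name: str = "result",
) -> MergeResult:
    """Evaluate a Boolean query over named datasets.

    Consolidation runs once over all referenced datasets (with the alias
    registry when ``use_aliases``); the AST is then folded bottom-up on
    group-sets: AND keeps groups with rows in both operands, OR in either,
    NOT (subtraction) in the left but not the right. An empty result is
    legal — an empty intersection is a valid scientific answer.
    """
    if isinstance(expr, str):
        expr = parse_query(expr, set(datasets))
    names = expr.dataset_names()
    missing = [n for n in names if n not in datasets]
    if missing:
        raise QueryError(f"unknown dataset name(s): {missing}")
    operand_datasets = [datasets[n] for n in names]
    reg = registry if (use_aliases and registry is not None) else None
    groups = consolidate(operand_datasets, reg, case_insensitive)

    by_source: dict[str, frozenset[int]] = {}
    for name in names:
        by_source[name] = frozenset(
            g.group_id for g in groups if g.rows_in(name)
        )

    def fold(node: Node) -> frozenset[int]:
        if isinstance(node, DatasetRef):
            return by_source[node.name]
        left, right = fold(node.left), fold(node.right)
        if isinstance(node, And):
            return left & right
        if isinstance(node, Or):
            return left | right
        return left - right  # Not: left-relative complement

    surviving_ids = fold(expr.root)
    surviving = [g for g in groups if g.group_id in surviving_ids]
    table = assemble_output(
        surviving, operand_datasets, aggregate_delimiter, result_name
    )
    return MergeResult(dataset=table, groups=surviving)


def assemble_output(
    groups: list[EntityGroup],
    operand_datasets: list[Dataset],
    aggregate_delimiter: str = "; ",
    result_name: str = "result",
) -> Dataset:
    """Build the merged output table, one row per surviving group.

    Columns: ``id``, ``aliases``, then each source dataset's attribute
    columns prefixed ``<dataset>.<column>``, in dataset order. Multi-row
    groups aggregate each cell's values in row order; a dataset that
    contributed no row to a group leaves its cells empty.
    """
    columns = ["id", "aliases"]
    for ds in operand_datasets:
        columns.extend(f"{ds.name}.{c}" for c in ds.attribute_columns)

    rows: list[Row] = []
    for group in sorted(groups, key=lambda g: g.group_id):
        first_member = ""
        for ds in operand_datasets:
            ds_rows = group.rows_in(ds.name)
            if ds_rows:
                first_member = ds_rows[0].identifier
                break
        if not first_member:  # group with no rows in any operand (degenerate)
            first_member = min(group.members)
        values = {
            "id": first_member,
            "aliases": ";".join(sorted(group.members)),
        }
        for ds in operand_datasets:
            ds_rows = group.rows_in(ds.name)
            for col in ds.attribute_columns:
                values[f"{ds.name}.{col}"] = aggregate_delimiter.join(
                    r.values[col] for r in ds_rows
                )
        rows.append(Row(identifier=first_member, values=values))
    return Dataset(name=result_name, id_column="id", columns=columns, rows=rows)


# --- touch-point switching --------------------------------------------------


@dataclass
class SwitchResult:
    """A re-keyed dataset plus the count of rows dropped for empty ids."""

    dataset: Dataset
    n_dropped: int


def switch_touch_point(
    dataset: Dataset, new_id_column: str, drop_empty: bool = True
) -> SwitchResult:
    """Re-key a dataset on a different column (switch its "touch point").

    Returns the same table with ``id_column`` set to ``new_id_column``;
    rows whose new identifier cell is empty are dropped (and counted) when
    ``drop_empty``, otherwise an empty cell raises. Switching the touch
    point lets a result table be re-queried on a different attribute —
    e.g. re-keying a drug → target table on "target" to chain it into a
    gene-level comparison.
    """
    if new_id_column not in dataset.columns:
        raise QueryError(
            f"unknown column {new_id_column!r}; available: {dataset.columns}"
        )
    rows: list[Row] = []
    dropped = 0
    for i, row in enumerate(dataset.rows):
        new_id = row.values[new_id_column]
        if not new_id:
            if drop_empty:
                dropped += 1
                continue
            raise QueryError(
                f"row {i} has an empty cell in column {new_id_column!r}"
            )
        rows.append(Row(identifier=new_id, values=dict(row.values)))
    switched = Dataset(
        name=dataset.name,
        id_column=new_id_column,
        columns=list(dataset.columns),
        rows=rows,
    )
    return SwitchResult(dataset=switched, n_dropped=dropped)
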