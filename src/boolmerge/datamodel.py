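"""Tabular dataset container and file I/O.

A :class:`Dataset` is the unit of the Boolean algebra: a named spreadsheet-like
table with one column designated as the *touch point* (identifier) column.
Cell values are uninterpreted strings; the algebra operates only on the
identifier column, everything else is payload that is carried through merges.

TSV is the canonical dialect; CSV is accepted with RFC-4180-style quoting.
Reading and writing go through the stdlib :mod:`csv` module so that a
write/read round trip is bit-exact, including cells that contain the
delimiter.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "Row",
    "Dataset",
    "DatasetError",
    "read_table",
    "write_table",
    "read_fasta_fingerprints",
]


class DatasetError(ValueError):
    """Raised for malformed tables or violated dataset invariants."""


@dataclass(frozen=True)
class Row:
    """One table row: an identifier plus a column-name -> value mapping.

    ``identifier`` always equals ``values[id_column]`` of the parent dataset.
    """

    identifier: str
    values: dict[str, str]


@dataclass
class Dataset:
    """A named table with a designated identifier ("touch point") column.

    Parameters
    ----------
    name
        Unique, non-empty label used to refer to the dataset in queries.
    id_column
        Name of the identifier column; must be one of ``columns``.
    columns
        Ordered column names.
    rows
        Ordered rows. Duplicate identifiers across rows are permitted — a
        gene may legitimately carry several annotation rows.
    """

    name: str
    id_column: str
    columns: list[str]
    rows: list[Row] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise DatasetError("dataset name must be non-empty")
        if self.id_column not in self.columns:
            raise DatasetError(
                f"id_column {self.id_column!r} not among columns {self.columns!r}"
            )
        for i, row in enumerate(self.rows):
            if set(row.values) != set(self.columns):
                raise DatasetError(f"row {i} does not match the column set")
            if not row.identifier:
                raise DatasetError(f"row {i} has an empty identifier")
            if row.values[self.id_column] != row.identifier:
                raise DatasetError(
                    f"row {i}: identifier differs from its {self.id_column!r} cell"
                )

    @property
    def attribute_columns(self) -> list[str]:
        """Columns other than the identifier column, in table order."""
        return [c for c in self.columns if c != self.id_column]

    def identifiers(self) -> list[str]:
        """Identifier of every row, in row order (duplicates preserved)."""
        return [row.identifier for row in self.rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[Row]:
        return iter(self.rows)

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[dict[str, str] | list[str]],
        columns: list[str],
        id_column: str | None = None,
    ) -> "Dataset":
        """Build a dataset from dicts or positional lists of cell values."""
        idc = id_column if id_column is not None else columns[0]
        rows = []
        for rec in records:
            if not isinstance(rec, dict):
                rec = dict(zip(columns, rec, strict=True))
            rows.append(Row(identifier=rec[idc], values=dict(rec)))
        return cls(name=name, id_column=idc, columns=list(columns), rows=rows)


def read_table(
    path: str | Path,
    delimiter: str = "\t",
    id_column: str | None = None,
    name: str | None = None,
) -> Dataset:
    """Read a delimited table (header row mandatory) into a :class:`Dataset`.

    Parameters
    ----------
    path
        File to read; UTF-8, first line is the header.
    delimiter
        Cell delimiter; tab by default, ``","`` for CSV.
    id_column
        Which header column holds the identifiers. Defaults to the first
        column, matching the copy-paste-from-a-spreadsheet idiom where the
        leftmost column is the gene/protein/drug name.
    name
        Dataset name; defaults to the file stem.

    Raises
    ------
    DatasetError
        If the header lacks ``id_column`` or a row has an empty identifier
        cell (the error message names the offending line number).
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise DatasetError(f"{path}: empty file, header row required") from None
        header = [h.strip() for h in header]
        idc = id_column if id_column is not None else header[0]
        if idc not in header:
            raise DatasetError(
                f"{path}: id_column {idc!r} not in header; available: {header}"
            )
        rows: list[Row] = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue  # blank line
            if len(cells) != len(header):
                raise DatasetError(
                    f"{path}: line {lineno} has {len(cells)} cells, expected {len(header)}"
                )
            values = {c: v.strip() for c, v in zip(header, cells)}
            if not values[idc]:
                raise DatasetError(
                    f"{path}: line {lineno} has an empty identifier cell in column {idc!r}"
                )
            rows.append(Row(identifier=values[idc], values=values))
    return Dataset(
        name=name if name is not None else path.stem,
        id_column=idc,
        columns=header,
        rows=rows,
    )


def write_table(dataset: Dataset, path: str | Path, delimiter: str = "\t") -> Path:
    """Write a dataset as a delimited UTF-8 text table.

    Cells containing the delimiter, quotes or newlines are quoted so that
    ``read_table(write_table(d))`` reproduces columns, row order and cell
    values exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(dataset.columns)
        for row in dataset.rows:
            writer.writerow([row.values[c] for c in dataset.columns])
    return path


def read_fasta_fingerprints(path: str | Path) -> list[tuple[str, str]]:
    """Extract (identifier, canonical sequence fingerprint) pairs from FASTA.

    The identifier is the record ID (text before the first whitespace of the
    header line); the fingerprint is the concatenated sequence,
    canonicalized as a sequence fingerprint (whitespace stripped,
    upper-cased). No de-duplication happens at this layer: two records with
    identical sequences yield two pairs with equal fingerprints.
    """
    from .aliasing import canonicalize  # late import: avoid module cycle

    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        # reject sequence data appearing before the first header line
        head = fh.read(4096)
        stripped = head.lstrip()
        if stripped and not stripped.startswith(">"):
            raise DatasetError(f"{path}: malformed FASTA, sequence before first header")
        fh.seek(0)
        for record in SeqIO.parse(fh, "fasta"):
            if not record.id:
                raise DatasetError(f"{path}: FASTA record with empty ID")
            fp = canonicalize("sequence", str(record.seq))
            pairs.append((record.id, fp.text))
    return pairs


def dataset_to_string(dataset: Dataset, delimiter: str = "\t") -> str:
    """Render a dataset as delimited text (same dialect as write_table)."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    writer.writerow(dataset.columns)
    for row in dataset.rows:
        writer.writerow([row.values[c] for c in dataset.columns])
    return buf.getvalue()
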