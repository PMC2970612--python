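"""Fingerprint canonicalization, hash-key derivation and the alias registry.

Identity between differently-named entities (a gene symbol, an Ensembl
protein ID, a RefSeq accession ...) is asserted through a shared
*fingerprint*: content that defines the entity independent of naming — a
sequence, a chemical formula, a URI. The 160-bit digest of the canonicalized
fingerprint, rendered as 40 lower-case hexadecimal characters, serves as a
non-semantic *hash key*; equal keys assert identity.

The default digest is SHA-1, the standard 160-bit hash; a SHA-256 digest
truncated to 160 bits is available as a configuration switch. Either way the
key is exactly 40 hex characters. The digest choice is fixed per registry so
that every key in one registry is comparable.
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "FINGERPRINT_KINDS",
    "DIGESTS",
    "Fingerprint",
    "AliasRegistry",
    "AliasError",
    "canonicalize",
    "compute_hash_key",
    "load_alias_table",
    "save_alias_table",
]

FINGERPRINT_KINDS = ("sequence", "formula", "uri", "opaque")

#: Supported digest configurations: name -> function bytes -> 40-hex-char key.
DIGESTS = {
    "sha160-standard": lambda data: hashlib.sha1(data).hexdigest(),
    "sha2-truncated": lambda data: hashlib.sha256(data).hexdigest()[:40],
}

DEFAULT_DIGEST = "sha160-standard"


class AliasError(ValueError):
    """Raised for invalid fingerprints, identifiers or alias-table files."""


@dataclass(frozen=True)
class Fingerprint:
    """A canonicalized identity fingerprint.

    ``kind`` is one of :data:`FINGERPRINT_KINDS`; ``text`` is non-empty,
    whitespace-free for sequences (and upper-case), surrounding-whitespace
    free otherwise. Construct through :func:`canonicalize`.
    """

    kind: str
    text: str

    def __post_init__(self) -> None:
        if self.kind not in FINGERPRINT_KINDS:
            raise AliasError(f"unknown fingerprint kind {self.kind!r}")
        if not self.text:
            raise AliasError("fingerprint text must be non-empty")
        if self.kind == "sequence" and (
            any(ch.isspace() for ch in self.text) or self.text != self.text.upper()
        ):
            raise AliasError("sequence fingerprint must be whitespace-free upper-case")


def canonicalize(kind: str, raw: str) -> Fingerprint:
    """Normalize raw fingerprint content deterministically.

    Sequences have all whitespace removed and are upper-cased, so that
    ``"atg c\\nat"`` and ``"ATGCAT"`` denote the same molecule. Formulas,
    URIs and opaque fingerprints only have surrounding whitespace stripped.

    Raises :class:`AliasError` if the result would be empty.
    """
    if kind not in FINGERPRINT_KINDS:
        raise AliasError(f"unknown fingerprint kind {kind!r}")
    if kind == "sequence":
        text = "".join(raw.split()).upper()
    else:
        text = raw.strip()
    if not text:
        raise AliasError("fingerprint is empty after canonicalization")
    return Fingerprint(kind=kind, text=text)


def compute_hash_key(fp: Fingerprint, digest: str = DEFAULT_DIGEST) -> str:
    """160-bit digest of the fingerprint text as 40 lower-case hex chars.

    The UTF-8 bytes of the canonicalized text are hashed; the kind is not
    mixed into the digest — two fingerprints with equal canonical text are
    the same identity statement regardless of how they were labelled.
    """
    if digest not in DIGESTS:
        raise AliasError(f"unknown digest {digest!r}; choose from {sorted(DIGESTS)}")
    return DIGESTS[digest](fp.text.encode("utf-8"))


@dataclass
class AliasRegistry:
    """Many-to-many relation between identifier strings and hash keys.

    An identifier may map to several keys — a gene whose aliases point to
    each of its protein variants carries one key per variant sequence — and
    one key maps back to every identifier registered with that fingerprint.
    Looking up an unregistered identifier yields the empty set, never an
    error: unaliased identifiers are still grouped by exact string match
    downstream.
    """

    digest: str = DEFAULT_DIGEST
    _by_identifier: dict[str, set[str]] = field(default_factory=dict)
    _by_key: dict[str, set[str]] = field(default_factory=dict)
    #: (identifier, key) -> (kind, raw canonical text) for round-tripping.
    _entries: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def register(
        self, identifier: str, fp: Fingerprint, source: str | None = None
    ) -> str:
        """Associate ``identifier`` with the key of ``fp``; returns the key.

        Idempotent: repeated identical registrations leave the relation
        unchanged.
        """
        if not identifier:
            raise AliasError("cannot register an empty identifier")
        key = compute_hash_key(fp, self.digest)
        self._by_identifier.setdefault(identifier, set()).add(key)
        self._by_key.setdefault(key, set()).add(identifier)
        self._entries[(identifier, key)] = (fp.kind, fp.text)
        if source is not None:
            self.provenance[(identifier, key)] = source
        return key

    def resolve_keys(self, identifier: str) -> set[str]:
        """Exact set of keys registered for ``identifier`` (empty if none)."""
        return set(self._by_identifier.get(identifier, ()))

    def identifiers_for_key(self, key: str) -> set[str]:
        """Every identifier registered with fingerprint key ``key``."""
        return set(self._by_key.get(key, ()))

    @property
    def entries(self) -> set[tuple[str, str]]:
        """The (identifier, key) relation as a set of pairs."""
        return set(self._entries)

    def identifiers(self) -> set[str]:
        return set(self._by_identifier)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, identifier: str) -> bool:
        return identifier in self._by_identifier


def save_alias_table(registry: AliasRegistry, path: str | Path) -> Path:
    """Write the registry as a 3-column TSV: identifier, kind, fingerprint."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["identifier", "kind", "fingerprint"])
        for (identifier, _key), (kind, text) in sorted(registry._entries.items()):
            writer.writerow([identifier, kind, text])
    return path


def load_alias_table(path: str | Path, digest: str = DEFAULT_DIGEST) -> AliasRegistry:
    """Read a 3-column TSV (identifier, kind, raw fingerprint) registry.

    Round trip with :func:`save_alias_table` preserves the entry relation.
    Malformed lines raise :class:`AliasError` naming the line number.
    """
    path = Path(path)
    registry = AliasRegistry(digest=digest)
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise AliasError(f"{path}: empty alias table, header required") from None
        if [h.strip() for h in header[:3]] != ["identifier", "kind", "fingerprint"]:
            raise AliasError(
                f"{path}: line 1: expected header 'identifier\\tkind\\tfingerprint'"
            )
        for lineno, cells in enumerate(reader, start=2):
            if not cells:
                continue
            if len(cells) != 3:
                raise AliasError(f"{path}: line {lineno}: expected 3 columns")
            identifier, kind, raw = (c.strip() for c in cells)
            if kind not in FINGERPRINT_KINDS:
                raise AliasError(
                    f"{path}: line {lineno}: unknown fingerprint kind {kind!r}"
                )
            if not identifier:
                raise AliasError(f"{path}: line {lineno}: empty identifier")
            try:
                fp = canonicalize(kind, raw)
            except AliasError as exc:
                raise AliasError(f"{path}: line {lineno}: {exc}") from None
            registry.register(identifier, fp, source=str(path))
    return registry
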