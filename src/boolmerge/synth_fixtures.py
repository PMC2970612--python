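"""Seeded generator of datasets and alias networks with controlled overlap.

The generator emulates the two structures the engine must handle:

* a *benchmark* shape — ``n_datasets`` gene lists of ``ids_per_dataset``
  identifiers apiece with a controlled shared fraction, the regime in which
  chained intersections of many 20,000-gene datasets are evaluated; and
* *alias families* — a gene parent with several protein variants, each
  variant carrying one external accession registered with the same
  sequence fingerprint, and the parent registered with every variant's
  fingerprint. Variants are placed in the first dataset and parents in the
  second, so consolidation must merge the family across datasets through
  the parent's keys.

Generation is fully deterministic: the same :class:`FixtureSpec` (seed
included) produces byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, asdict
from pathlib import Path

from .aliasing import AliasRegistry, canonicalize, save_alias_table
from .datamodel import Dataset, Row, write_table

__all__ = ["FixtureSpec", "FixtureBundle", "build_fixture", "generate", "load_manifest"]

_DNA = "ACGT"
_VARIANT_SUFFIXES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic fixture.

    overlap_fraction is the fraction of each dataset drawn from a pool of
    identifiers present in *every* dataset; alias_families counts
    gene-parent families of variant_count protein variants each.
    """

    n_datasets: int
    ids_per_dataset: int
    overlap_fraction: float = 0.0
    alias_families: int = 0
    variant_count: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1 or self.ids_per_dataset < 1:
            raise ValueError("n_datasets and ids_per_dataset must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.alias_families < 0 or self.variant_count < 1:
            raise ValueError("alias_families >= 0 and variant_count >= 1 required")
        if self.alias_families:
            if self.n_datasets < 2:
                raise ValueError("alias families need at least 2 datasets")
            free = self.ids_per_dataset - self.shared_count
            if self.alias_families * self.variant_count > free:
                raise ValueError(
                    "not enough non-shared identifier slots for the variant rows"
                )
            if self.alias_families > free:
                raise ValueError(
                    "not enough non-shared identifier slots for the parent rows"
                )

    @property
    def shared_count(self) -> int:
        return int(self.overlap_fraction * self.ids_per_dataset)

    @property
    def total_combined_identifiers(self) -> int:
        """Total identifier count summed over datasets (the benchmark x-axis)."""
        return self.n_datasets * self.ids_per_dataset

    @property
    def expected_intersection(self) -> int:
        """Group count of the chained intersection of all datasets.

        The shared pool survives always; an alias family survives only when
        every dataset holds part of it, i.e. when there are exactly two
        datasets (variants in the first, parent in the second).
        """
        if self.n_datasets == 1:
            return self.ids_per_dataset
        return self.shared_count + (
            self.alias_families if self.n_datasets == 2 else 0
        )


@dataclass
class FixtureBundle:
    """In-memory fixture: the datasets, the alias registry, the manifest."""

    datasets: list[Dataset]
    registry: AliasRegistry
    manifest: dict


def _random_sequence(rng: random.Random, length: int = 30) -> str:
    return "".join(rng.choice(_DNA) for _ in range(length))


def _random_attr(rng: random.Random) -> str:
    return "".join(rng.choice("abcdefghijklmnopqrstuvwxyz") for _ in range(6))


def build_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the fixture in memory. Deterministic in ``spec``."""
    rng = random.Random(spec.seed)
    shared = [f"S{i:06d}" for i in range(spec.shared_count)]

    registry = AliasRegistry()
    family_variants: list[str] = []
    family_parents: list[str] = []
    for f in range(spec.alias_families):
        parent = f"FG{f + 1:04d}"
        family_parents.append(parent)
        for v in range(spec.variant_count):
            variant = f"{parent}-P{_VARIANT_SUFFIXES[v % 26]}{v // 26 or ''}"
            external = f"XP_{spec.seed % 997:03d}{f:04d}{v:03d}"
            fp = canonicalize("sequence", _random_sequence(rng))
            registry.register(variant, fp)
            registry.register(external, fp)
            registry.register(parent, fp)  # parent holds every variant's key
            family_variants.append(variant)

    datasets: list[Dataset] = []
    used: set[str] = set(shared)
    for d in range(spec.n_datasets):
        ids = list(shared)
        if d == 0:
            ids.extend(family_variants)
        elif d == 1:
            ids.extend(family_parents)
        while len(ids) < spec.ids_per_dataset:
            candidate = f"G{rng.randrange(10**9):09d}"  # seed-specific pool
            if candidate not in used:
                used.add(candidate)
                ids.append(candidate)
        rng.shuffle(ids)
        name = f"dataset_{d + 1:02d}"
        rows = [
            Row(identifier=i, values={"id": i, "attr": _random_attr(rng)})
            for i in ids
        ]
        datasets.append(
            Dataset(name=name, id_column="id", columns=["id", "attr"], rows=rows)
        )

    manifest = dict(asdict(spec))
    manifest["expected_intersection"] = spec.expected_intersection
    manifest["total_combined_identifiers"] = spec.total_combined_identifiers
    return FixtureBundle(datasets=datasets, registry=registry, manifest=manifest)


def generate(
    spec: FixtureSpec, out_dir: str | Path
) -> tuple[list[Path], Path, Path]:
    """Write the fixture to ``out_dir``.

    Produces one TSV per dataset, an alias table ``aliases.tsv`` and a
    ``manifest.txt`` of ``key=value`` lines recording the spec together
    with the expected chained-intersection size and the total combined
    identifier count. Returns (dataset paths, alias table path, manifest
    path).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = build_fixture(spec)
    dataset_paths = [
        write_table(ds, out_dir / f"{ds.name}.tsv") for ds in bundle.datasets
    ]
    alias_path = save_alias_table(bundle.registry, out_dir / "aliases.tsv")
    manifest_path = out_dir / "manifest.txt"
    with manifest_path.open("w", encoding="utf-8") as fh:
        for key, value in bundle.manifest.items():
            fh.write(f"{key}={value}\n")
    return dataset_paths, alias_path, manifest_path


def load_manifest(path: str | Path) -> dict[str, str]:
    """Read a ``key=value`` manifest back as a string-valued dict."""
    manifest: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.strip():
            key, _, value = line.partition("=")
            manifest[key] = value
    return manifest
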