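import pytest
from hypothesis import HealthCheck, settings

from boolmerge.aliasing import AliasRegistry, canonicalize
from boolmerge.datamodel import Dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def variant_registry() -> AliasRegistry:
    """Gene/protein-variant alias network: a gene parent CG6995 whose two
    protein variants each carry an external accession sharing the variant's
    sequence fingerprint, while the parent is registered with both."""
    reg = AliasRegistry()
    seq_a = canonicalize("sequence", "ATGAAACCCGGG")
    seq_c = canonicalize("sequence", "ATGCCCGGGTTT")
    for ident in ("CG6995-PA", "FPpp00084077", "CG6995"):
        reg.register(ident, seq_a)
    for ident in ("CG6995-PC", "NP_001034066", "CG6995"):
        reg.register(ident, seq_c)
    return reg


@pytest.fixture
def variant_dataset() -> Dataset:
    return Dataset.from_records(
        "variants",
        [["CG6995-PA", "v1"], ["CG6995-PC", "v2"]],
        ["id", "note"],
    )


@pytest.fixture
def parent_dataset() -> Dataset:
    return Dataset.from_records("parents", [["CG6995", "gene"]], ["id", "note"])
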