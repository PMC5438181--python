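import numpy as np
import pytest

from codoncons.code import CODON_INDEX, SENSE_CODONS
from codoncons.orfeome import CodonUsageTable


def table_from_counts(counts_by_codon: dict[str, int], default: int = 1,
                      species_id: str = "toy") -> CodonUsageTable:
    """Usage table from explicit codon counts; unlisted codons get `default`."""
    counts = np.full(61, default, dtype=np.int64)
    for codon, c in counts_by_codon.items():
        counts[CODON_INDEX[codon]] = c
    return CodonUsageTable(species_id=species_id, counts=counts)


@pytest.fixture
def uniform_table() -> CodonUsageTable:
    return table_from_counts({}, default=10)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_usage_table(rng: np.random.Generator, species_id: str = "rand") -> CodonUsageTable:
    """Random strictly-ordered usage table (no ties within synonymous sets)."""
    from codoncons.code import SYN_CODON_ARRAYS

    counts = np.zeros(61, dtype=np.int64)
    for syn in SYN_CODON_ARRAYS:
        while True:
            c = rng.integers(1, 1000, size=len(syn))
            if len(np.unique(c)) == len(syn):
                break
        counts[syn] = c
    return CodonUsageTable(species_id=species_id, counts=counts)


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random in-frame CDS over the 61 sense codons."""
    idx = rng.integers(0, 61, size=n_codons)
    return "".join(SENSE_CODONS[i] for i in idx)
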