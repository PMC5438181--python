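"""Standard genetic code tables and codon indexing.

All downstream numerics index the 61 sense codons by an integer in
``range(61)``; the arrays here give O(1) lookups for amino-acid identity,
synonymous-set membership and third-position GC content.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # the standard code

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: The 61 sense codons in lexicographic order (A < C < G < T).
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if set(c) <= set("ACGT"))
)

#: codon string -> index in range(61)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

#: amino acid (one-letter) encoded by each sense codon, indexed like SENSE_CODONS
CODON_AA: tuple[str, ...] = tuple(_TABLE.forward_table[c] for c in SENSE_CODONS)

AMINO_ACIDS: tuple[str, ...] = tuple(sorted(set(CODON_AA)))  # 20
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: integer amino-acid index per sense codon
CODON_AA_IDX: np.ndarray = np.array([AA_INDEX[a] for a in CODON_AA], dtype=np.intp)

#: amino acid -> sorted tuple of synonymous codon indices
SYN_SETS: dict[str, tuple[int, ...]] = {
    a: tuple(i for i, aa in enumerate(CODON_AA) if aa == a) for a in AMINO_ACIDS
}

#: list of numpy index arrays, one per amino acid (ordered like AMINO_ACIDS)
SYN_CODON_ARRAYS: list[np.ndarray] = [
    np.array(SYN_SETS[a], dtype=np.intp) for a in AMINO_ACIDS
]

#: True where the codon's third base is G or C
CODON_GC3: np.ndarray = np.array([c[2] in "GC" for c in SENSE_CODONS], dtype=bool)


def codons_of(cds: str) -> list[str]:
    """Split an in-frame CDS into its codons."""
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def codon_indices(cds: str) -> np.ndarray:
    """Map an in-frame CDS to an array of sense-codon indices.

    Raises ``ValueError`` on stop codons or unrecognised triplets.
    """
    idx = np.empty(len(cds) // 3, dtype=np.intp)
    for j, codon in enumerate(codons_of(cds)):
        k = CODON_INDEX.get(codon)
        if k is None:
            kind = "stop" if codon in STOP_CODONS else "invalid"
            raise ValueError(f"{kind} codon {codon!r} at codon position {j}")
        idx[j] = k
    return idx


def indices_to_cds(idx: np.ndarray) -> str:
    """Inverse of :func:`codon_indices`."""
    return "".join(SENSE_CODONS[int(k)] for k in idx)


def translate_indices(idx: np.ndarray) -> str:
    return "".join(CODON_AA[int(k)] for k in idx)


def aa_indices(protein: str) -> np.ndarray:
    """Map a protein string to integer amino-acid indices."""
    try:
        return np.array([AA_INDEX[a] for a in protein], dtype=np.intp)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown amino acid {exc.args[0]!r}") from None
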