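"""ORFeome input, validation and species codon-usage tables.

An ORFeome is the complete set of annotated coding sequences (CDS) of one
species, supplied as a nucleotide FASTA.  Records are validated (length a
multiple of 3, unambiguous bases, no internal stops), a trailing stop codon
is stripped, and when one gene identifier carries several sequences only the
longest is kept.  Codon usage is counted over the retained records and a
codon is *rare* when its usage frequency falls below the mean frequency of
its synonymous set — relative, not absolute, rarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .code import (
    CODON_AA,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    SYN_CODON_ARRAYS,
    codon_indices,
)

logger = logging.getLogger(__name__)

__all__ = ["OrfRecord", "CodonUsageTable", "read_orfeome", "usage_table", "is_rare"]


@dataclass(frozen=True)
class OrfRecord:
    """One validated coding sequence.

    ``cds`` excludes the trailing stop codon; ``protein`` is its standard-code
    translation, so ``len(protein) == len(cds) / 3``.
    """

    gene_id: str
    species_id: str
    cds: str
    protein: str = field(default="")

    def __post_init__(self) -> None:
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if not self.protein:
            object.__setattr__(self, "protein", str(Seq(self.cds).translate()))
        if "*" in self.protein:
            raise ValueError(f"{self.gene_id}: internal stop codon")

    @property
    def codon_idx(self) -> np.ndarray:
        return codon_indices(self.cds)


def _clean_cds(seq: str, gene_id: str) -> str | None:
    """Validate one raw CDS; return the stop-stripped sequence or None."""
    seq = seq.upper()
    if len(seq) % 3:
        logger.info("dropping %s: length %d not a multiple of 3", gene_id, len(seq))
        return None
    if set(seq) - set("ACGT"):
        logger.info("dropping %s: ambiguous bases", gene_id)
        return None
    if seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    if not seq:
        logger.info("dropping %s: empty after stop stripping", gene_id)
        return None
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if any(c in STOP_CODONS for c in codons):
        logger.info("dropping %s: internal stop codon", gene_id)
        return None
    return seq


def read_orfeome(path: str | Path, species_id: str | None = None) -> list[OrfRecord]:
    """Read and validate one species ORFeome FASTA.

    Parameters
    ----------
    path
        Nucleotide FASTA of coding sequences; record IDs are gene IDs.
    species_id
        Defaults to the file stem.

    Returns
    -------
    list of OrfRecord
        Records failing validation are dropped (and logged).  When a gene ID
        occurs more than once, the longest sequence wins; equal lengths keep
        the first encountered.
    """
    path = Path(path)
    if species_id is None:
        species_id = path.stem
    best: dict[str, str] = {}
    order: list[str] = []
    n_seen = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_seen += 1
        raw = str(rec.seq)
        prev = best.get(rec.id)
        if prev is not None:
            if len(raw) > len(prev):
                best[rec.id] = raw
            continue
        best[rec.id] = raw
        order.append(rec.id)
    if n_seen == 0:
        raise ValueError(f"{path}: empty or unparseable FASTA")
    records = []
    for gene_id in order:
        cds = _clean_cds(best[gene_id], gene_id)
        if cds is not None:
            records.append(OrfRecord(gene_id=gene_id, species_id=species_id, cds=cds))
    logger.info(
        "%s: %d/%d sequences retained (%d unique IDs)",
        species_id, len(records), n_seen, len(order),
    )
    return records


@dataclass
class CodonUsageTable:
    """Per-species codon counts, frequencies and synonymous-set summaries.

    ``counts`` and ``freq`` are length-61 arrays indexed like
    :data:`codoncons.code.SENSE_CODONS`; ``freq`` is per 1000 codons.  The
    ``set_*`` arrays give, for each codon, the max / min / mean frequency over
    its synonymous set — the ingredients of the %MinMax score.
    """

    species_id: str
    counts: np.ndarray
    freq: np.ndarray = field(init=False)
    set_max: np.ndarray = field(init=False)
    set_min: np.ndarray = field(init=False)
    set_mean: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (61,):
            raise ValueError("counts must have one entry per sense codon")
        if (self.counts < 0).any():
            raise ValueError("negative codon count")
        total = self.counts.sum()
        if total == 0:
            raise ValueError("empty usage table")
        self.freq = 1000.0 * self.counts / total
        self._set_from_freq()

    def _set_from_freq(self) -> None:
        self.set_max = np.empty(61)
        self.set_min = np.empty(61)
        self.set_mean = np.empty(61)
        for syn in SYN_CODON_ARRAYS:
            f = self.freq[syn]
            self.set_max[syn] = f.max()
            self.set_min[syn] = f.min()
            self.set_mean[syn] = f.mean()

    @classmethod
    def from_records(cls, records: list[OrfRecord]) -> "CodonUsageTable":
        if not records:
            raise ValueError("no records")
        counts = np.zeros(61, dtype=np.int64)
        for rec in records:
            counts += np.bincount(rec.codon_idx, minlength=61)
        return cls(species_id=records[0].species_id, counts=counts)

    @classmethod
    def from_freq(cls, species_id: str, freq: np.ndarray, total: int = 10**6) -> "CodonUsageTable":
        """Build a table from target frequencies by scaling to integer counts."""
        freq = np.asarray(freq, dtype=float)
        counts = np.maximum(np.rint(freq / freq.sum() * total), 1).astype(np.int64)
        return cls(species_id=species_id, counts=counts)

    def is_rare(self, codon: str | int) -> bool:
        """True iff the codon's frequency is below its synonymous-set mean."""
        if isinstance(codon, str):
            if codon in STOP_CODONS:
                raise ValueError(f"{codon} is a stop codon")
            idx = CODON_INDEX.get(codon)
            if idx is None:
                raise ValueError(f"invalid codon {codon!r}")
        else:
            idx = int(codon)
        return bool(self.freq[idx] < self.set_mean[idx])

    @property
    def rare_mask(self) -> np.ndarray:
        return self.freq < self.set_mean

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "codon": SENSE_CODONS,
                "amino_acid": CODON_AA,
                "count": self.counts,
                "freq_per_1000": self.freq,
                "is_rare": self.rare_mask,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def usage_table(records: list[OrfRecord]) -> CodonUsageTable:
    """Count codon usage over an ORFeome (trailing stops already stripped)."""
    return CodonUsageTable.from_records(records)


def is_rare(table: CodonUsageTable, codon: str) -> bool:
    return table.is_rare(codon)


def write_orfeome(records: list[OrfRecord], path: str | Path) -> None:
    """Write records back to FASTA (no stop codons; used for round-trips)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n{rec.cds}\n")
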