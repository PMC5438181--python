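"""Homolog families: aligned proteins, species filtering and coordinate maps.

A homolog family is a set of homologous proteins, at most one per species,
together with a pre-computed protein multiple alignment.  This module only
consumes alignments (e.g. MUSCLE output); it never computes them.  Its job
is bookkeeping: enforcing one-member-per-species (representatives drawn at
random, as recent paralogs would otherwise inflate co-occurrence), checking
that each aligned row matches the translated CDS, and mapping 0-based
residue indices to 0-based alignment columns.  Columns containing a gap in
any member are excluded from all downstream statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .orfeome import OrfRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyMember",
    "HomologFamily",
    "load_family",
    "filter_paralogs",
    "map_peaks_to_columns",
    "read_membership",
]


@dataclass(frozen=True)
class FamilyMember:
    species_id: str
    gene_id: str
    aligned: str  # protein with '-' gaps
    record: OrfRecord | None = None

    @property
    def protein(self) -> str:
        return self.aligned.replace("-", "")


@dataclass
class HomologFamily:
    """Aligned homolog family with residue-to-column maps.

    ``col_maps[k][i]`` is the alignment column of residue ``i`` of member
    ``k``; ``eligible_cols`` are the columns gap-free in every member.
    """

    family_id: str
    members: list[FamilyMember]
    L: int = field(init=False)
    col_maps: list[np.ndarray] = field(init=False)
    eligible_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.family_id}: empty family")
        lengths = {len(m.aligned) for m in self.members}
        if len(lengths) != 1:
            raise ValueError(f"{self.family_id}: alignment rows of unequal length")
        self.L = lengths.pop()
        species = [m.species_id for m in self.members]
        if len(set(species)) != len(species):
            raise ValueError(f"{self.family_id}: more than one member per species")
        gap = np.stack(
            [np.frombuffer(m.aligned.encode(), dtype=np.uint8) == ord("-") for m in self.members]
        )
        self.col_maps = [np.nonzero(~row)[0] for row in gap]
        self.eligible_mask = ~gap.any(axis=0)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def eligible_cols(self) -> np.ndarray:
        return np.nonzero(self.eligible_mask)[0]


def filter_paralogs(
    members: list[FamilyMember], rng: np.random.Generator
) -> list[FamilyMember]:
    """Keep exactly one member per species, chosen uniformly at random.

    Output preserves the input order of the chosen representatives and is
    deterministic under a fixed generator state.
    """
    by_species: dict[str, list[int]] = {}
    for i, m in enumerate(members):
        by_species.setdefault(m.species_id, []).append(i)
    keep = set()
    for species in sorted(by_species):
        idxs = by_species[species]
        keep.add(idxs[int(rng.integers(len(idxs)))] if len(idxs) > 1 else idxs[0])
    return [m for i, m in enumerate(members) if i in keep]


def load_family(
    family_id: str,
    membership: pd.DataFrame,
    alignment_path: str | Path,
    orfeomes: dict[str, dict[str, OrfRecord]],
    rng: np.random.Generator | None = None,
) -> HomologFamily | None:
    """Assemble one family from its membership rows and aligned FASTA.

    Aligned FASTA headers are ``species_id|gene_id``.  Members whose
    ungapped alignment row does not equal their translated CDS are dropped
    with a warning; families left with fewer than two members are skipped
    (returns None).  When a species contributes several members a random
    representative is kept (``rng`` required in that case).
    """
    rows = membership[membership["family_id"] == family_id]
    allowed = {(r.species_id, r.gene_id) for r in rows.itertuples()}
    members: list[FamilyMember] = []
    for rec in SeqIO.parse(str(alignment_path), "fasta"):
        species_id, _, gene_id = rec.id.partition("|")
        if allowed and (species_id, gene_id) not in allowed:
            logger.warning("%s: %s not in membership table; dropped", family_id, rec.id)
            continue
        orf = orfeomes.get(species_id, {}).get(gene_id)
        if orf is None:
            logger.warning("%s: %s|%s missing from ORFeome; dropped", family_id, species_id, gene_id)
            continue
        member = FamilyMember(species_id=species_id, gene_id=gene_id, aligned=str(rec.seq), record=orf)
        if member.protein != orf.protein:
            logger.warning("%s: %s|%s alignment/CDS mismatch; dropped", family_id, species_id, gene_id)
            continue
        members.append(member)
    species = [m.species_id for m in members]
    if len(set(species)) != len(species):
        if rng is None:
            raise ValueError(f"{family_id}: paralogs present but no RNG supplied")
        members = filter_paralogs(members, rng)
    if len(members) < 2:
        logger.warning("%s: fewer than 2 members after filtering; skipped", family_id)
        return None
    return HomologFamily(family_id=family_id, members=members)


def map_peaks_to_columns(
    family: HomologFamily, peaks_per_member: list[np.ndarray]
) -> list[np.ndarray]:
    """Map per-member peak codon indices to alignment columns.

    ``peaks_per_member[k]`` holds 0-based residue indices of member ``k``'s
    cluster peaks.  Returns per-member sorted column arrays.  Peaks cannot
    land on that member's gap columns by construction.
    """
    if len(peaks_per_member) != family.n:
        raise ValueError("one peak array required per member")
    cols = []
    for cmap, peaks in zip(family.col_maps, peaks_per_member):
        peaks = np.asarray(peaks, dtype=np.intp)
        if peaks.size and (peaks.min() < 0 or peaks.max() >= len(cmap)):
            raise ValueError("peak codon index outside member protein")
        cols.append(np.sort(cmap[peaks]))
    return cols


def peak_column_membership(
    family: HomologFamily, peak_cols: list[np.ndarray]
) -> dict[int, set[int]]:
    """Invert per-member peak columns into column -> set of member indices."""
    out: dict[int, set[int]] = {}
    for k, cols in enumerate(peak_cols):
        for c in cols.tolist():
            out.setdefault(c, set()).add(k)
    return out


def read_membership(path: str | Path) -> pd.DataFrame:
    """Read the family membership table (family_id, species_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "species_id", "gene_id"}
    if not required <= set(df.columns):
        raise ValueError(f"membership table must have columns {sorted(required)}")
    return df
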