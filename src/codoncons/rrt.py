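"""Random reverse translations (RRTs): a GC3- and codon-pair-matched null.

Rare codon clusters can align across homologs for reasons unrelated to
codon rarity — amino-acid composition, selection on GC content, codon-pair
bias.  An RRT re-encodes a protein with synonymous codons sampled from its
species' usage, conditioned on two features of the source sequence:

* **GC3 bins** — coding sequences are sorted into partially overlapping
  %GC3 bins (10 points wide, 5-point step: 20-30, 25-35, ...), each
  sequence joining the bin whose midpoint is nearest its own %GC3.  RRT
  codons are drawn from the codon counts of the source sequence's bin,
  which reproduces the source's local GC3 regime.
* **Codon-pair multipliers** — for an ordered pair (A, B), the enrichment
  of codon A immediately 5' of codon B relative to A's local background:
  the usage frequency of A among aa(A) residues at the -1 position of B,
  divided by A's frequency among aa(A) residues inside 17-codon windows
  centred on B occurrences (the -1 slot excluded).

RRTs are built 3' to 5': the last codon is drawn proportional to its bin
count, and every earlier codon proportional to bin count times the pair
multiplier against the already-chosen 3' neighbour.

Scoring the ensemble with the *original* species usage tables and the same
co-occurrence machinery yields, per alignment column, the number of
replicates showing significant co-occurrence.  Among columns significant in
at least one replicate, the top 5% by count are *suspect*, and suspects
+/- 8 columns are masked from family-level calls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .code import CODON_GC3, SYN_CODON_ARRAYS, aa_indices
from .cooccurrence import DEFAULT_THRESHOLD, DEFAULT_TOLERANCE, column_pvalues
from .families import HomologFamily
from .minmax import DEFAULT_WINDOW, minmax_scores, peak_positions
from .orfeome import CodonUsageTable, OrfRecord

logger = logging.getLogger(__name__)

__all__ = [
    "GC3BinTable",
    "PairMultiplierTable",
    "RRTEnsemble",
    "gc3_fraction",
    "build_gc3_bins",
    "pair_multipliers",
    "generate_rrt",
    "generate_rrt_batch",
    "suspect_mask",
    "rrt_column_counts",
]

GC3_BIN_WIDTH = 10.0
GC3_BIN_STEP = 5.0
DEFAULT_REPLICATES = 200
DEFAULT_MASK_RADIUS = 8
DEFAULT_SUSPECT_FRAC = 0.05


def gc3_fraction(cds_or_idx: str | np.ndarray) -> float:
    """%GC3 of a CDS as a fraction in [0, 1] (stop codon already stripped)."""
    if isinstance(cds_or_idx, str):
        third = cds_or_idx[2::3]
        return sum(b in "GC" for b in third) / len(third)
    idx = np.asarray(cds_or_idx)
    return float(CODON_GC3[idx].mean())


@dataclass
class GC3BinTable:
    """Codon counts per overlapping %GC3 bin for one species.

    Bins are ``(lo, lo + width)`` for ``lo = 0, step, 2*step, ...`` in
    percentage points; a sequence belongs to the bin whose midpoint is
    nearest its %GC3 (ties resolved toward the lower bin).  Bins that end
    up empty fall back to the species-wide counts.
    """

    species_id: str
    counts: np.ndarray  # (n_bins, 61)
    global_counts: np.ndarray  # (61,)
    width: float = GC3_BIN_WIDTH
    step: float = GC3_BIN_STEP
    midpoints: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        n_bins = self.counts.shape[0]
        self.midpoints = self.width / 2 + self.step * np.arange(n_bins)

    @property
    def bins(self) -> list[tuple[float, float]]:
        return [(m - self.width / 2, m + self.width / 2) for m in self.midpoints]

    def bin_index(self, gc3: float) -> int:
        """Nearest-midpoint bin of a %GC3 value given as a fraction."""
        g = 100.0 * gc3
        half = self.width / 2
        idx = math.ceil((g - half) / self.step - 0.5)
        return int(np.clip(idx, 0, len(self.midpoints) - 1))

    def counts_for(self, gc3: float) -> np.ndarray:
        """Codon counts of the sequence's bin, falling back to global."""
        row = self.counts[self.bin_index(gc3)]
        if row.sum() == 0:
            return self.global_counts
        return row


def build_gc3_bins(
    records: list[OrfRecord], width: float = GC3_BIN_WIDTH, step: float = GC3_BIN_STEP
) -> GC3BinTable:
    """Aggregate codon counts of an ORFeome into overlapping %GC3 bins."""
    if not records:
        raise ValueError("no records")
    n_bins = int(round((100.0 - width) / step)) + 1
    counts = np.zeros((n_bins, 61), dtype=np.int64)
    table = GC3BinTable(
        species_id=records[0].species_id,
        counts=counts,
        global_counts=np.zeros(61, dtype=np.int64),
    )
    for rec in records:
        idx = rec.codon_idx
        c = np.bincount(idx, minlength=61)
        counts[table.bin_index(gc3_fraction(idx))] += c
        table.global_counts += c
    empty = np.nonzero(counts.sum(axis=1) == 0)[0]
    if empty.size:
        logger.info(
            "%s: %d/%d empty GC3 bins fall back to global counts",
            table.species_id, empty.size, n_bins,
        )
    return table


@dataclass
class PairMultiplierTable:
    """61x61 matrix of codon-pair multipliers ``mult[A, B]``.

    ``mult[A, B]`` is the enrichment of codon A at the -1 position of codon
    B relative to A's background frequency (among synonymous codons of
    aa(A)) inside windows centred on B.  Pairs whose background or focal
    *denominator* is zero default to 1; a zero focal *numerator* with
    observed denominator yields 0 (strong avoidance).
    """

    species_id: str
    mult: np.ndarray
    window: int = 17

    def __post_init__(self) -> None:
        if self.mult.shape != (61, 61):
            raise ValueError("multiplier matrix must be 61x61")
        if (self.mult < 0).any():
            raise ValueError("multipliers must be non-negative")


def _offset_pair_counts(seqs: list[np.ndarray], offsets: list[int]) -> np.ndarray:
    """count[A, B] of codon A at the given offsets relative to codon B."""
    counts = np.zeros(61 * 61, dtype=np.int64)
    for x in seqs:
        L = len(x)
        for d in offsets:
            if L <= abs(d):
                continue
            # positions i of B range so that i + d stays in bounds
            if d < 0:
                a, b = x[: L + d], x[-d:]
            elif d > 0:
                a, b = x[d:], x[: L - d]
            else:
                a, b = x, x
            counts += np.bincount(a * 61 + b, minlength=61 * 61)
    return counts.reshape(61, 61)


def _aa_sums(codon_matrix: np.ndarray) -> np.ndarray:
    """Sum rows of a (61, 61) codon-by-codon matrix over synonymous sets of A."""
    out = np.empty_like(codon_matrix, dtype=np.float64)
    for syn in SYN_CODON_ARRAYS:
        out[syn] = codon_matrix[syn].sum(axis=0)
    return out


def pair_multipliers(
    records: list[OrfRecord], window: int = 17
) -> PairMultiplierTable:
    """Estimate codon-pair multipliers from an ORFeome.

    ``window`` (odd) is the width of the local-background window centred on
    each occurrence of the 3' codon B; the -1 slot is excluded from the
    background.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not records:
        raise ValueError("no records")
    half = window // 2
    seqs = [rec.codon_idx for rec in records]
    bg_offsets = [d for d in range(-half, half + 1) if d != -1]
    bg = _offset_pair_counts(seqs, bg_offsets).astype(np.float64)
    focal = _offset_pair_counts(seqs, [-1]).astype(np.float64)
    bg_aa = _aa_sums(bg)
    focal_aa = _aa_sums(focal)
    mult = np.ones((61, 61))
    ok = (bg_aa > 0) & (focal_aa > 0) & (bg > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (focal / focal_aa) / (bg / bg_aa)
    mult[ok] = ratio[ok]
    return PairMultiplierTable(species_id=records[0].species_id, mult=mult, window=window)


def generate_rrt_batch(
    protein: str,
    bin_counts: np.ndarray,
    multipliers: PairMultiplierTable | None,
    n_replicates: int,
    rng: np.random.Generator,
    global_counts: np.ndarray | None = None,
) -> np.ndarray:
    """Sample ``n_replicates`` RRT codon-index sequences for one protein.

    Built 3' to 5': the last codon of each replicate is drawn proportional
    to ``bin_counts``; each earlier codon proportional to
    ``bin_counts[c] * mult[c, next]``.  Amino acids whose synonymous codons
    all have zero bin counts fall back to ``global_counts`` (then uniform).
    Every replicate translates back to ``protein`` by construction.
    """
    aa_idx = aa_indices(protein)
    L = len(aa_idx)
    mult = None if multipliers is None else multipliers.mult
    out = np.empty((n_replicates, L), dtype=np.intp)
    nxt = None  # codon indices chosen at position i + 1, shape (R,)
    for i in range(L - 1, -1, -1):
        syn = SYN_CODON_ARRAYS[aa_idx[i]]
        base = bin_counts[syn].astype(np.float64)
        if base.sum() == 0 and global_counts is not None:
            base = global_counts[syn].astype(np.float64)
        if base.sum() == 0:
            base = np.ones(len(syn))
        if nxt is None or mult is None:
            w = np.broadcast_to(base[:, None], (len(syn), n_replicates))
        else:
            w = base[:, None] * mult[np.ix_(syn, nxt)]
        # columns where the pair multipliers zero everything out revert to base
        dead = w.sum(axis=0) == 0
        if dead.any():
            w = w.copy()
            w[:, dead] = base[:, None]
        cum = np.cumsum(w, axis=0)
        u = rng.random(n_replicates) * cum[-1]
        choice = (cum <= u).sum(axis=0)
        np.clip(choice, 0, len(syn) - 1, out=choice)
        nxt = syn[choice]
        out[:, i] = nxt
    return out


def generate_rrt(
    record: OrfRecord,
    bins: GC3BinTable,
    multipliers: PairMultiplierTable | None,
    seed: int | np.random.Generator,
) -> str:
    """One RRT coding sequence (nucleotide string) for one record."""
    from .code import indices_to_cds

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = bins.counts_for(gc3_fraction(record.codon_idx))
    idx = generate_rrt_batch(
        record.protein, counts, multipliers, 1, rng, global_counts=bins.global_counts
    )[0]
    return indices_to_cds(idx)


@dataclass
class RRTEnsemble:
    """Per-column RRT co-occurrence counts and the derived suspect mask."""

    family_id: str
    n_replicates: int
    column_counts: np.ndarray  # replicates with p < threshold at each column
    suspect_columns: np.ndarray
    masked: np.ndarray  # boolean over alignment columns


def suspect_mask(
    column_counts: np.ndarray,
    top_frac: float = DEFAULT_SUSPECT_FRAC,
    radius: int = DEFAULT_MASK_RADIUS,
) -> tuple[np.ndarray, np.ndarray]:
    """Suspect columns and the +/- radius mask they induce.

    Among columns with a count >= 1, the top ``top_frac`` by count are
    suspect: ``k = max(1, ceil(top_frac * #nonzero))`` with all ties at the
    cutoff included.
    """
    counts = np.asarray(column_counts)
    L = len(counts)
    nz = np.nonzero(counts > 0)[0]
    masked = np.zeros(L, dtype=bool)
    if nz.size == 0:
        return np.empty(0, dtype=np.intp), masked
    k = max(1, math.ceil(top_frac * nz.size))
    cutoff = np.sort(counts[nz])[::-1][k - 1]
    suspects = nz[counts[nz] >= cutoff]
    for c in suspects:
        masked[max(0, c - radius) : c + radius + 1] = True
    return suspects, masked


def rrt_column_counts(
    family: HomologFamily,
    bins_by_species: dict[str, GC3BinTable],
    mult_by_species: dict[str, PairMultiplierTable] | None,
    tables_by_species: dict[str, CodonUsageTable],
    n_replicates: int = DEFAULT_REPLICATES,
    threshold: float = DEFAULT_THRESHOLD,
    tolerance: int = DEFAULT_TOLERANCE,
    window_size: int = DEFAULT_WINDOW,
    rng: int | np.random.Generator = 0,
) -> np.ndarray:
    """Per-column count of RRT replicates with significant co-occurrence.

    Each replicate re-encodes every member with an RRT, re-detects rare
    codon cluster peaks against the member's *original* species usage
    table, and reruns the column test on the family.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    # per member: (R, n_windows) score matrix
    peak_cols_by_rep: list[list[np.ndarray]] = [[] for _ in range(n_replicates)]
    for member, cmap in zip(family.members, family.col_maps):
        rec = member.record
        if rec is None:
            raise ValueError(f"{family.family_id}: member {member.gene_id} has no CDS record")
        bins = bins_by_species[member.species_id]
        mult = None if mult_by_species is None else mult_by_species[member.species_id]
        table = tables_by_species[member.species_id]
        counts = bins.counts_for(gc3_fraction(rec.codon_idx))
        batch = generate_rrt_batch(
            rec.protein, counts, mult, n_replicates, rng,
            global_counts=bins.global_counts,
        )
        scores = minmax_scores(batch, table, window_size)
        for r in range(n_replicates):
            peaks = peak_positions(scores[r])
            peak_cols_by_rep[r].append(np.sort(cmap[peaks]))
    col_counts = np.zeros(family.L, dtype=np.int64)
    for r in range(n_replicates):
        _, p, _ = column_pvalues(
            family.L, family.eligible_mask, peak_cols_by_rep[r], tolerance
        )
        with np.errstate(invalid="ignore"):
            col_counts += np.nan_to_num(p, nan=np.inf) < threshold
    return col_counts


def rrt_ensemble(
    family: HomologFamily,
    bins_by_species: dict[str, GC3BinTable],
    mult_by_species: dict[str, PairMultiplierTable] | None,
    tables_by_species: dict[str, CodonUsageTable],
    n_replicates: int = DEFAULT_REPLICATES,
    threshold: float = DEFAULT_THRESHOLD,
    tolerance: int = DEFAULT_TOLERANCE,
    window_size: int = DEFAULT_WINDOW,
    top_frac: float = DEFAULT_SUSPECT_FRAC,
    radius: int = DEFAULT_MASK_RADIUS,
    rng: int | np.random.Generator = 0,
) -> RRTEnsemble:
    """Full RRT screen of one family: counts, suspects and mask."""
    counts = rrt_column_counts(
        family, bins_by_species, mult_by_species, tables_by_species,
        n_replicates=n_replicates, threshold=threshold, tolerance=tolerance,
        window_size=window_size, rng=rng,
    )
    suspects, masked = suspect_mask(counts, top_frac=top_frac, radius=radius)
    return RRTEnsemble(
        family_id=family.family_id,
        n_replicates=n_replicates,
        column_counts=counts,
        suspect_columns=suspects,
        masked=masked,
    )
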