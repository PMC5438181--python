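"""%MinMax sliding-window profiles and rare codon cluster detection.

The %MinMax score of a codon window compares the actual mean codon usage
frequency against the two hypothetical encodings of the same amino acids
using, respectively, the most common (+100) and the most rare (-100)
synonymous codon for each residue.  With window means

    Xactual = mean freq(c_i)          (codons actually used)
    Xmax    = mean max-synonymous freq per residue
    Xmin    = mean min-synonymous freq per residue
    Xavg    = mean synonymous-set mean freq per residue

the score is ``100 * (Xactual - Xavg) / (Xmax - Xavg)`` when
``Xactual >= Xavg`` and ``-100 * (Xavg - Xactual) / (Xavg - Xmin)``
otherwise.  A window whose denominator vanishes (only single-codon amino
acids, or a fully degenerate set of frequencies) scores 0: such a window
carries no synonymous signal.

A *rare codon cluster* is a maximal run of consecutive windows with score
strictly below zero; its *peak* is the most negative window (ties broken
toward the 5' end).  Windows are anchored at their first codon, so a peak's
codon index is the 0-based index of the first codon in the peak window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .orfeome import CodonUsageTable, OrfRecord

__all__ = [
    "MinMaxProfile",
    "RareCodonCluster",
    "minmax_profile",
    "detect_clusters",
    "minmax_scores",
    "peak_positions",
]

DEFAULT_WINDOW = 17


def _window_means(values: np.ndarray, w: int) -> np.ndarray:
    """Sliding means of length-w windows along the last axis."""
    cs = np.cumsum(values, axis=-1, dtype=float)
    pad_shape = values.shape[:-1] + (1,)
    cs = np.concatenate([np.zeros(pad_shape), cs], axis=-1)
    return (cs[..., w:] - cs[..., :-w]) / w


def minmax_scores(
    codon_idx: np.ndarray, table: CodonUsageTable, window_size: int = DEFAULT_WINDOW
) -> np.ndarray:
    """%MinMax scores for one codon-index sequence or a batch of them.

    ``codon_idx`` may be shape (L,) or (R, L); the result drops the last
    ``window_size - 1`` positions along the final axis.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    codon_idx = np.asarray(codon_idx)
    if codon_idx.shape[-1] < window_size:
        return np.empty(codon_idx.shape[:-1] + (0,))
    # difference before the window mean: degenerate windows are exactly zero
    # and the +/-100 endpoints are exact (no cancellation between cumsums)
    up = _window_means(table.freq[codon_idx] - table.set_mean[codon_idx], window_size)
    den_up = _window_means(table.set_max[codon_idx] - table.set_mean[codon_idx], window_size)
    den_dn = _window_means(table.set_mean[codon_idx] - table.set_min[codon_idx], window_size)
    # ratio before the factor of 100: up/den is exact at the +/-100 endpoints
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = np.where(den_up > 0, 100.0 * (up / np.where(den_up > 0, den_up, 1.0)), 0.0)
        neg = np.where(den_dn > 0, 100.0 * (up / np.where(den_dn > 0, den_dn, 1.0)), 0.0)
    return np.where(up >= 0, pos, neg)


@dataclass
class MinMaxProfile:
    """Per-window %MinMax scores for one coding sequence."""

    gene_id: str
    window_size: int
    scores: np.ndarray

    @property
    def window_start_index(self) -> np.ndarray:
        """0-based codon index of each window's first codon."""
        return np.arange(len(self.scores))

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RareCodonCluster:
    gene_id: str
    start_window: int
    end_window: int  # inclusive
    peak_codon_index: int
    peak_score: float


def minmax_profile(
    record: OrfRecord, table: CodonUsageTable, window_size: int = DEFAULT_WINDOW
) -> MinMaxProfile:
    """Compute the %MinMax profile of one CDS against a species usage table.

    Proteins shorter than the window yield an empty profile.
    """
    scores = minmax_scores(record.codon_idx, table, window_size)
    return MinMaxProfile(gene_id=record.gene_id, window_size=window_size, scores=scores)


def _negative_runs(scores: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) inclusive window index pairs of maximal runs with score < 0."""
    neg = scores < 0
    if not neg.any():
        return []
    padded = np.concatenate([[False], neg, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_clusters(profile: MinMaxProfile) -> list[RareCodonCluster]:
    """Maximal negative runs of the profile, each with its 5'-most minimal peak."""
    clusters = []
    for start, end in _negative_runs(profile.scores):
        seg = profile.scores[start : end + 1]
        off = int(np.argmin(seg))  # argmin returns the first minimum
        clusters.append(
            RareCodonCluster(
                gene_id=profile.gene_id,
                start_window=start,
                end_window=end,
                peak_codon_index=start + off,
                peak_score=float(seg[off]),
            )
        )
    return clusters


def peak_positions(scores: np.ndarray) -> np.ndarray:
    """Peak codon indices of all clusters in one score vector (fast path)."""
    return np.array(
        [s + int(np.argmin(scores[s : e + 1])) for s, e in _negative_runs(scores)],
        dtype=np.intp,
    )
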