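"""Downstream association tests for families with conserved rare codon clusters.

Three analyses relate CRCC calls to external annotation, all consumed as
plain tables (GO assignments, domain boundary coordinates):

* GO-term enrichment among CRCC vs non-CRCC families (Fisher's exact test,
  family-level counting, by default restricted to the 10 most common terms
  per GO class);
* position of CRCCs relative to structural domain boundaries (binomial
  tests against a uniform-placement null);
* a length-matched control set (greedy nearest-length matching without
  replacement) to separate length effects from CRCC effects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "Domain",
    "go_enrichment",
    "boundary_enrichment",
    "nc_window_test",
    "length_matched_controls",
    "read_go_table",
    "read_domain_table",
]

GO_CLASSES = ("cellular_component", "molecular_function", "biological_process")


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table ((a, b), (c, d))."""
    return float(stats.fisher_exact(((a, b), (c, d)), alternative="two-sided")[1])


def binom_two_sided(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p for k successes out of n at rate p."""
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)


@dataclass
class EnrichmentResult:
    unit: str
    p_value: float
    direction: str  # "enriched" | "depleted" | "none"
    table: tuple | None = None  # contingency or (k, n, expected) inputs
    degenerate: bool = False
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class Domain:
    """One structural domain in 1-based inclusive residue coordinates."""

    protein_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"{self.protein_id}: invalid domain {self.start}-{self.end}")


def read_go_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_id", "go_term", "go_class"}
    if not required <= set(df.columns):
        raise ValueError(f"GO table must have columns {sorted(required)}")
    bad = set(df["go_class"]) - set(GO_CLASSES)
    if bad:
        raise ValueError(f"invalid GO classes: {sorted(bad)}")
    return df.drop_duplicates(["family_id", "go_term"])


def read_domain_table(path) -> list[Domain]:
    df = pd.read_csv(path, sep="\t")
    return [
        Domain(protein_id=str(r.protein_id), start=int(r.start), end=int(r.end))
        for r in df.itertuples()
    ]


def go_enrichment(
    go_table: pd.DataFrame,
    crcc_families: set[str],
    background_families: set[str],
    top_n: int | None = 10,
) -> list[EnrichmentResult]:
    """Fisher's exact test per GO term, CRCC vs non-CRCC families.

    A family counts once per term.  ``top_n`` keeps the N most common terms
    of each GO class (as measured over all analysed families); ``None``
    tests every term.
    """
    if crcc_families & background_families:
        raise ValueError("family sets must be disjoint")
    go = go_table.drop_duplicates(["family_id", "go_term"])
    universe = crcc_families | background_families
    go = go[go["family_id"].isin(universe)]
    terms = []
    for go_class, sub in go.groupby("go_class"):
        counts = sub.groupby("go_term")["family_id"].nunique()
        ranked = counts.sort_values(ascending=False, kind="stable")
        chosen = ranked.index if top_n is None else ranked.index[:top_n]
        terms.extend((t, go_class) for t in chosen)
    results = []
    fam_by_term = go.groupby("go_term")["family_id"].agg(set)
    n_crcc, n_bg = len(crcc_families), len(background_families)
    for term, go_class in terms:
        fams = fam_by_term.get(term, set())
        a = len(fams & crcc_families)
        c = len(fams & background_families)
        b, d = n_crcc - a, n_bg - c
        table = ((a, b), (c, d))
        degenerate = min(a + c, b + d, a + b, c + d) == 0
        if degenerate:
            p, direction = 1.0, "none"
        else:
            p = fisher_two_sided(a, b, c, d)
            odds_num, odds_den = a * d, b * c
            direction = (
                "enriched" if odds_num > odds_den
                else "depleted" if odds_num < odds_den else "none"
            )
        results.append(
            EnrichmentResult(
                unit=term, p_value=p, direction=direction, table=table,
                degenerate=degenerate, extra={"go_class": go_class},
            )
        )
    return results


def _boundary_near_mask(length: int, domains: list[Domain], window: int) -> np.ndarray:
    """Boolean over 1..length: residue within +/- window of a domain boundary."""
    near = np.zeros(length + 1, dtype=bool)  # index 0 unused
    for dom in domains:
        for b in (dom.start, dom.end):
            near[max(1, b - window) : min(length, b + window) + 1] = True
    return near


def _within_mask(length: int, domains: list[Domain]) -> np.ndarray:
    within = np.zeros(length + 1, dtype=bool)
    for dom in domains:
        within[dom.start : min(length, dom.end) + 1] = True
    return within


def boundary_enrichment(
    crcc_positions: dict[str, list[int]],
    domains: dict[str, list[Domain]],
    protein_lengths: dict[str, int],
    near_window: int = 10,
    mode: str = "boundary",
) -> EnrichmentResult:
    """Binomial test of CRCC positions against uniform placement.

    Parameters
    ----------
    crcc_positions
        1-based residue positions of CRCCs per protein.
    mode
        "boundary": near (within +/- near_window of a domain start/end) vs
        far.  "within": inside a domain vs outside.

    Proteins without domain annotation are excluded.  The expected near
    fraction pools eligible residues over all annotated proteins, matching
    a null where CRCCs land uniformly on those proteins.
    """
    if mode not in ("boundary", "within"):
        raise ValueError("mode must be 'boundary' or 'within'")
    k = n = 0
    special = total = 0
    for pid, doms in domains.items():
        if not doms or pid not in protein_lengths:
            continue
        length = protein_lengths[pid]
        mask = (
            _boundary_near_mask(length, doms, near_window)
            if mode == "boundary"
            else _within_mask(length, doms)
        )
        special += int(mask[1:].sum())
        total += length
        for pos in crcc_positions.get(pid, []):
            if not (1 <= pos <= length):
                raise ValueError(f"{pid}: CRCC position {pos} outside protein")
            n += 1
            k += bool(mask[pos])
    if n == 0 or total == 0:
        return EnrichmentResult(
            unit=f"{mode}_enrichment", p_value=1.0, direction="none", degenerate=True
        )
    q = special / total
    if q in (0.0, 1.0):
        return EnrichmentResult(
            unit=f"{mode}_enrichment", p_value=1.0, direction="none",
            table=(k, n, q), degenerate=True,
        )
    p = binom_two_sided(k, n, q)
    direction = "enriched" if k > n * q else "depleted" if k < n * q else "none"
    return EnrichmentResult(
        unit=f"{mode}_enrichment", p_value=p, direction=direction, table=(k, n, q),
        extra={"observed_near": k, "total_crccs": n, "expected_fraction": q},
    )


def _window_span(boundary: int, window: int, mode: str) -> tuple[int, int]:
    """1-based inclusive residue span of a fixed window at a boundary."""
    if mode == "following":
        return boundary + 1, boundary + window
    if mode == "centered":
        return boundary - window // 2 + 1, boundary + (window - window // 2)
    if mode == "flanking":
        return boundary - window, boundary - 1
    raise ValueError("mode must be 'following', 'centered' or 'flanking'")


def nc_window_test(
    crcc_positions: dict[str, list[int]],
    domains: dict[str, list[Domain]],
    protein_lengths: dict[str, int],
    window: int = 50,
    mode: str = "following",
) -> EnrichmentResult:
    """Sign test: CRCCs in N-terminal vs C-terminal domain-boundary windows.

    For each domain a fixed ``window``-residue span is placed at the
    N boundary (domain start) and at the C boundary (domain end), either
    following, centred on, or flanking the boundary.  Domains whose windows
    do not fit inside the protein or whose N and C windows overlap are
    skipped.  Counts are compared with a two-sided Binomial(nN + nC, 0.5).
    """
    n_count = c_count = 0
    skipped = 0
    for pid, doms in domains.items():
        length = protein_lengths.get(pid)
        if length is None:
            continue
        positions = crcc_positions.get(pid, [])
        for dom in doms:
            n_lo, n_hi = _window_span(dom.start, window, mode)
            c_lo, c_hi = _window_span(dom.end, window, mode)
            if n_lo < 1 or c_lo < 1 or n_hi > length or c_hi > length:
                skipped += 1
                continue
            if n_hi >= c_lo:  # overlapping windows
                skipped += 1
                logger.info("%s: overlapping N/C windows for %d-%d; skipped", pid, dom.start, dom.end)
                continue
            for pos in positions:
                n_count += n_lo <= pos <= n_hi
                c_count += c_lo <= pos <= c_hi
    total = n_count + c_count
    if total == 0:
        return EnrichmentResult(
            unit=f"nc_window_{mode}", p_value=1.0, direction="none", degenerate=True,
            extra={"skipped_domains": skipped},
        )
    p = binom_two_sided(n_count, total, 0.5)
    direction = (
        "enriched" if n_count > c_count else "depleted" if n_count < c_count else "none"
    )
    return EnrichmentResult(
        unit=f"nc_window_{mode}", p_value=p, direction=direction,
        table=(n_count, total, 0.5),
        extra={"n_side": n_count, "c_side": c_count, "skipped_domains": skipped},
    )


def length_matched_controls(
    crcc_proteins: list[tuple[str, int]],
    pool: list[tuple[str, int]],
) -> dict[str, str]:
    """Greedy nearest-length matching without replacement.

    Each (id, length) in ``crcc_proteins``, in input order, is matched to
    the unused pool protein with minimal absolute length difference; ties go
    to the shorter candidate (then first-listed).  Returns a mapping
    crcc_id -> control_id; raises if the pool runs out.
    """
    crcc_ids = {pid for pid, _ in crcc_proteins}
    if crcc_ids & {pid for pid, _ in pool}:
        raise ValueError("control pool overlaps the CRCC set")
    available = list(pool)
    matching: dict[str, str] = {}
    unmatched = []
    for pid, length in crcc_proteins:
        if not available:
            unmatched.append(pid)
            continue
        best_i = min(
            range(len(available)),
            key=lambda i: (abs(available[i][1] - length), available[i][1], i),
        )
        matching[pid] = available.pop(best_i)[0]
    if unmatched:
        raise ValueError(f"control pool exhausted; unmatched proteins: {unmatched}")
    return matching
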