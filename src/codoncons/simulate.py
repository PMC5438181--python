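"""Synthetic ORFeomes and homolog families with known ground truth.

Every stage of the pipeline is exercised against data whose generative
process is fully known: species-specific codon usage tables (Dirichlet-skewed
within each synonymous set), per-gene GC3 heterogeneity (Beta-distributed
targets), optional codon-pair bias, homolog families with a conserved core
and gapped termini, and *planted* 17-codon windows of synonymous-rare
encoding at chosen alignment columns in a chosen fraction of species.

Alignments come from simulation bookkeeping, not an aligner, so alignment
error never confounds the statistics; the phylogeny is a star (independent
substitutions from one ancestor), which is all the column tests assume.
Coding sequences are sampled 3' to 5' through the same weighted sampler the
RRT generator uses, so GC3 targets and pair bias enter the data exactly the
way the null model later conditions on them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .code import AMINO_ACIDS, SYN_CODON_ARRAYS, indices_to_cds, translate_indices
from .families import FamilyMember, HomologFamily
from .orfeome import OrfRecord
from .rrt import PairMultiplierTable, generate_rrt_batch

__all__ = [
    "PlantSpec",
    "PairBiasSpec",
    "SimulationConfig",
    "FamilyTruth",
    "SyntheticDataset",
    "simulate_usage_tables",
    "simulate_family",
    "simulate_dataset",
    "emit_dataset",
]


@dataclass(frozen=True)
class PlantSpec:
    """Planted conserved-rare-codon windows.

    ``depth`` is the per-codon probability of forcing a rare synonymous
    codon inside the planted window; ``carrier_fraction`` the fraction of a
    family's members that carry the plant.
    """

    family_fraction: float = 0.6
    depth: float = 0.8
    carrier_fraction: float = 0.8
    width: int = 17

    def __post_init__(self) -> None:
        for p in (self.family_fraction, self.depth, self.carrier_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("plant probabilities must lie in [0, 1]")
        if self.width < 1:
            raise ValueError("plant width must be >= 1")


@dataclass(frozen=True)
class PairBiasSpec:
    """Codon-pair bias tied to the encoded dipeptide, with sequence hotspots.

    A subset of ``n_aa`` multi-codon amino acids is drawn; every ordered
    dipeptide (a, b) within the subset is biased: in each species, the
    rare-side synonymous codons of ``a`` (usage below the set mean in that
    species) receive a multiplier uniform in [strength/2, strength] when the
    3' neighbour encodes ``b``.  Because each species realises the bias on
    its *own* rare codons, conserved dipeptides accumulate aligned rare
    codons across homologs — co-occurrence unrelated to selection on rarity,
    exactly the confounder the RRT null must absorb.

    Scattered biased dipeptides nudge single codons and never localise a
    cluster peak; the positional confounder in real sequences comes from
    conserved low-complexity motifs whose composition triggers the bias
    throughout a window.  ``motif_fraction`` of families therefore receive
    one conserved ``motif_width``-residue segment drawn from the biased
    subset at a random interior position.
    """

    n_aa: int = 0
    strength: float = 6.0
    motif_width: int = 17
    motif_fraction: float = 1.0

    @property
    def enabled(self) -> bool:
        return self.n_aa > 0


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 20
    n_families: int = 50
    family_size: int | None = None  # None: every species in every family
    background_genes_per_species: int = 60
    length_range: tuple[int, int] = (180, 240)
    dirichlet_concentration: float = 0.5
    gc3_beta: tuple[float, float] = (6.0, 6.0)
    substitution_rate: float = 0.3
    #: probability that a codon is chosen frequency-blind (uniform over its
    #: synonymous set) instead of proportional to usage; keeps the realised
    #: rare-codon fraction in the 30-40% range real coding sequences show,
    #: so background genes carry rare codon clusters at realistic densities
    codon_noise: float = 0.5
    max_terminal_extension: int = 25
    internal_deletion_rate: float = 0.0
    internal_deletion_length: tuple[int, int] = (3, 10)
    pair_bias: PairBiasSpec = field(default_factory=PairBiasSpec)
    plant: PlantSpec = field(default_factory=PlantSpec)
    #: margin (columns) kept between a planted window and the trimmed termini
    plant_margin: int = 55
    seed: int = 0


@dataclass
class FamilyTruth:
    family_id: str
    planted: bool
    plant_column: int | None  # 0-based alignment column of the window start
    plant_core_start: int | None  # residue index within the conserved core
    carriers: tuple[str, ...] = ()
    bias_column: int | None = None  # alignment column of a biased-motif segment


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    species: list[str]
    orfeomes: dict[str, list[OrfRecord]]
    families: list[HomologFamily]
    truth: list[FamilyTruth]
    true_freq: dict[str, np.ndarray]  # per-species generator codon frequencies
    true_mult: dict[str, np.ndarray]  # per-species 61x61 pair-multiplier matrix


def simulate_usage_tables(
    n_species: int, concentration: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-species codon frequency vectors (summing to 1 over 61 codons).

    Within each synonymous set, proportions are Dirichlet(concentration);
    amino acids carry equal total mass.  Sets are redrawn on (measure-zero)
    ties so that every multi-codon set has a strict rare/common ordering.
    """
    out = {}
    for s in range(n_species):
        freq = np.empty(61)
        for syn in SYN_CODON_ARRAYS:
            k = len(syn)
            while True:
                props = rng.dirichlet(np.full(k, concentration)) if k > 1 else np.ones(1)
                if k == 1 or len(np.unique(props)) == k:
                    break
            freq[syn] = props / len(SYN_CODON_ARRAYS)
        out[f"sp{s:02d}"] = freq
    return out


def _draw_pair_bias(
    spec: PairBiasSpec,
    species_freq: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], list[int]]:
    """Per-species 61x61 multiplier matrices plus the biased aa subset."""
    mults = {sp: np.ones((61, 61)) for sp in species_freq}
    if not spec.enabled:
        return mults, []
    n_aa = len(SYN_CODON_ARRAYS)
    multi_aa = [i for i in range(n_aa) if len(SYN_CODON_ARRAYS[i]) > 1]
    subset = sorted(rng.choice(multi_aa, size=min(spec.n_aa, len(multi_aa)), replace=False).tolist())
    for aa_a in subset:
        for aa_b in subset:
            s = float(rng.uniform(spec.strength / 2, spec.strength))
            for sp, freq in species_freq.items():
                syn = SYN_CODON_ARRAYS[aa_a]
                rare = syn[freq[syn] < freq[syn].mean()]
                mults[sp][np.ix_(rare, SYN_CODON_ARRAYS[aa_b])] = s
    return mults, subset


def _effective_weights(freq: np.ndarray, noise: float) -> np.ndarray:
    """Within-set sampling weights: (1-noise) * usage + noise * uniform."""
    w = np.empty(61)
    for syn in SYN_CODON_ARRAYS:
        w[syn] = (1.0 - noise) * freq[syn] / freq[syn].sum() + noise / len(syn)
    return w


def _encode(
    protein: str,
    weights: np.ndarray,
    gc3_target: float,
    mult_table: PairMultiplierTable | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample one codon-index encoding honouring GC3 target and pair bias."""
    from .code import CODON_GC3

    gc3_factor = np.where(CODON_GC3, gc3_target / 0.5, (1.0 - gc3_target) / 0.5)
    return generate_rrt_batch(protein, weights * gc3_factor, mult_table, 1, rng)[0]


def _plant_rare(
    idx: np.ndarray,
    span: slice,
    freq: np.ndarray,
    depth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Force rare synonymous codons inside ``span`` with probability depth."""
    idx = idx.copy()
    set_mean = np.empty(61)
    for syn in SYN_CODON_ARRAYS:
        set_mean[syn] = freq[syn].mean()
    for i in range(*span.indices(len(idx))):
        if rng.random() >= depth:
            continue
        syn = next(s for s in SYN_CODON_ARRAYS if idx[i] in s)
        rare = syn[freq[syn] < set_mean[syn]]
        if rare.size == 0:
            continue
        w = freq[rare]
        idx[i] = int(rng.choice(rare, p=w / w.sum()))
    return idx


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length))


def _mutate(
    protein: str, rate: float, protected: list[slice], rng: np.random.Generator
) -> str:
    chars = list(protein)
    shielded = np.zeros(len(chars), dtype=bool)
    for sl in protected:
        shielded[sl] = True
    for i in range(len(chars)):
        if not shielded[i] and rng.random() < rate:
            chars[i] = AMINO_ACIDS[int(rng.integers(len(AMINO_ACIDS)))]
    return "".join(chars)


def simulate_family(
    family_id: str,
    species_freq: dict[str, np.ndarray],
    mults: dict[str, np.ndarray],
    config: SimulationConfig,
    planted: bool,
    rng: np.random.Generator,
    bias_subset: list[int] | None = None,
) -> tuple[HomologFamily, FamilyTruth, dict[str, OrfRecord]]:
    """One homolog family with optional planted rare-codon window.

    Returns the family (alignment built from bookkeeping), its ground
    truth, and the member CDS records keyed by species.
    """
    species = sorted(species_freq)
    if config.family_size is not None and config.family_size < len(species):
        chosen = rng.choice(len(species), size=config.family_size, replace=False)
        species = [species[i] for i in sorted(chosen)]
    n = len(species)
    lo, hi = config.length_range
    L = int(rng.integers(lo, hi + 1))
    plant_spec = config.plant
    margin = config.plant_margin
    if planted:
        start_max = L - plant_spec.width - margin
        if start_max < margin:
            raise ValueError("proteins too short to place an interior plant")
        core_start = int(rng.integers(margin, start_max + 1))
        plant_sl = slice(core_start, core_start + plant_spec.width)
        n_carriers = max(1, round(plant_spec.carrier_fraction * n))
        carriers = {species[i] for i in rng.choice(n, size=n_carriers, replace=False)}
    else:
        core_start = None
        plant_sl = slice(0, 0)
        carriers = set()

    bias = config.pair_bias
    motif_start = None
    if bias.enabled and bias_subset and rng.random() < bias.motif_fraction:
        # conserved low-complexity segment over the biased amino-acid subset
        for _ in range(100):
            cand = int(rng.integers(margin, L - bias.motif_width - margin + 1))
            if not planted or (
                cand + bias.motif_width <= plant_sl.start or cand >= plant_sl.stop
            ):
                motif_start = cand
                break
    motif_sl = (
        slice(motif_start, motif_start + bias.motif_width)
        if motif_start is not None
        else slice(0, 0)
    )
    protected = [plant_sl, motif_sl]

    ancestor = _random_protein(L, rng)
    if motif_start is not None:
        seg = "".join(
            AMINO_ACIDS[int(i)]
            for i in rng.choice(bias_subset, size=bias.motif_width)
        )
        ancestor = ancestor[: motif_sl.start] + seg + ancestor[motif_sl.stop :]
    mult_tables = {sp: PairMultiplierTable(species_id=sp, mult=m) for sp, m in mults.items()}
    weights = {sp: _effective_weights(f, config.codon_noise) for sp, f in species_freq.items()}
    members: list[tuple[str, str, np.ndarray, int, int, np.ndarray]] = []
    max_n_ext = max_c_ext = 0
    for sp in species:
        core = _mutate(ancestor, config.substitution_rate, protected, rng)
        deleted = np.zeros(L, dtype=bool)
        if config.internal_deletion_rate > 0 and rng.random() < config.internal_deletion_rate:
            dlo, dhi = config.internal_deletion_length
            for _ in range(50):
                dlen = int(rng.integers(dlo, dhi + 1))
                dstart = int(rng.integers(0, L - dlen + 1))
                overlaps = any(
                    sl.stop > sl.start
                    and not (dstart + dlen <= sl.start or dstart >= sl.stop)
                    for sl in protected
                )
                if overlaps:
                    continue
                deleted[dstart : dstart + dlen] = True
                break
            else:
                raise ValueError(f"{family_id}: could not place deletion off protected windows")
        n_ext = int(rng.integers(0, config.max_terminal_extension + 1))
        c_ext = int(rng.integers(0, config.max_terminal_extension + 1))
        max_n_ext, max_c_ext = max(max_n_ext, n_ext), max(max_c_ext, c_ext)
        core_kept = "".join(c for c, d in zip(core, deleted) if not d)
        protein = _random_protein(n_ext, rng) + core_kept + _random_protein(c_ext, rng)
        gc3_target = float(rng.beta(*config.gc3_beta))
        idx = _encode(protein, weights[sp], gc3_target, mult_tables[sp], rng)
        if sp in carriers:
            # plant coordinates within this member's ungapped protein
            kept_before = int((~deleted[: plant_sl.start]).sum())
            span = slice(n_ext + kept_before, n_ext + kept_before + plant_spec.width)
            idx = _plant_rare(idx, span, species_freq[sp], plant_spec.depth, rng)
        members.append((sp, core, idx, n_ext, c_ext, deleted))

    fam_members = []
    records: dict[str, OrfRecord] = {}
    for sp, core, idx, n_ext, c_ext, deleted in members:
        gene_id = f"{sp}_{family_id}"
        protein = translate_indices(idx)
        rec = OrfRecord(gene_id=gene_id, species_id=sp, cds=indices_to_cds(idx), protein=protein)
        records[sp] = rec
        pos = 0
        n_ext_gap = "-" * (max_n_ext - n_ext)
        n_part = protein[pos : pos + n_ext]; pos += n_ext
        core_part = []
        for d in deleted:
            if d:
                core_part.append("-")
            else:
                core_part.append(protein[pos]); pos += 1
        c_part = protein[pos : pos + c_ext]; pos += c_ext
        aligned = (
            n_ext_gap + n_part + "".join(core_part) + c_part + "-" * (max_c_ext - c_ext)
        )
        fam_members.append(
            FamilyMember(species_id=sp, gene_id=gene_id, aligned=aligned, record=rec)
        )
    family = HomologFamily(family_id=family_id, members=fam_members)
    truth = FamilyTruth(
        family_id=family_id,
        planted=planted,
        plant_column=None if core_start is None else max_n_ext + core_start,
        plant_core_start=core_start,
        carriers=tuple(sorted(carriers)),
        bias_column=None if motif_start is None else max_n_ext + motif_start,
    )
    return family, truth, records


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full dataset: ORFeomes, families, truth. Deterministic in seed."""
    rng = np.random.default_rng(config.seed)
    species_freq = simulate_usage_tables(
        config.n_species, config.dirichlet_concentration, rng
    )
    species = sorted(species_freq)
    mults, bias_subset = _draw_pair_bias(config.pair_bias, species_freq, rng)
    mult_tables = {sp: PairMultiplierTable(species_id=sp, mult=m) for sp, m in mults.items()}

    weights = {sp: _effective_weights(f, config.codon_noise) for sp, f in species_freq.items()}
    orfeomes: dict[str, list[OrfRecord]] = {sp: [] for sp in species}
    for sp in species:
        lo, hi = config.length_range
        for g in range(config.background_genes_per_species):
            length = int(rng.integers(lo, hi + 1))
            protein = _random_protein(length, rng)
            gc3_target = float(rng.beta(*config.gc3_beta))
            idx = _encode(protein, weights[sp], gc3_target, mult_tables[sp], rng)
            orfeomes[sp].append(
                OrfRecord(
                    gene_id=f"{sp}_bg{g:04d}", species_id=sp,
                    cds=indices_to_cds(idx), protein=protein,
                )
            )

    n_planted = round(config.plant.family_fraction * config.n_families)
    planted_flags = np.zeros(config.n_families, dtype=bool)
    planted_flags[:n_planted] = True
    rng.shuffle(planted_flags)

    families, truths = [], []
    for f in range(config.n_families):
        fam_id = f"fam{f:04d}"
        family, truth, records = simulate_family(
            fam_id, species_freq, mults, config, bool(planted_flags[f]), rng,
            bias_subset=bias_subset,
        )
        families.append(family)
        truths.append(truth)
        for sp, rec in records.items():
            orfeomes[sp].append(rec)
    return SyntheticDataset(
        config=config,
        species=species,
        orfeomes=orfeomes,
        families=families,
        truth=truths,
        true_freq=species_freq,
        true_mult=mults,
    )


def emit_dataset(config: SimulationConfig, outdir: str | Path) -> SyntheticDataset:
    """Write a simulated dataset in the layout the pipeline consumes.

    ``orfeomes/<species>.fasta``, ``families.tsv``, ``alignments/<family>.fasta``
    (headers ``species|gene``) and ``truth.tsv``.
    """
    ds = simulate_dataset(config)
    outdir = Path(outdir)
    (outdir / "orfeomes").mkdir(parents=True, exist_ok=True)
    (outdir / "alignments").mkdir(parents=True, exist_ok=True)
    for sp in ds.species:
        with open(outdir / "orfeomes" / f"{sp}.fasta", "w") as fh:
            for rec in ds.orfeomes[sp]:
                fh.write(f">{rec.gene_id}\n{rec.cds}\n")
    with open(outdir / "families.tsv", "w") as fh:
        fh.write("family_id\tspecies_id\tgene_id\n")
        for fam in ds.families:
            for m in fam.members:
                fh.write(f"{fam.family_id}\t{m.species_id}\t{m.gene_id}\n")
    for fam in ds.families:
        with open(outdir / "alignments" / f"{fam.family_id}.fasta", "w") as fh:
            for m in fam.members:
                fh.write(f">{m.species_id}|{m.gene_id}\n{m.aligned}\n")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("family_id\tplanted\tplant_column_1based\tcarriers\tbias_column_1based\n")
        for t in ds.truth:
            col = "" if t.plant_column is None else str(t.plant_column + 1)
            bcol = "" if t.bias_column is None else str(t.bias_column + 1)
            fh.write(
                f"{t.family_id}\t{int(t.planted)}\t{col}\t{','.join(t.carriers)}\t{bcol}\n"
            )
    return ds


def dataset_digest(outdir: str | Path) -> str:
    """SHA-256 over all emitted files (byte-identity check for determinism)."""
    h = hashlib.sha256()
    for path in sorted(Path(outdir).rglob("*")):
        if path.is_file():
            h.update(path.name.encode())
            h.update(path.read_bytes())
    return h.hexdigest()
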