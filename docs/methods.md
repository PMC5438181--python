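# Methods

This note documents the statistical model, the parameter choices, the
synthetic-data generator, and the numerical decisions behind `codoncons`.

## Model and assumptions

The analysis asks whether *relatively rare* synonymous codons cluster at
the same positions across homologous genes from different species. Rarity
is relative to the synonymous set: codon `c` is rare in a species when its
ORFeome frequency is below the mean frequency of the codons encoding the
same amino acid. This deliberately removes amino-acid composition from the
rarity signal — an absolute-rarity measure would confound codon choice with
residue choice.

Key assumptions:

* one representative sequence per species per family (recent paralogs would
  otherwise contribute pseudo-replicated peaks); representatives are chosen
  uniformly at random under a fixed seed;
* the protein alignment is taken as given and correct; columns containing a
  gap in **any** member are excluded from all statistics;
* peaks of different members are exchangeable under the null — no
  phylogenetic correction is applied (closely related species should be
  pruned from the input, as any dataset built for this analysis does).

## Parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `window_size` | 17 codons | %MinMax sliding-window width |
| `tolerance` | 2 columns | peak co-occurrence distance |
| `threshold` | 1e-4 | per-column significance level |
| `trim` | 50 columns | terminal exclusion beyond the first/last gap-free column |
| `rrt_replicates` | 200 | RRT replicates per gene (50 in the desk-scale studies below) |
| `suspect_frac` | 0.05 | top fraction of replicate-significant columns regarded suspect |
| `mask_radius` | 8 columns | mask around a suspect column (half a %MinMax window) |
| `gc3_bin_width` / `step` | 10 / 5 points | overlapping GC3 bins for RRT codon counts |
| `pair_window` | 17 codons | local-background window for codon-pair multipliers |

All defaults are the analysis' reference values; everything is
configurable through `PipelineParams` / the CLI.

## The column test and the choice of p0

For an eligible column with peaks (within ±`tolerance`) from `m` of `n`
members, the p-value is `P(X ≥ m | X ≥ 1)` with `X ~ Binomial(n, p0)`.
`p0` must be the per-member probability of the *event being counted*: "this
member has ≥1 peak within ±tolerance of the column". We use the empirical
marginal rate — the fraction of eligible columns within ±tolerance of a
peak, averaged over members. Two plausible closed forms were examined and
rejected on calibration grounds (measured on shift-randomized null
families, 20 species, 200 families):

* `(2·tol+1)·P_total/(n·L_eligible)` overstates the rate whenever peak
  windows overlap or clip at the termini; at realistic peak densities
  (~4 peaks per member) the null rejection fraction at `p ≤ 1e-2` drops to
  ~0.09·α — an order of magnitude conservative;
* `P_total/(n·L_eligible)` (no tolerance factor, the "probability of a
  position being a peak") ignores that `m` counts hits in a 5-column
  window; it rejects at ~6.9·α — badly anti-conservative and unusable at
  `threshold = 1e-4`.

With the empirical rate the test is valid but still conservative
(~0.24·α): the conditional binomial tail is discrete, and the true `m` is
Poisson-binomial (members differ in peak count), which has a thinner tail
than the binomial with the same mean. Both effects are inherent to any
single-`p0` binomial model of this statistic; consumers should read the
per-column p-values as upper bounds. The dataset-level circular-shift
permutation test does not share this conservatism and its p-values are
uniform on shift-randomized data (KS p ≈ 0.6 in the test suite).

A noteworthy calibration observation: *un*-shifted null families (no
planted rarity signal at all) already show genuine co-occurrence
enrichment in the global shift test. This is the amino-acid-composition
confounder — conserved residues bias the expected %MinMax contribution the
same way in every member — and is precisely what the RRT null exists to
absorb.

## The RRT null

RRTs re-encode each protein 3'→5' with codons drawn proportional to the
codon counts of the gene's GC3 bin times the codon-pair multiplier against
the already-chosen 3' neighbour. Scoring replicates with the *original*
species usage tables asks: how often does a rarity-blind re-encoding of
these very proteins, with this GC3 and this pair bias, reproduce
significant co-occurrence at this column? Columns where that happens
repeatedly (top 5% by replicate count among columns with ≥1 significant
replicate; `k = max(1, ceil(0.05·#nonzero))`, ties at the cutoff included)
are masked ±8 columns — half a %MinMax window, so any window overlapping
the suspect position is discounted.

Numerical edge rules: a pair whose background or focal denominator is
unobserved gets multiplier 1 (no information); an observed denominator with
zero focal numerator gets 0 (strong avoidance). Amino acids with no counts
in the gene's GC3 bin fall back to the species-wide counts. Masking is
applied per family; the suspect fraction is computed per family (the
dataset-wide alternative would let a few signal-dense families mask columns
in unrelated families).

## Terminal trimming

The most N-terminal gap-free column plus the next 50 columns, and the most
C-terminal gap-free column plus the preceding 50, are flagged and excluded
from family-level calls (the C-side rule mirrors the N-side one). An
alignment whose N and C blocks overlap — or that has no gap-free column —
is trimmed entirely.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Usage tables** — per species, synonymous-set proportions drawn from a
  Dirichlet (concentration 0.5 → strongly skewed sets with a strict
  rare/common ordering), equal mass per amino acid.
* **Codon sampling** — codons are drawn from a mixture of
  usage-proportional and frequency-blind synonymous choice
  (`codon_noise = 0.5`). Pure usage-proportional sampling yields almost no
  rare codon clusters (~0.09 peaks per gene: the mixture puts the realised
  rare-codon fraction at ~40%, as in real coding sequences, giving ~4
  clusters per 200-codon gene).
* **GC3 heterogeneity** — per-gene GC3 targets from Beta(6, 6), applied as
  a third-position GC weighting during sampling. The realised mean sits
  slightly below 0.5 because not every synonymous set offers a GC-ending
  codon.
* **Families** — star phylogeny: one random ancestor, independent
  substitutions at rate 0.3 per member, random terminal extensions (0–25
  residues, producing gapped termini), optional internal deletions. The
  alignment comes from generator bookkeeping, never from an aligner, so
  alignment error cannot confound the statistics.
* **Planted CRCCs** — in 60% of families (default), a 17-codon window at a
  random interior position (≥55 columns from either terminal boundary) is
  amino-acid-conserved in all members; in 80% of members each window codon
  is replaced, with probability 0.8, by a rare-side synonymous codon drawn
  proportional to usage.
* **Pair bias** — all dipeptides over a small amino-acid subset (default 5)
  are biased: each species multiplies the *rare side* of the 5' codon's
  synonymous set by a factor in [strength/2, strength]. One conserved
  17-residue low-complexity motif from the subset is placed per family.
  This is the sequence-driven confounder: scattered biased dipeptides only
  nudge single codons and never localise a cluster peak, whereas a
  conserved motif forces aligned rare codons in every species — exactly
  the false-positive class the RRT screen is built to remove.

What the generator does **not** emulate: phylogenetic correlation between
species, realistic amino-acid composition, within-gene autocorrelated
rarity beyond planted windows/motifs, mRNA-structure-driven codon choice,
and alignment error. Passing the recovery tests therefore shows the
statistics behave as designed under their own assumptions, not that real
ORFeomes meet those assumptions.

## Study scales and measured behaviour

The test suite and `scripts/acceptance.py` run three desk-scale studies
(sized so the whole suite completes in minutes on one CPU):

* **Planted recovery** — 20 species, 50 families, plants in 60% at depth
  0.8 carried by 80% of species, 50 RRT replicates: sensitivity 1.0,
  family false-positive rate 0.0, all recovered best columns within ±2 of
  the planted window start (seed 1 of the acceptance script).
* **Pair-bias efficacy** — same scale, no plants, motif bias at strength 8:
  54% of families significant before RRT masking, 0% after; all motif
  columns masked.
* **Null calibration** — shift-randomized plant-free families: column-test
  rejection fraction at `p ≤ 1e-2` ≈ 0.003 (the conservatism quantified
  above); global shift-test p-values uniform.

## Known limitations

* The per-column binomial p-values are conservative (≈0.2–0.5·α at these
  conditions); the family-level threshold `1e-4` therefore under-calls
  rather than over-calls.
* No multiple-testing correction is applied across columns or families —
  the per-column threshold plus any-column family rule is used as-is.
* The "near domain boundary" window is configurable (default 10 residues);
  an alternative convention of ±20 appears in some analyses and can be set
  via `near_window`.
* `filter_paralogs` and the shift test are seeded; changing the seed
  changes representative choice and permutation draws but, at the study
  scales above, none of the reported conclusions.
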