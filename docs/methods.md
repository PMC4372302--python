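# Methods

`silkgland` re-implements, as a tested library, the comparative analyses
used to contrast the silk glands of six Saturniidae wild silkmoths
(*Antheraea pernyi*, *A. yamamai*, *A. assama*, *Actias selene*,
*Rhodinia newara*, *Samia cynthia*) with each other and with the
domesticated silkworm *Bombyx mori*. This note describes the models and
procedures, the defaults and why they were chosen, what the synthetic
data do and do not emulate, and the numerical decisions that matter.

## Species tree and groups

All tree-aware analyses use the fixed rooted topology

```
((((((A.pernyi, A.yamamai), A.assama), Ac.selene), R.newara), S.cynthia), B.mori)
```

with *S. cynthia* the deepest split inside Saturniidae and *B. mori* the
outgroup. Cocoon-color groups: colored (stable coloration, trait 1) =
{A.yamamai, R.newara, A.assama}; non-colored (trait 0) = {A.pernyi,
Ac.selene, S.cynthia}. `make_species_tree` uses 0.1 substitutions/site
per branch by default; branch lengths are configurable and only their
relative magnitudes matter for the simulations.

## Silk-protein features

**Isoelectric point.** Net charge at a given pH is the
Henderson–Hasselbalch sum over ionizable side chains plus the two
termini; pI is the zero crossing, found by bisection on [0, 14] to
|ΔpH| < 1e-4 (the charge is strictly decreasing in pH, so bisection is
exact). Default pKa values (side chains C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1; N-terminus 8.6, C-terminus 3.6) are a widely
used electrophoresis-calibrated set; any table can be supplied, because
published pI values depend strongly on the constants used and matching
another calculator requires matching its pKa set. 'X' residues carry no
charge.

**Hydropathy.** Sliding-window arithmetic mean of the Kyte–Doolittle
scale; window 9 by default (odd, configurable), hydrophilicity reported
as the negated scale when requested. Profile length is
`len(seq) − window + 1` with window-center coordinates.

**Reference-anchored comparison.** Pairwise global alignment
(end-gap-penalized) under BLOSUM62 with gap open 10 / extend 1, via
Biopython's `PairwiseAligner`; the first gapped position costs the open
penalty, later ones the extension penalty. Downstream composition and
hydropathy comparisons are restricted to columns where neither sequence
is gapped.

**Repeat grammar.** Within an annotated repeat region, maximal
poly-alanine runs of length ≥ 3 (configurable) become polyA blocks;
everything between them is spacer. Spacers are scanned left to right,
greedily and non-overlapping, trying GGGX, then GGX, then GX at each
position (X = any non-glycine residue); unmatched residues are counted
as unparsed, so motifs plus unparsed residues always account for every
spacer position. Longest-first matching avoids double counting; scans
never cross block boundaries.

**Region detection.** The N-terminus/repeat boundary is the start of the
first poly-A run at or after residue 14 (the conserved head), capped at
`nterm_max` (default 110, just above the observed 87–103 range of
fibroin N termini). Detection refuses sequences with no poly-A run and
asks for manual spans instead of guessing.

All coordinates are 0-based, half-open.

## Codon-level molecular evolution

**NG86.** Synonymous/nonsynonymous site counts per codon are the
per-position fractions of non-stop single-base changes that are
synonymous, averaged over the two sequences; codons differing at
several positions average their (syn, nonsyn) difference counts over
all minimal mutational pathways that avoid stop codons (over all
pathways if every one is blocked). Proportions are Jukes–Cantor
corrected; dS = 0 leaves ω undefined rather than infinite.

**One-ratio / free-ratio ML.** The substitution process acts on the 61
sense codons: single-position change i→j has rate
π_j · κ^[transition] · ω^[nonsynonymous], zero otherwise, scaled to one
expected substitution per codon per unit branch length. Likelihood is
computed by Felsenstein pruning with per-site rescaling; identical
columns are collapsed into weighted patterns. Because the chain is
reversible, one symmetric eigendecomposition per (ω, κ) yields P(t) for
every branch, which keeps a 7-taxon, 300-codon fit under a second.

Codon frequencies are F3x4 from the alignment by default (positional
nucleotide frequencies, renormalized over sense codons) with a
uniform-61 option used by the closed-form tests and the simulator.
Optimization is bounded L-BFGS-B from fixed initials — ω 0.4, κ 2,
branch lengths by nonnegative least squares on NG86-derived pairwise
distances — with bounds ω ∈ [1e-4, 10], κ ∈ [0.01, 50], branch
∈ [1e-6, 20]; given identical inputs the fit is deterministic.
Columns containing any gap are deleted before fitting. The free-ratio
model gives each branch its own ω; the likelihood-ratio test compares
2Δl to a chi-square with df = (#branches − 1), the parameter-count
difference of the nested models.

## Trees

**Distances.** p-distance or Tajima–Nei (1984), with complete pairwise
deletion of gap columns; saturated pairs raise an error naming the
pair rather than returning NaN.

**Neighbor joining.** Canonical Saitou–Nei with the Q criterion;
deterministic tie-break by lexicographically smallest label pair;
negative branch estimates are clamped to zero with the deficit moved to
the sibling branch so path lengths are preserved. On additive matrices
the input distances are reproduced exactly.

**Independent contrasts.** Felsenstein's recursion: standardized
contrasts (x_i − x_j)/√(v_i + v_j), weighted-average node values, and
extended branch lengths v + v_i v_j/(v_i + v_j). Polytomies are
refused; a helper resolves them by label order with zero-length
branches, which the recursion accepts (leaf branches must still be
positive). Trait–trait association uses the correlation of contrast
pairs through the origin with a two-sided t-test on (n − 1) df; the
binary color-retention label (1 stable / 0 unstable) is treated as a
continuous trait, mirroring how such labels are used in practice.
Zero-variance contrasts flag the result and return p = 1.

**Reconciliation.** Parsimony LCA mapping: each gene node maps to the
species-tree LCA of its leaves' species; a node is a duplication iff it
maps to the same species node as one of its children; losses along a
gene edge are the species edges skipped between the parent's and
child's images (one fewer at speciations), each attributed to the
species lineage that disappeared. Per-species-node duplication and loss
totals are reported. No rearrangement of weakly supported edges is
attempted.

## Family expression

Transcript RPKM is reads/((length/1000)·(library/1e6)); family RPKM
pools all member reads over all member lengths, so it is invariant to
re-partitioning reads and lengths among members. A family is
group-specific when its RPKM is ≥ 1 (a conventional detection floor) in
every species of one group and < 1 in every species of the other.
Group-specific families are then filtered by the PIC correlation of
their per-species RPKM with the color trait at α = 0.05 (two-sided by
default; a positive-only flag exists because "significant positive
relationship" is the stricter reading of the procedure).

Differential family expression treats the three species of each group
as replicates — the study design has one silk-gland library per
species, so group membership is the only replication; this is a
documented caveat, since species effects and biological noise are
confounded. Counts are scaled to the geometric-mean library size, a
common dispersion is estimated by conditional maximum likelihood
(the conditional likelihood of replicate counts given the group total
is free of the mean when effective library sizes are equal; a log-grid
scan refined by bounded scalar search, deterministic), and each family
gets a two-sided exact test: group sums are negative binomial with
shape n_g/φ, their conditional law given the grand total is negative
hypergeometric, and the p-value doubles the smaller tail (observed
point included, capped at 1). At φ = 0 this reduces to the doubled
binomial tail of the Poisson case. BH step-up controls FDR at 0.05.
The test agrees with edgeR's `exactTest` at fixed common dispersion to
near machine precision for equal group sizes, which the test suite
asserts via Rscript.

## Enrichment

Per GO term, a 2×2 Pearson chi-square (no continuity correction) of
(annotated, not annotated) × (target, background), with the background
excluding target genes — a two-list comparison; overlapping lists are
an error. Expected counts < 5 are flagged. Raw p-values are reported by
default, matching the classical chi-square two-list comparison; BH
adjustment is available. No GO-graph ancestor propagation is performed:
annotations are taken as given.

## Synthetic data

Generators are pure functions of (parameters, seed) and record planted
truth alongside their output.

- **Families** evolve from one ancestral copy down the species tree; on
  each edge every lineage is independently lost with probability
  `loss_rate`, else duplicated with probability `dup_rate` (at most one
  event per lineage per edge, so species membership is exactly
  derivable from per-edge event counts — an invariant the tests
  replay). Families losing every lineage are emitted as extinct with
  empty membership.
- **Counts** are negative binomial (variance μ + φμ², default φ 0.2, a
  typical bulk RNA-seq value) around log-normal family baselines
  (median 100 reads), with planted DE families' means multiplied by the
  fold change in the colored group. Transcript lengths are
  log-normal(6.5, 0.5) truncated at 200 bp, mimicking de novo unigene
  scale (~660 bp median); library sizes default to 2×10⁷ per species.
- **Codon alignments** draw root codons from the equilibrium
  distribution and propagate exact transition matrices down each
  branch, so stop codons can never appear and no gaps are simulated.
- **Fibroin-like proteins** share a fixed 14-residue head; the rest of
  the N terminus (total 87–103 residues) descends from one ancestral
  tail with per-site substitution probability 0.05. Tails exclude
  alanine entirely — substitutions included — so the planted
  repeat-region boundary and poly-A positions are unambiguous ground
  truth. The repeat region alternates poly-A runs (uniform 5–12) with
  spacers of six motifs drawn GGGX:GGX:GX at 1:2:1, X weighted toward
  serine and tyrosine. Sericin-like sequences are i.i.d. draws with an
  elevated serine weight (default 0.33).
- **GO annotations** assign each term to each gene with probability
  0.05, multiplied by the planted factor for enriched terms inside the
  target set.

What the generators do **not** emulate: assembly artifacts and
fragmented or chimeric unigenes, mapping ambiguity between paralogs,
indels in codon alignments, rate variation across sites or lineages,
GC-content covariates, and species-level biological replication. A
passing suite therefore demonstrates correctness of the computations
and calibration under the stated models, not robustness to real
assembly and annotation noise.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use sizes chosen to make the
statistical checks informative at desk scale: 20 seeds × 300 codons for
ω recovery (estimates fall within ±0.1 of the truth 0.3), 500 families
for dispersion recovery (φ̂ ∈ [0.1, 0.3] at truth 0.2), 2000 replicates
for each null calibration (type-I error within [0.03, 0.07] at α =
0.05), and 1000 families with 50 planted 8-fold changes for DE power
(≥ 80% recovered at FDR < 0.05). Every random quantity flows from a
single integer seed through `numpy.random.default_rng`.

## Known limitations

- Published pI values cannot be reproduced exactly without knowing the
  original calculator's pKa table; only the table is configurable.
- Real fibroin repeat regions contain irregularities (broken runs,
  non-grammar insertions) that the clean generator does not produce.
- The free-ratio optimizer handles the 7–9 taxon trees of this problem;
  very large trees would need analytic gradients.
- The exact test conditions on equal effective library sizes after
  normalization; strongly unequal libraries are only approximately
  handled by the geometric-mean scaling.
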