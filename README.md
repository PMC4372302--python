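# silkgland

Comparative silk-gland transcriptomics toolkit for wild silkmoths.

Saturniidae silkmoths (*Antheraea pernyi*, *A. yamamai*, *A. assama*,
*Actias selene*, *Rhodinia newara*, *Samia cynthia*) spin silks that
differ markedly from domesticated *Bombyx mori* silk in strength,
color and spinnability. Comparing their silk-gland transcriptomes
raises a recurring set of computational questions: how do the silk
proteins themselves differ (isoelectric point of the fibroin
N terminus, hydropathy of the repeat region, the poly-alanine /
glycine-motif grammar)? Is the fibroin N terminus under purifying
selection, and uniformly so across lineages? How did the sericin gene
family expand and contract? Which gene families distinguish
colored-cocoon from non-colored-cocoon species once shared ancestry is
accounted for, and what are those families enriched for?

`silkgland` packages each of these analyses as a tested, reusable
library with a synthetic-data generator that plants known truth for
every stage, so every statistic can be validated by recovery and
calibration rather than by eye.

## What it computes

- **Silk-protein features** — pI by Henderson–Hasselbalch bisection
  over a configurable pKa table; Kyte–Doolittle hydropathy profiles;
  reference-anchored global alignment (BLOSUM62) restricted to mutually
  ungapped columns; poly-alanine/spacer decomposition; greedy
  GGGX > GGX > GX motif inventory; amino-acid composition.
- **Codon-level molecular evolution** — Nei–Gojobori (1986) pairwise
  dN/dS with pathway averaging and Jukes–Cantor correction; one-ratio
  and free-ratio Goldman–Yang-style codon models
  (q_ij = π_j κ^[ts] ω^[nonsyn]) fitted by maximum likelihood via
  Felsenstein pruning on the 61 sense codons; likelihood-ratio test
  between the nested branch models.
- **Trees** — Tajima–Nei and p-distances; canonical neighbor joining;
  Felsenstein independent contrasts with origin-constrained
  correlation; parsimony duplication–loss reconciliation of gene trees
  against the species tree by LCA mapping.
- **Family expression** — transcript and family RPKM
  (reads / (kb · million mapped reads), pooled over family members);
  group-specific family calls; phylogenetic trait filtering via PIC;
  negative-binomial exact test (edgeR-equivalent at fixed common
  dispersion) with conditional-ML dispersion estimation and BH FDR.
- **Enrichment** — per-term 2×2 Pearson chi-square of a target gene
  list against a disjoint background.
- **Synthetic data** — the fixed seven-taxon species tree; birth–death
  gene families; NB counts with planted fold changes; codon alignments
  under the one-ratio process; fibroin-like and sericin-like proteins;
  GO tables with planted enrichment — all pure functions of
  (parameters, seed) with recorded truth.

## Worked example

```python
from silkgland import synthetic_data as synth
from silkgland.codon_evol import fit_one_ratio
from silkgland.silk_features import (
    compute_pI, detect_regions, decompose_repeats, motif_inventory,
)

tree = synth.make_species_tree()
aln = synth.simulate_codon_alignment(tree, n_codons=300, omega=0.3,
                                     kappa=2.0, seed=11)
fit = fit_one_ratio(aln, tree, freqs="uniform")
print(f"omega = {fit.omega:.3f}, kappa = {fit.kappa:.2f}, lnL = {fit.lnL:.1f}")

silk = synth.generate_silk_proteins(seed=11)
for species, seq in silk.sequences.records[:3]:
    rec = detect_regions(seq, record_id=species)
    nterm = seq[slice(*rec.nterm_span)]
    inv = motif_inventory(decompose_repeats(rec).spacer_sequences())
    print(f"{species}: nterm pI = {compute_pI(nterm):.2f}, "
          f"boundary = {rec.nterm_span[1]}, motifs = {inv.counts}")
```

prints

```
omega = 0.265, kappa = 2.29, lnL = -2850.9
A.pernyi: nterm pI = 5.00, boundary = 89, motifs = {'GGGX': 13, 'GGX': 27, 'GX': 20}
A.yamamai: nterm pI = 4.74, boundary = 89, motifs = {'GGGX': 11, 'GGX': 30, 'GX': 19}
A.assama: nterm pI = 5.48, boundary = 89, motifs = {'GGGX': 16, 'GGX': 33, 'GX': 11}
```

The one-ratio fit recovers the simulation's ω = 0.3 (an ω well below 1
indicates purifying selection on the N terminus); region detection
finds the planted N-terminus/repeat boundary at residue 89 for every
species, and the motif inventory counts the glycine-rich spacer units
between poly-alanine runs. The acidic pI values reflect the
aspartate/glutamate content that the tail generator happens to draw —
real fibroin N termini span pI ~4.4–7.2 across these species.

## Command line

A thin CLI wraps the library:

```sh
silkgland --seed 3 --out run/ simulate            # full synthetic dataset + truth.json
silkgland --out run/ silk-features run/proteins.faa
silkgland --out run/ dnds run/codons.fna run/species.nwk --mode m0
silkgland --out run/ phylo --mode reconcile \
    --gene-trees run/genetrees.nwk --species-tree run/species.nwk
silkgland --out run/ famexpr run/counts.tsv run/families.tsv run/species.nwk
silkgland --out run/ enrich target.txt background.txt run/go.tsv
```

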