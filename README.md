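# orgpopgen

Intraspecific variation analysis for organellar genomes — plastomes and
multichromosomal plant mitogenomes — at the fine scale of a handful of
populations of one species, where the entire signal is a few dozen SNPs and
InDels scattered over 150–350 kb of sequence.

The package takes aligned complete (or regional) organellar genomes plus a
GFF-style annotation and a sample→population map, and produces:

- **SNP and InDel calls** from the multiple alignment, after trimming the
  duplicated plastome inverted-repeat copy. InDels are *events* under
  simple indel coding: a maximal run of alignment columns with an identical
  per-sample gap pattern is one mutational step, regardless of length.
- **Annotation** of every variant by genomic context (exon / intron /
  intergenic spacer named after its flanking genes, e.g. *ndhD—ccsA*) and
  synonymous/nonsynonymous classification of coding SNPs by codon
  translation (plastid code 11, plant-mitochondrial code 1).
- **Summary statistics**: the substitution spectrum over the six unordered
  base-pair classes (A↔G, C↔T transitions; A↔C, A↔T, G↔C, G↔T
  transversions), per-region variability under both conventional metrics
  (share of all mutations and mutations per bp), within-population
  polymorphism counts, and overall changes per bp.
- **Haplotype networks** by the randomized minimum-spanning-tree method:
  individuals collapse to haplotypes by exact identity over all variant
  characters; Kruskal's algorithm is repeated with random tie-breaking of
  equal-weight edges and the union of the resulting trees is the network,
  with each edge's support being its inclusion fraction (support < 1 marks
  an "alternative pathway" in the genealogy).
- **Phylogenetics**: neighbor-joining (Saitou–Nei) on Jukes–Cantor- or
  HKY-corrected distances, column-bootstrap supports, model choice between
  JC and HKY by AIC using Felsenstein-pruning likelihoods
  (AIC = 2k − 2 ln L, k = 0 for JC, k = 4 for HKY), outgroup rooting, and
  Robinson–Foulds comparison of the plastome and mitogenome trees.
- **A synthetic organellar population simulator** that generates a
  plastome-like reference (LSC/SSC, two exact reverse-complement IRs,
  intron-bearing and minus-strand genes, named spacers) or a 14-region,
  3-chromosome mitogenome-like set, plants SNPs (tunable Ts/Tv ratio κ)
  and InDels (geometric lengths) at region-class-dependent rates with
  hotspot multipliers, and emits the *true* alignment plus a truth table —
  so every downstream stage is testable exactly, with no aligner or
  downloads in the loop.

It also bundles, as an analysis-ready dataset, the published 16-individual
× 8-position mitochondrial SNP genotype matrix and population roster from a
five-population survey of *Pulsatilla patens* (`orgpopgen.datasets`).

## Worked example

Run the whole pipeline on one synthetic plastome dataset:

```bash
orgpopgen run --kind plastome --seed 1 --out out/
# done: 63 SNPs, 99 InDels, 16 haplotypes -> out/
```

This simulates a ~52 kb plastome-like reference and 16 samples from five
populations, calls variants on the true alignment after removing the second
IR copy, and writes the report tree. The numbers mean: 63 substitution
sites and 99 indel events segregate among the 16 samples (the generator is
calibrated so these are ≈64 and ≈96 in expectation, the scale of variation
observed in real intraspecific plastome surveys), and all 16 individuals
carry distinct haplotypes over the full variant set.

`out/summary/regions.tsv` ranks regions by their share of all mutations —
the hotspot spacers dominate, e.g.:

```
region_name      region_class  length  snp_count  indel_count  share_of_total
ndhD—ccsA        intergenic    500     17         38           0.34
trnL(UAG)—ndhF   intergenic    2079    11         17           0.17
rps4—rps16       intergenic    400     6          15           0.13
```

`out/network/edges.tsv` holds the randomized-MST haplotype network; edges
with `support < 1` are alternative genealogical pathways:

```
from   to     distance  support  alternative
P4-1   P4-3   27.0      1.0      False
P4-1   P9-2   27.0      0.5      True
```

`out/tree/tree.nwk` is the NJ tree with bootstrap percentages on internal
nodes, and `out/tree/model_selection.tsv` reports the JC-vs-HKY AIC table.

The same stages are available individually (`simulate`, `call`, `annotate`,
`summarize`, `network`, `tree`, `compare`) for real alignments produced by
an external aligner; see `orgpopgen <command> --help`.

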