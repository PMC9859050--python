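# Methods

## Scope and data model

`orgpopgen` analyses intraspecific variation in organellar genomes from a
multiple sequence alignment; assembly, read mapping and the alignment step
itself are upstream of the package. Coordinates are 1-based inclusive
everywhere (the GFF3 convention), including alignment columns. Sequences
are uppercased on read and `U` is folded to `T`; IUPAC ambiguity codes and
`N` are retained but treated as missing data by every downstream caller —
they are never counted as alleles, never enter distances, and contribute a
flat partial likelihood at the tips.

## Variant calling from the alignment

**IR trimming.** Plastome alignments carry the inverted repeat twice; the
columns whose projected reference position falls inside the later-starting
IR copy are removed before calling, so IR-resident variation is counted
once. Gap columns project to the preceding reference base, so an insertion
immediately following the trimmed copy is removed with it — irrelevant in
practice because the second IR copy ends the circular map. A genome with no
IR annotation passes through unchanged; exactly one IR feature is an error.

**SNPs.** One variant per alignment column containing ≥ 2 distinct
canonical bases. Multiallelic columns yield a single record carrying every
alternative allele; alleles are counted against the majority base, with
ties resolved toward the designated reference sample's base and then
alphabetically. The default reporting threshold is `min_alt_count = 1`
(every variable column, singletons included): with ~16 deep-coverage
assembled genomes per dataset, singleton alleles are real observations, and
a read-mapping-style variant-frequency floor (>0.1) or p-value filter would
erase exactly the private alleles that distinguish individuals. A frequency
threshold remains available as an option; no p-value filter is implemented
because it belongs to read-backed calling, which is out of scope.

**InDels (simple indel coding).** Gap-containing columns are partitioned
into events: a maximal run of contiguous columns with an *identical*
per-sample gap/base pattern is one event, scored presence/absence per
sample, contributing one mutational step however long it is. Pattern
identity (not mere gap presence) defines the block, which makes event
counts well defined when indels of different carriers abut. A column gapped
in every sample is rejected as a malformed alignment. A multiallelic column
is one SNP record (allele multiplicity retained in the record) rather than
several — the convention is stated here because published counts can follow
either rule.

**Positions.** The reference position of a column is the count of non-gap
reference characters at or before it; an InDel's `ref_position` is the last
reference base before the block, and region assignment uses the block's
first reference base (insertions: the base before the insertion point).

## Annotation

The reference is tiled, without gaps or overlaps, into exon segments,
introns (within-gene gaps between CDS segments) and intergenic spacers
named `geneA—geneB` in forward-strand order. On a circular genome the two
terminal spans form one wrapped spacer sharing a single name. Overlapping
gene-level features are rejected rather than disambiguated. Coding SNPs are
classified by translating the reference and alternative codon of the
spliced CDS (exons concatenated, minus-strand genes reverse-complemented)
under NCBI table 11 for plastid and table 1 for plant-mitochondrial CDS
(overridable); a change creating or destroying a stop codon is reported
nonsynonymous with a flag. Variants in tRNA/rRNA genes take exon context
with effect "noncoding" — translation would be meaningless there. RNA
editing is ignored, a known limitation for mitochondrial effect calls.

## Summary statistics

The substitution spectrum assigns each biallelic SNP to one of the six
unordered base-pair classes; a multiallelic SNP contributes one unit split
equally across its alternative alleles' classes. Two per-region
variability metrics circulate in this literature and are both computed and
labelled explicitly: `share_of_total` = (SNPs+InDels)/all mutations, and
`per_bp_density` = (SNPs+InDels)/region length. Within-population
polymorphism counts a site or event for a population iff its members carry
≥ 2 distinct non-missing states there; single-sample populations are zero
by definition and flagged. This ≥2-alleles rule is the package's stated
convention — published per-population counts built by other attribution
rules (e.g. assigning each mutation to one population on a plot) can differ
by one or two. The overall changes-per-bp density takes its denominator as
an explicit argument because the reference-length convention (full genome
including both IRs vs trimmed alignment) varies between studies.

## Haplotypes and the randomized-MST network

Individuals with identical states over all variant characters (SNP bases
plus InDel block presence/absence) share a haplotype, labelled by its first
member. Network distances are simple-indel-coding distances computed on
the event-coded character matrix: each differing SNP state and each
differing block presence is one step (the pairwise `indelblock_distance`
on gapped sequences — substitutions plus gap blocks private to one of the
two sequences — is also provided and is cross-checked in the tests against
the reference implementation in the R package ape).

The network is the union of minimum spanning trees under repeated random
tie-breaking: each iteration runs Kruskal on the haplotype distance matrix
with equal-weight edges processed in a random order; edge support is the
inclusion fraction and support < 1 marks an alternative pathway. The
iteration count is not prescribed by any source; the default is 200 with an
explicit seed, and the tests verify convergence of the union at 2000
iterations to an exhaustive enumeration of *all* minimum spanning trees
(feasible for ≤ 8 nodes via weight-ordered spanning-tree iteration).

## Phylogenetics

**Distances.** Jukes–Cantor: d = −(3/4) ln(1 − 4p/3), defined for
p < 0.75 ("saturated" otherwise). "HKY distance" is the closed-form TN93
estimator evaluated at the single-κ constraint — no simple exact HKY
pairwise formula exists, and the TN93 form is consistent under HKY and
reduces to JC for equal frequencies and JC-proportioned mismatches (checked
to 1e-10). Gaps/ambiguities are excluded pairwise. A pair with a degenerate
base composition (some base absent) falls back to the JC correction.

**NJ.** Saitou–Nei agglomeration with the standard Q-criterion;
Q-ties are broken deterministically by the smallest leaf label in the
candidate clusters. A negative branch length is clamped to zero with the
deficit moved to its sister branch, preserving the joined pair's distance.
NJ recovers additive matrices exactly (tested on random trees, n ≤ 12).

**Bootstrap.** Columns are resampled with replacement; each replicate is
rebuilt into an NJ tree; the support of each internal bipartition of the
full-data tree is the percentage of replicates containing it (supports are
mapped onto the full-data tree rather than onto a consensus). Replicates
whose distances saturate are skipped and count against support.

**Likelihood and model choice.** Felsenstein pruning over site patterns
with the model's rate matrix exponentials; the rate matrix is normalized to
one expected substitution per unit branch length and the root prior is the
stationary distribution, making the log-likelihood reroot-invariant (the
pulley principle; asserted to 1e-8 in tests, and against the analytic
two-sequence JC likelihood). Model selection fixes the NJ topology and
optimizes a single global branch-length scale per model (model choice, not
branch lengths, is the deliverable); JC has no free parameters beyond the
scale, while HKY optimizes κ and the base frequencies by L-BFGS-B from two
starts — the empirical composition and the JC point — so ln L(HKY) ≥
ln L(JC) holds by construction. AIC = 2k − 2 ln L with k = 0 (JC) and
k = 4 (HKY: κ plus three free frequencies). On data simulated under JC,
AIC is expected to pick HKY in a few percent of replicates (the
chi-square tail of the likelihood-ratio statistic against the 2k = 8
penalty); recovery-rate checks are therefore thresholded at 45/50, not
50/50. Scalar optimizations use bounded Brent with tolerance 1e-6 and at
most 200 iterations; non-convergence is flagged on the fit.

**Rooting and comparison.** The root is placed at the midpoint of the
outgroup's pendant edge. Tree comparison reports the Robinson–Foulds
distance (bipartitions present in exactly one tree) plus the leaf
association table used for tanglegram-style displays; graphical rotation
optimization is out of scope.

## The synthetic-data generator

The simulator emulates the structure of a 16-individual, five-population
organellar resequencing survey (population sizes 3/3/4/3/3), not any
particular sequence. The plastome-like reference has an LSC and an SSC
separated by two exact reverse-complement IR copies, ~36 genes including
intron-bearing (one- and two-intron) and minus-strand genes, tRNA/rRNA
genes, and named spacers including the recurrent hotspot spacers
*ndhD—ccsA* (fixed at 500 bp), *rps4—rps16* and *trnL(UAG)—ndhF* (~2 kb).
The mitogenome-like reference is 14 unlinked single-copy regions labelled
chMt1×8, chMt2×4, chMt3×2. The default scale yields a ~50 kb plastome and
a ~40 kb region set — a structurally faithful, reduced-size stand-in chosen
so that a hundred simulated datasets can be analysed in seconds; every
length scales with the `scale` parameter.

Mutational model, with every distribution an explicit artifact choice:

- SNP and InDel counts per region are binomial at per-site,
  region-class-specific rates multiplied by per-region hotspot factors
  (defaults 30/8/3 for the three hotspot spacers). The `calibrated`
  constructor solves the base rates so the expected totals match a target —
  by default 64 SNPs + 96 InDels for the plastome and 8 + 16 for the
  mitogenome set, with 7% of SNPs in coding sequence, the scale of
  variation reported in intraspecific organellar surveys.
- A planted SNP is a transition with probability κ/(κ+2) and each
  transversion with probability 1/(κ+2); the default κ = 0.91 reproduces a
  ~31% transition share (transversion-rich spectra are typical of
  non-coding organellar variation).
- InDel lengths are geometric (p = 0.5, capped at 40 bp); insertions and
  deletions are equally likely; InDels are planted only in non-coding
  regions by default so CDS frames are never broken and effect annotation
  stays well-posed.
- Each mutation is assigned one uniformly chosen population, within which
  every member carries it with probability 0.8 (at least one carrier
  enforced) — a simple, stated stand-in for the mix of private and shared
  variation inside populations. An optional `population_divergence` adds
  Poisson-distributed fully-shared private SNPs per population.
- The first sample of the first population is the annotated reference
  individual and never carries a mutation; both IR copies are held
  invariant (concerted evolution).
- Events never overlap and keep ≥ 1 untouched reference base between InDel
  blocks, so each planted event is recoverable as exactly one called
  variant; the true alignment is emitted directly from the planted events
  with no aligner in the loop. Rates that would mutate more than half the
  sites are refused.

What passing tests on this generator do and do not show: exact recovery
demonstrates that calling, block coalescing and coordinate projection are
correct *given a correct alignment*; it says nothing about alignment error,
repeat-induced ambiguity, heteroplasmy, RNA editing or MTPT paralogy in
real data, none of which are simulated.

## Problem sizes and determinism

Default test and acceptance sizes: 100 simulated plastome datasets
(~50 kb × 16 samples) for truth recovery; 50 random ≤ 8-node tied-weight
matrices at 2000 RMST iterations against the exhaustive all-MST oracle; 100
random additive matrices (n ≤ 12) for NJ; 50 seeded replicates per
generating model (6 taxa × 2 kb) for JC/HKY recovery. All randomness flows
from explicit integer seeds (`numpy.random.default_rng`); the pipeline
splits one base seed into fixed per-stage streams, so identical
config + seed reproduces identical output checksums, and changing the seed
moves only the stochastic stages (network tie-breaking, bootstrap), never
the variant calls on a fixed alignment.
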