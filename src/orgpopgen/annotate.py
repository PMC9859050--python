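"""Genomic context and coding effect of variants.

The reference is tiled, without gaps or overlaps, into exon segments,
introns (the within-gene gaps between exon segments), and intergenic
spacers named after their flanking genes ("geneA—geneB", forward-strand
order).  Coding SNPs are classified synonymous/nonsynonymous by
translating the reference and mutated codon of the spliced CDS; variants
in tRNA/rRNA genes sit in exon context but are never translated
(effect "noncoding").
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Sequence

from Bio.Seq import Seq

from .io import AnnotatedGenome, Feature
from .variants import Variant

__all__ = [
    "Region",
    "RegionInventory",
    "EffectCall",
    "build_region_inventory",
    "locate_variant",
    "snp_effect",
    "annotate_variants",
]

#: NCBI translation tables: plastid CDS use the bacterial/plastid code,
#: plant mitochondrial CDS the standard code.
GENETIC_CODES = {"plastid": 11, "mito": 1}


@dataclass(frozen=True)
class Region:
    name: str
    rclass: str  # "exon" | "intron" | "intergenic"
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class RegionInventory:
    """Ordered regions tiling the whole reference."""

    def __init__(self, regions: Sequence[Region], reference_length: int):
        self.regions = sorted(regions, key=lambda r: r.start)
        self.reference_length = reference_length
        pos = 1
        for r in self.regions:
            if r.start != pos:
                raise ValueError(f"inventory does not tile: gap/overlap at {pos}")
            pos = r.end + 1
        if pos != reference_length + 1:
            raise ValueError("inventory does not tile: short of reference end")
        self._starts = [r.start for r in self.regions]

    def __iter__(self):
        return iter(self.regions)

    def __len__(self):
        return len(self.regions)

    def locate(self, position: int) -> Region:
        if position < 1 or position > self.reference_length:
            raise ValueError(f"out of range: position {position}")
        return self.regions[bisect.bisect_right(self._starts, position) - 1]


def build_region_inventory(
    features: Sequence[Feature], reference_length: int, circular: bool = False
) -> RegionInventory:
    """Tile the reference into exons, introns and named spacers.

    Gene-level features (gene/tRNA/rRNA) must not overlap ("ambiguous
    annotation").  A gene's exon segments are its CDS features when
    present, otherwise its full span; the gaps between consecutive exon
    segments are introns.  On a circular reference the two terminal
    spacers share one name (lastGene—firstGene) and are reported as a
    single wrapped region split in two spans.
    """
    genes = sorted(
        (f for f in features if f.ftype in ("gene", "tRNA", "rRNA")),
        key=lambda f: f.start,
    )
    for a, b in zip(genes, genes[1:]):
        if b.start <= a.end:
            raise ValueError(f"ambiguous annotation: {a.name} overlaps {b.name}")
    cds: dict[str, list[Feature]] = {}
    for f in features:
        if f.ftype == "CDS":
            cds.setdefault(f.name, []).append(f)

    regions: list[Region] = []
    prev_name = None
    pos = 1
    for g in genes:
        if g.start > pos:
            if prev_name is None:
                left = genes[-1].name if circular else "5'"
            else:
                left = prev_name
            regions.append(Region(f"{left}—{g.name}", "intergenic", pos, g.start - 1))
        # a gene's segments are its CDS features contained in its span (IR
        # genes exist in two copies under one name; containment separates them)
        segments = sorted(
            (f for f in cds.get(g.name, []) if g.start <= f.start and f.end <= g.end),
            key=lambda f: f.start,
        ) or [g]
        cursor = g.start
        n_intron = 0
        for k, seg in enumerate(segments):
            if seg.start > cursor:
                n_intron += 1
                suffix = "" if len(segments) == 2 else f" {n_intron}"
                regions.append(
                    Region(f"{g.name} intron{suffix}", "intron", cursor, seg.start - 1)
                )
            regions.append(Region(g.name, "exon", seg.start, seg.end))
            cursor = seg.end + 1
        if cursor <= g.end:  # trailing unsegmented tail folded into the last exon
            regions.append(Region(g.name, "exon", cursor, g.end))
        pos = g.end + 1
        prev_name = g.name
    if pos <= reference_length:
        right = genes[0].name if circular and genes else "3'"
        left = prev_name if prev_name is not None else "5'"
        regions.append(Region(f"{left}—{right}", "intergenic", pos, reference_length))
    if not genes:
        regions = [Region("5'—3'", "intergenic", 1, reference_length)]
    return RegionInventory(regions, reference_length)


def locate_variant(variant: Variant, inventory: RegionInventory) -> Region:
    """Region containing the variant's first reference base.

    InDel blocks straddling a region boundary are assigned to the region
    containing their first reference base.
    """
    return inventory.locate(min(variant.anchor_position, inventory.reference_length))


@dataclass(frozen=True)
class EffectCall:
    effect: str  # "synonymous" | "nonsynonymous" | "noncoding"
    stop_codon: bool = False  # a stop codon was created or destroyed

    def __str__(self) -> str:
        return self.effect + ("*" if self.stop_codon else "")


def _spliced_cds(genome: AnnotatedGenome, gene: Feature) -> tuple[str, list[int]]:
    """Spliced CDS sequence (coding orientation) and genome position per CDS base."""
    segments = sorted(
        (
            f
            for f in genome.features
            if f.ftype == "CDS"
            and f.name == gene.name
            and gene.start <= f.start
            and f.end <= gene.end
        ),
        key=lambda f: f.start,
    ) or [gene]
    seq = "".join(genome.sequence[s.start - 1 : s.end] for s in segments)
    positions = [p for s in segments for p in range(s.start, s.end + 1)]
    if gene.strand == "-":
        seq = str(Seq(seq).reverse_complement())
        positions = positions[::-1]
    return seq, positions


def snp_effect(
    variant: Variant, genome: AnnotatedGenome, code: str = "plastid"
) -> EffectCall:
    """Classify a SNP as synonymous, nonsynonymous or noncoding.

    The reference and the alternative codon of the spliced CDS (exons
    concatenated; minus-strand genes reverse-complemented) are translated
    under the configured genetic code; a SNP creating or destroying a stop
    codon is nonsynonymous with the ``stop_codon`` flag set.
    """
    if variant.vtype != "SNP":
        raise ValueError("effect classification applies to SNPs")
    table = GENETIC_CODES.get(code, code)
    pos = variant.anchor_position
    gene = None
    for f in genome.features:
        if f.ftype in ("gene", "tRNA", "rRNA") and f.start <= pos <= f.end:
            gene = f
            break
    if gene is None or gene.ftype in ("tRNA", "rRNA"):
        return EffectCall("noncoding")
    seq, positions = _spliced_cds(genome, gene)
    if pos not in positions:  # intron
        return EffectCall("noncoding")
    if len(seq) % 3 != 0:
        raise ValueError(f"frame error: spliced CDS of {gene.name} not divisible by 3")
    idx = positions.index(pos)
    ref_base, alt_base = variant.ref_allele, variant.alt_alleles[0]
    if gene.strand == "-":
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        ref_base, alt_base = comp[ref_base], comp[alt_base]
    if seq[idx] != ref_base:
        # the majority allele may differ from the annotated reference's
        # base; translate against what the reference actually carries
        ref_base = seq[idx]
        if alt_base == ref_base:
            alt_base = variant.ref_allele
    codon_start = idx - idx % 3
    ref_codon = seq[codon_start : codon_start + 3]
    alt_codon = (
        ref_codon[: idx % 3] + alt_base + ref_codon[idx % 3 + 1 :]
    )
    aa_ref = str(Seq(ref_codon).translate(table=table))
    aa_alt = str(Seq(alt_codon).translate(table=table))
    if aa_ref == aa_alt:
        return EffectCall("synonymous")
    return EffectCall("nonsynonymous", stop_codon="*" in (aa_ref, aa_alt))


def annotate_variants(
    variants: Sequence[Variant],
    genome: AnnotatedGenome,
    inventory: RegionInventory | None = None,
    code: str = "plastid",
) -> list[Variant]:
    """Fill region and effect fields of every variant, in place."""
    if inventory is None:
        inventory = build_region_inventory(
            genome.features, len(genome), circular=genome.circular
        )
    for v in variants:
        region = locate_variant(v, inventory)
        v.region_name = region.name
        v.region_type = region.rclass
        if v.vtype == "SNP":
            if region.rclass == "exon":
                v.effect = str(snp_effect(v, genome, code=code))
            else:
                v.effect = "noncoding"
        else:
            v.effect = "noncoding"
    return list(variants)
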