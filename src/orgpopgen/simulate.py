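"""Synthetic organellar population data with known truth.

The generator emulates the structure of an intraspecific organellar
resequencing study: a plastome-like circular reference (LSC and SSC
single-copy regions separated by two exact reverse-complement inverted
repeats, with intron-bearing and minus-strand genes and named intergenic
spacers) and a mitogenome-like set of 14 single-copy regions spread over
three chromosomes (8/4/2).  Population samples carry planted SNPs (with a
tunable transition/transversion rate ratio) and InDels (geometric length
distribution) at region-class-dependent rates boosted by per-region
hotspot multipliers, concentrated in non-coding sequence.

The simulator emits the *true* alignment directly — gap columns are placed
where the planted insertions and deletions dictate, with no aligner in the
loop — together with a truth table holding every planted event in exactly
the representation the caller produces, so exact-recovery comparisons are
well defined.

The first sample of the first population is the annotated reference
individual and never carries a mutation; its ungapped sequence equals the
reference.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq

from .annotate import RegionInventory, build_region_inventory
from .io import Alignment, AnnotatedGenome, Feature, write_features, write_population_map
from .variants import Variant

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "build_reference",
    "simulate_population",
    "simulate_regions",
    "concat_alignments",
    "expected_mutation_counts",
    "write_simulation",
]

#: hotspot spacers observed repeatedly in plastome studies of this kind,
#: with their default rate multipliers
DEFAULT_HOTSPOTS = {
    "ndhD—ccsA": 30.0,
    "rps4—rps16": 8.0,
    "trnL(UAG)—ndhF": 3.0,
}

_REGION_CLASS = {"exon": "exon", "intron": "intron", "intergenic": "spacer"}


@dataclass
class SimulationConfig:
    """Study design and mutational parameters of one simulated dataset.

    Default sampling mirrors a 16-individual, 5-population survey
    (3/3/4/3/3).  Rates are per-site event probabilities by region class;
    ``kappa`` is the transition/transversion rate ratio (a planted SNP is a
    transition with probability kappa/(kappa+2)); InDel lengths are
    geometric with success parameter ``indel_length_p``; each mutation is
    assigned to one uniformly chosen population within which every member
    carries it with probability ``carrier_prob`` (at least one carrier
    enforced).
    """

    seed: int = 0
    population_names: tuple[str, ...] = ("P4", "P8", "P9", "P13", "P15")
    population_sizes: tuple[int, ...] = (3, 3, 4, 3, 3)
    snp_rate: dict = field(
        default_factory=lambda: {"exon": 5e-5, "intron": 5e-4, "spacer": 1e-3}
    )
    indel_rate: dict = field(
        default_factory=lambda: {"exon": 0.0, "intron": 1e-3, "spacer": 2e-3}
    )
    hotspot_regions: dict = field(default_factory=lambda: dict(DEFAULT_HOTSPOTS))
    kappa: float = 0.91
    indel_length_p: float = 0.5
    max_indel_length: int = 40
    carrier_prob: float = 0.8
    population_divergence: float = 0.0  # expected extra private SNPs per population

    def __post_init__(self) -> None:
        if len(self.population_names) != len(self.population_sizes):
            raise ValueError("population names/sizes length mismatch")
        for rates in (self.snp_rate, self.indel_rate):
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate out of [0,1]: {k}={v}")
        for name, m in self.hotspot_regions.items():
            if m < 1.0:
                raise ValueError(f"hotspot multiplier < 1: {name}={m}")
        if not 0.0 < self.indel_length_p <= 1.0:
            raise ValueError("indel_length_p outside (0,1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{p}-{i + 1}"
            for p, n in zip(self.population_names, self.population_sizes)
            for i in range(n)
        ]

    @property
    def population_map(self) -> dict[str, str]:
        return {
            f"{p}-{i + 1}": p
            for p, n in zip(self.population_names, self.population_sizes)
            for i in range(n)
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=list))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        for k in ("population_names", "population_sizes"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def calibrated(
        cls,
        reference: "AnnotatedGenome | Sequence[AnnotatedGenome]",
        total_snps: float = 64.0,
        total_indels: float = 96.0,
        coding_snp_fraction: float = 0.07,
        **overrides,
    ) -> "SimulationConfig":
        """Rates solved so the expected planted totals match a target.

        The defaults reproduce the scale of variation of a 16-plastome
        survey (64 SNPs, 96 InDels, ~7% of SNPs in coding sequence); for a
        mitogenome set pass e.g. ``total_snps=8, total_indels=16``.
        """
        cfg = cls(**overrides)
        weights = _class_weights(reference, cfg)
        exon_len = weights["exon_len"]
        noncoding_w = weights["intron_w"] + weights["spacer_w"]
        snp_exon = (
            coding_snp_fraction * total_snps / exon_len if exon_len else 0.0
        )
        snp_nc = (1 - coding_snp_fraction) * total_snps / noncoding_w
        cfg.snp_rate = {"exon": snp_exon, "intron": snp_nc, "spacer": snp_nc}
        indel_nc = total_indels / noncoding_w
        cfg.indel_rate = {"exon": 0.0, "intron": indel_nc, "spacer": indel_nc}
        return cfg


@dataclass
class SimulationTruth:
    """Planted mutations, the true alignment, and per-region counts."""

    variants: list[Variant]
    alignment: Alignment
    reference_id: str
    per_region_counts: dict = field(default_factory=dict)

    def count(self, vtype: str | None = None) -> int:
        if vtype is None:
            return len(self.variants)
        return sum(1 for v in self.variants if v.vtype == vtype)


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------

_LSC_GENES = [
    ("psbA", "-", 0), ("matK", "-", 0), ("rps4", "+", 0), ("rps16", "-", 1),
    ("atpA", "-", 0), ("atpF", "-", 1), ("rpoB", "-", 0), ("petN", "+", 0),
    ("trnV(UAC)", "-", 0), ("ndhC", "-", 0), ("ndhK", "-", 0), ("ndhJ", "-", 0),
    ("rbcL", "+", 0), ("accD", "+", 0), ("ycf4", "+", 0), ("petA", "+", 0),
    ("psbE", "-", 0), ("rps18", "+", 0), ("clpP", "-", 2), ("psbB", "+", 0),
    ("petB", "+", 1), ("rpoA", "-", 0), ("rps14", "+", 0), ("rps8", "-", 0),
]
_SSC_GENES = [
    ("trnL(UAG)", "+", 0), ("ndhF", "-", 0), ("ndhD", "-", 0), ("ccsA", "+", 0),
    ("psaC", "-", 0), ("ndhE", "-", 0), ("ndhA", "-", 1), ("rps15", "-", 0),
]
_IR_GENES = [("rpl2", "-", 0), ("ycf2", "+", 0), ("rrn16", "+", 0), ("rrn5", "+", 0)]

_MT_REGION_GENES = [
    # (chromosome, gene or None, strand, n_introns)
    ("chMt1", "nad5", "+", 1), ("chMt1", "cox1", "+", 0), ("chMt1", "atp9", "-", 0),
    ("chMt1", "ccmB", "+", 0), ("chMt1", "nad7", "+", 1), ("chMt1", "rpl5", "-", 0),
    ("chMt1", None, "+", 0), ("chMt1", "matR", "+", 0),
    ("chMt2", "cox3", "+", 0), ("chMt2", "atp6", "-", 0), ("chMt2", "nad4", "+", 1),
    ("chMt2", None, "+", 0),
    ("chMt3", "rps4", "+", 0), ("chMt3", "nad2", "+", 1),
]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _gene_block(
    rng: np.random.Generator,
    name: str,
    strand: str,
    n_introns: int,
    offset: int,
    scale: float,
) -> tuple[str, list[Feature], int]:
    """Sequence and features of one gene starting at ``offset+1``."""
    feats: list[Feature] = []
    if name.startswith("trn"):
        glen = int(rng.integers(70, 91))
        seq = _random_seq(rng, glen)
        feats.append(Feature(name, "tRNA", offset + 1, offset + glen, strand))
        return seq, feats, glen
    if name.startswith("rrn"):
        glen = max(120, int(rng.integers(400, 1200) * scale))
        seq = _random_seq(rng, glen)
        feats.append(Feature(name, "rRNA", offset + 1, offset + glen, strand))
        return seq, feats, glen
    pieces: list[str] = []
    pos = offset
    exon_lens = [
        3 * int(rng.integers(max(34, int(100 * scale)), max(68, int(400 * scale))))
        for _ in range(n_introns + 1)
    ]
    # pad so the spliced CDS begins with a start and ends with a stop codon
    cds_feats: list[Feature] = []
    exon_seqs = [_random_seq(rng, L) for L in exon_lens]
    exon_seqs[0] = "ATG" + exon_seqs[0][3:]
    exon_seqs[-1] = exon_seqs[-1][:-3] + "TAA"
    # strip internal stop codons so translation is well-behaved
    spliced = "".join(exon_seqs)
    codons = [spliced[i : i + 3] for i in range(0, len(spliced), 3)]
    for i, c in enumerate(codons[:-1]):
        if c in ("TAA", "TAG", "TGA"):
            codons[i] = "CA" + c[2]
    spliced = "".join(codons)
    cut = 0
    exon_seqs = []
    for L in exon_lens:
        exon_seqs.append(spliced[cut : cut + L])
        cut += L
    for i, es in enumerate(exon_seqs):
        if i > 0:
            ilen = max(60, int(rng.integers(200, 700) * scale))
            pieces.append(_random_seq(rng, ilen))
            pos += ilen
        pieces.append(es)
        cds_feats.append(Feature(name, "CDS", pos + 1, pos + len(es), strand))
        pos += len(es)
    if strand == "-":
        # lay the gene down in genome orientation: reverse-complement the
        # spliced pieces while keeping intron placement
        whole = "".join(pieces)
        whole_rc = str(Seq(whole).reverse_complement())
        glen = len(whole)
        new_feats = []
        for f in cds_feats:
            s = offset + 1 + (offset + glen - f.end)
            e = offset + 1 + (offset + glen - f.start)
            new_feats.append(Feature(name, "CDS", s, e, "-"))
        cds_feats = sorted(new_feats, key=lambda f: f.start)
        seq = whole_rc
    else:
        seq = "".join(pieces)
    glen = len(seq)
    feats.append(Feature(name, "gene", offset + 1, offset + glen, strand))
    feats.extend(cds_feats)
    return seq, feats, glen


def _gene_run(
    rng: np.random.Generator,
    genes: list[tuple[str, str, int]],
    offset: int,
    scale: float,
    fixed_spacers: dict[str, int] | None = None,
) -> tuple[str, list[Feature], int]:
    """A run of genes separated by random-length spacers."""
    fixed_spacers = fixed_spacers or {}
    chunks: list[str] = []
    feats: list[Feature] = []
    pos = offset
    prev = None
    for name, strand, n_introns in genes:
        spacer_key = f"{prev}—{name}" if prev else None
        slen = fixed_spacers.get(
            spacer_key, max(40, int(rng.integers(80, 600) * scale))
        )
        chunks.append(_random_seq(rng, slen))
        pos += slen
        seq, gfeats, glen = _gene_block(rng, name, strand, n_introns, pos, scale)
        chunks.append(seq)
        feats.extend(gfeats)
        pos += glen
        prev = name
    return "".join(chunks), feats, pos - offset


def build_reference(
    kind: str, seed: int = 0, scale: float = 1.0
) -> AnnotatedGenome | list[AnnotatedGenome]:
    """Build a plastome-like genome or a 14-region mitogenome-like set.

    ``kind="plastome"`` returns one circular genome with LSC/SSC and two
    exact reverse-complement IR copies, intron-bearing and minus-strand
    genes, and the canonical hotspot spacers at realistic lengths
    (ndhD—ccsA 500 bp, trnL(UAG)—ndhF ~2 kb).  ``kind="mitogenome"``
    returns 14 single-copy regions labelled chMt1 x8, chMt2 x4, chMt3 x2.
    ``scale`` shrinks or grows every random length; the default yields a
    plastome of roughly 35-45 kb — a structurally faithful, reduced-size
    stand-in for a full organellar genome.
    """
    rng = np.random.default_rng(seed)
    if kind == "plastome":
        fixed = {
            "ndhD—ccsA": 500,
            "rps4—rps16": max(150, int(400 * scale)),
            "trnL(UAG)—ndhF": max(300, int(2079 * scale)),
        }
        lsc_seq, lsc_feats, lsc_len = _gene_run(rng, _LSC_GENES, 0, scale, fixed)
        ira_seq, ira_feats, ira_len = _gene_run(rng, _IR_GENES, lsc_len, scale)
        ira_seq += _random_seq(rng, max(50, int(300 * scale)))
        ira_len = len(ira_seq)
        ssc_off = lsc_len + ira_len
        ssc_seq, ssc_feats, ssc_len = _gene_run(rng, _SSC_GENES, ssc_off, scale, fixed)
        ssc_seq += _random_seq(rng, max(40, int(200 * scale)))
        ssc_len = len(ssc_seq)
        irb_seq = str(Seq(ira_seq).reverse_complement())
        irb_off = ssc_off + ssc_len
        irb_feats = []
        for f in ira_feats:
            s = irb_off + 1 + (ssc_off - f.end)
            e = irb_off + 1 + (ssc_off - f.start)
            irb_feats.append(
                Feature(f.name, f.ftype, s, e, "+" if f.strand == "-" else "-")
            )
        seq = lsc_seq + ira_seq + ssc_seq + irb_seq
        feats = (
            lsc_feats
            + ira_feats
            + ssc_feats
            + irb_feats
            + [
                Feature("IRa", "IR", lsc_len + 1, lsc_len + ira_len, "+"),
                Feature("IRb", "IR", irb_off + 1, irb_off + ira_len, "-"),
            ]
        )
        return AnnotatedGenome("plastome", seq, sorted(feats, key=lambda f: f.start),
                               circular=True)
    if kind == "mitogenome":
        regions: list[AnnotatedGenome] = []
        counter: dict[str, int] = {}
        for chrom, gene, strand, n_introns in _MT_REGION_GENES:
            counter[chrom] = counter.get(chrom, 0) + 1
            name = f"{chrom}_r{counter[chrom]}"
            lead = _random_seq(rng, max(60, int(rng.integers(300, 1500) * scale)))
            if gene is not None:
                gseq, gfeats, _ = _gene_block(rng, gene, strand, n_introns, len(lead), scale)
            else:
                gseq, gfeats = "", []
            tail = _random_seq(rng, max(60, int(rng.integers(300, 1500) * scale)))
            regions.append(AnnotatedGenome(name, lead + gseq + tail, gfeats))
        return regions
    raise ValueError(f"unknown reference kind: {kind}")


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def _region_rates(
    inventory: RegionInventory,
    genome: AnnotatedGenome,
    config: SimulationConfig,
    rates: dict,
) -> list[tuple[int, int, float]]:
    """(start, end, per-site rate) for every mutable region.

    Regions inside either inverted repeat are skipped: the two IR copies
    are modelled as evolving in concert and are left invariant.
    """
    irs = genome.features_of_type("IR")
    out = []
    for r in inventory:
        if any(f.start <= r.start <= f.end or f.start <= r.end <= f.end for f in irs):
            continue
        rate = rates.get(_REGION_CLASS[r.rclass], 0.0)
        rate *= config.hotspot_regions.get(r.name, 1.0)
        if rate > 0:
            out.append((r.start, r.end, min(rate, 1.0)))
    return out


def _class_weights(
    reference: AnnotatedGenome | Sequence[AnnotatedGenome], config: SimulationConfig
) -> dict:
    genomes = [reference] if isinstance(reference, AnnotatedGenome) else list(reference)
    exon_len = 0
    intron_w = spacer_w = 0.0
    for g in genomes:
        inv = build_region_inventory(
            [f for f in g.features if f.ftype != "IR"], len(g), circular=g.circular
        )
        irs = g.features_of_type("IR")
        for r in inv:
            if any(
                f.start <= r.start <= f.end or f.start <= r.end <= f.end for f in irs
            ):
                continue
            m = config.hotspot_regions.get(r.name, 1.0)
            if r.rclass == "exon":
                exon_len += r.length
            elif r.rclass == "intron":
                intron_w += r.length * m
            else:
                spacer_w += r.length * m
    return {"exon_len": exon_len, "intron_w": intron_w, "spacer_w": spacer_w}


def expected_mutation_counts(
    reference: AnnotatedGenome, config: SimulationConfig
) -> tuple[float, float]:
    """Analytic expectation of (planted SNPs, planted InDel events)."""
    inv = build_region_inventory(
        [f for f in reference.features if f.ftype != "IR"],
        len(reference),
        circular=reference.circular,
    )
    e_snp = sum(
        (e - s + 1) * p for s, e, p in _region_rates(inv, reference, config, config.snp_rate)
    )
    e_indel = sum(
        (e - s + 1) * p
        for s, e, p in _region_rates(inv, reference, config, config.indel_rate)
    )
    e_snp += config.population_divergence * len(config.population_names)
    return e_snp, e_indel


def _draw_carriers(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference_id: str,
    whole_population: bool = False,
    population: str | None = None,
) -> frozenset[str]:
    popmap = config.population_map
    pops = list(config.population_names)
    by_pop = {p: [s for s, q in popmap.items() if q == p and s != reference_id]
              for p in pops}
    while True:
        pop = population or pops[rng.integers(len(pops))]
        members = by_pop[pop]
        if not members:
            population = None
            continue
        if whole_population:
            return frozenset(members)
        carriers = [m for m in members if rng.random() < config.carrier_prob]
        if carriers:
            return frozenset(carriers)


_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _draw_alt(rng: np.random.Generator, ref: str, kappa: float) -> str:
    p_ts = 1.0 if math.isinf(kappa) else kappa / (kappa + 2.0)
    if rng.random() < p_ts:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][rng.integers(2)]


def _indel_truth(
    alleles: dict[str, str], columns: tuple[int, int], ref_position: int,
    ref_gapped: bool,
) -> Variant:
    """InDel truth record with the majority gap state as reference allele."""
    n_gap = sum(1 for a in alleles.values() if a == "-")
    major = "-" if n_gap > len(alleles) - n_gap else "+"
    alt = "+" if major == "-" else "-"
    return Variant(
        vtype="InDel",
        columns=columns,
        ref_position=ref_position,
        ref_allele=major,
        alt_alleles=(alt,),
        alleles=alleles,
        alt_count=sum(1 for a in alleles.values() if a == alt),
        ref_gapped=ref_gapped,
    )


def simulate_population(
    reference: AnnotatedGenome,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SimulationTruth:
    """Plant mutations on a reference and emit samples plus the true alignment.

    SNP and InDel sites are drawn per region at the configured
    class-specific, hotspot-boosted rates; events never overlap and keep at
    least one untouched reference base between InDel blocks, so every
    planted event is recoverable as exactly one called variant.  InDels are
    insertions or deletions with equal probability.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = len(reference)
    seq = reference.sequence
    inventory = build_region_inventory(
        [f for f in reference.features if f.ftype != "IR"], L,
        circular=reference.circular,
    )
    e_snp, e_indel = expected_mutation_counts(reference, config)
    if e_snp + e_indel / config.indel_length_p > 0.5 * L:
        raise ValueError("saturation refused")

    samples = config.sample_ids
    reference_id = samples[0]
    occupied = np.zeros(L + 2, dtype=bool)  # 1-based with margin slot

    events: list[dict] = []

    # --- InDel events first (they occupy spans plus a 1 bp margin) --------
    for start, end, rate in _region_rates(inventory, reference, config, config.indel_rate):
        n = rng.binomial(end - start + 1, rate)
        for _ in range(n):
            for _try in range(200):
                length = min(int(rng.geometric(config.indel_length_p)),
                             config.max_indel_length)
                p = int(rng.integers(start, end + 1))
                if p + length - 1 > end:
                    continue
                span = slice(p - 1, p + length + 1)  # includes 1 bp margins
                if occupied[max(0, p - 2) : p + length + 1].any():
                    continue
                occupied[max(0, p - 2) : p + length + 1] = True
                kind = "deletion" if rng.random() < 0.5 else "insertion"
                events.append(
                    {
                        "etype": kind,
                        "pos": p,
                        "length": length,
                        "carriers": _draw_carriers(rng, config, reference_id),
                        "inserted": _random_seq(rng, length)
                        if kind == "insertion"
                        else "",
                    }
                )
                break

    # --- SNPs --------------------------------------------------------------
    def plant_snp(p: int, carriers: frozenset[str]) -> None:
        ref_base = seq[p - 1]
        events.append(
            {
                "etype": "snp",
                "pos": p,
                "length": 1,
                "carriers": carriers,
                "alt": _draw_alt(rng, ref_base, config.kappa),
            }
        )

    for start, end, rate in _region_rates(inventory, reference, config, config.snp_rate):
        n = rng.binomial(end - start + 1, rate)
        for _ in range(n):
            for _try in range(200):
                p = int(rng.integers(start, end + 1))
                if occupied[p]:
                    continue
                occupied[p] = True
                plant_snp(p, _draw_carriers(rng, config, reference_id))
                break

    if config.population_divergence > 0:
        spacers = [
            (s, e) for s, e, _ in _region_rates(
                inventory, reference, config, {"spacer": 1.0, "intron": 1.0}
            )
        ]
        for pop in config.population_names:
            for _ in range(rng.poisson(config.population_divergence)):
                for _try in range(200):
                    s, e = spacers[rng.integers(len(spacers))]
                    p = int(rng.integers(s, e + 1))
                    if occupied[p]:
                        continue
                    occupied[p] = True
                    carriers = _draw_carriers(
                        rng, config, reference_id, whole_population=True, population=pop
                    )
                    plant_snp(p, carriers)
                    break

    # --- assemble the true alignment ---------------------------------------
    events.sort(key=lambda ev: ev["pos"])
    chunks: dict[str, list[str]] = {s: [] for s in samples}
    truth_variants: list[Variant] = []
    col = 0  # alignment columns emitted so far
    cursor = 1  # next reference position to copy

    def emit_ref(upto: int) -> None:
        nonlocal col, cursor
        if upto >= cursor:
            block = seq[cursor - 1 : upto]
            for s in samples:
                chunks[s].append(block)
            col += len(block)
            cursor = upto + 1

    for ev in events:
        p, carriers = ev["pos"], ev["carriers"]
        alleles: dict[str, str]
        if ev["etype"] == "snp":
            emit_ref(p - 1)
            ref_base = seq[p - 1]
            for s in samples:
                chunks[s].append(ev["alt"] if s in carriers else ref_base)
            col += 1
            alleles = {s: (ev["alt"] if s in carriers else ref_base) for s in samples}
            n_alt = len(carriers)
            # encode the majority base as the reference allele, exactly as
            # the caller reports it (ties resolve to the reference sample's
            # base, which never carries a mutation)
            if n_alt > len(samples) - n_alt:
                major, minor, n_minor = ev["alt"], ref_base, len(samples) - n_alt
            else:
                major, minor, n_minor = ref_base, ev["alt"], n_alt
            truth_variants.append(
                Variant(
                    vtype="SNP",
                    columns=(col, col),
                    ref_position=p,
                    ref_allele=major,
                    alt_alleles=(minor,),
                    alleles=alleles,
                    alt_count=n_minor,
                )
            )
            cursor = p + 1
        elif ev["etype"] == "deletion":
            emit_ref(p - 1)
            length = ev["length"]
            block = seq[p - 1 : p + length - 1]
            for s in samples:
                chunks[s].append("-" * length if s in carriers else block)
            alleles = {s: ("-" if s in carriers else "+") for s in samples}
            truth_variants.append(
                _indel_truth(alleles, (col + 1, col + length), p - 1, ref_gapped=False)
            )
            col += length
            cursor = p + length
        else:  # insertion after position p
            emit_ref(p)
            length = ev["length"]
            for s in samples:
                chunks[s].append(ev["inserted"] if s in carriers else "-" * length)
            alleles = {s: ("+" if s in carriers else "-") for s in samples}
            truth_variants.append(
                _indel_truth(alleles, (col + 1, col + length), p, ref_gapped=True)
            )
            col += length
    emit_ref(L)

    alignment = Alignment(samples, ["".join(chunks[s]) for s in samples])
    per_region: dict[tuple[str, str], int] = {}
    for v in truth_variants:
        r = inventory.locate(min(v.anchor_position, L))
        per_region[(r.name, v.vtype)] = per_region.get((r.name, v.vtype), 0) + 1
    return SimulationTruth(
        variants=truth_variants,
        alignment=alignment,
        reference_id=reference_id,
        per_region_counts=per_region,
    )


def simulate_regions(
    references: Sequence[AnnotatedGenome],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, SimulationTruth]:
    """Simulate each unlinked region (shared sampling design, one RNG stream)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return {g.name: simulate_population(g, config, rng=rng) for g in references}


def concat_alignments(alignments: Sequence[Alignment]) -> Alignment:
    """Column-wise concatenation over an identical sample set."""
    ids = alignments[0].ids
    for a in alignments[1:]:
        if set(a.ids) != set(ids):
            raise ValueError("sample sets differ")
    return Alignment(
        ids, ["".join(a[s] for a in alignments) for s in ids], normalize=False
    )


def write_simulation(
    outdir: str | Path,
    reference: AnnotatedGenome | Sequence[AnnotatedGenome],
    truths: SimulationTruth | dict[str, SimulationTruth],
    config: SimulationConfig,
) -> dict[str, Path]:
    """Write FASTA/GFF3/TSV artefacts of one simulation to a directory."""
    from .io import write_variant_table  # local import to avoid cycle at import time

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomes = [reference] if isinstance(reference, AnnotatedGenome) else list(reference)
    truth_map = truths if isinstance(truths, dict) else {genomes[0].name: truths}
    paths: dict[str, Path] = {}
    for g in genomes:
        t = truth_map[g.name]
        aln_path = outdir / f"{g.name}.true_alignment.fasta"
        t.alignment.to_fasta(aln_path)
        paths[f"{g.name}.alignment"] = aln_path
        fasta = outdir / f"{g.name}.samples.fasta"
        with open(fasta, "w") as fh:
            for sid in t.alignment.ids:
                fh.write(f">{sid}\n{t.alignment[sid].replace('-', '')}\n")
        paths[f"{g.name}.samples"] = fasta
        gff = outdir / f"{g.name}.gff3"
        write_features(gff, g.features, g.name)
        paths[f"{g.name}.features"] = gff
        tt = outdir / f"{g.name}.truth.tsv"
        write_variant_table(tt, t.variants, samples=list(t.alignment.ids))
        paths[f"{g.name}.truth"] = tt
    pm = outdir / "populations.tsv"
    write_population_map(pm, config.population_map)
    paths["popmap"] = pm
    config.to_json(outdir / "config.json")
    paths["config"] = outdir / "config.json"
    return paths
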