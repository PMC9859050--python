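"""Bundled published data for the *Pulsatilla patens* organellar survey.

Sixteen individuals from five populations in Northeastern Poland
(Kopna Góra P4, Kopytkowo P8, Bemowo Piskie P9, Rudne P13, Zabiele P15)
were resequenced for the complete plastome and for fourteen single-copy
mitogenome regions on three chromosomes.  This module carries the
published sample roster with GenBank accessions and the published
concatenated mitochondrial SNP genotype matrix: 8 SNP positions (five on
chMt1, one on chMt2, two on chMt3) scored in all 16 individuals.  The
SNP at chMt3:4214 lies in the *rps4* gene; the SNP at chMt3:30033 lies in
the *nad2* intron.
"""

from __future__ import annotations

import pandas as pd

from .io import SampleRecord

__all__ = [
    "mt_snp_table",
    "mt_snp_positions",
    "mt_snp_genes",
    "population_roster",
    "population_map",
    "plastome_spectrum_percentages",
    "plastome_totals",
    "plastome_hotspot_counts",
]

#: (chromosome, 1-based position) of each mitochondrial SNP column
MT_SNP_POSITIONS: list[tuple[str, int]] = [
    ("chMt1", 22156),
    ("chMt1", 110241),
    ("chMt1", 110242),
    ("chMt1", 167288),
    ("chMt1", 167297),
    ("chMt2", 30884),
    ("chMt3", 4214),
    ("chMt3", 30033),
]

#: gene context where a SNP falls inside an annotated gene or intron
MT_SNP_GENES: dict[tuple[str, int], str] = {
    ("chMt3", 4214): "rps4",
    ("chMt3", 30033): "nad2 intron",
}

_MT_GENOTYPES = {
    "P4-103": "CGCAACCC",
    "P4-105": "CGCAACCG",
    "P4-106": "CGCAACAC",
    "P8-173": "CGCAACAA",
    "P8-197": "CGCAACAA",
    "P8-206": "CGCCCCCG",
    "P9-120": "CGCAACCG",
    "P9-121": "AGCAAAAG",
    "P9-122": "CGCAACCG",
    "P9-133": "ATAAAAAG",
    "P13-1": "CGCAACCG",
    "P13-2": "CGCAACCG",
    "P13-3": "CGCAACCG",
    "P15-121": "CGCAACCG",
    "P15-123": "CGCAACCG",
    "P15-124": "CGCAACCG",
}

_ROSTER = [
    # (population, locality, samples, plastome accessions, chMt1, chMt2, chMt3)
    ("P4", "Kopna Góra",
     ["P4-103", "P4-105", "P4-106"],
     ["OP115677", "OP115678", "OP115679"],
     ["ON454164", "ON454165", "ON454166"],
     ["ON454180", "ON454181", "ON454182"],
     ["ON454196", "ON454197", "ON454198"]),
    ("P8", "Kopytkowo",
     ["P8-173", "P8-197", "P8-206"],
     ["OP115680", "OP115681", "OP115682"],
     ["ON454167", "ON454168", "ON454169"],
     ["ON454183", "ON454184", "ON454185"],
     ["ON454199", "ON454200", "ON454201"]),
    ("P9", "Bemowo Piskie",
     ["P9-120", "P9-121", "P9-122", "P9-133"],
     ["OP115683", "OP115684", "OP115685", "OP115686"],
     ["ON454170", "ON454171", "ON454172", "ON454173"],
     ["ON454186", "ON454187", "ON454188", "ON454189"],
     ["ON454202", "ON454203", "ON454204", "ON454205"]),
    ("P13", "Rudne",
     ["P13-1", "P13-2", "P13-3"],
     ["OP115687", "OP115688", "OP115689"],
     ["ON454174", "ON454175", "ON454176"],
     ["ON454190", "ON454191", "ON454192"],
     ["ON454206", "ON454207", "ON454208"]),
    ("P15", "Zabiele",
     ["P15-121", "P15-123", "P15-124"],
     ["OP115690", "OP115691", "OP115692"],
     ["ON454177", "ON454178", "ON454179"],
     ["ON454193", "ON454194", "ON454195"],
     ["ON454209", "ON454210", "ON454211"]),
]

#: published substitution spectrum of the 64 plastome SNPs, in percent
PLASTOME_SPECTRUM_PERCENTAGES = {
    "A<->C": 9.38,
    "A<->T": 37.5,
    "G<->C": 3.12,
    "G<->T": 18.75,  # published transversion breakdown lists four classes
    "A<->G": 14.06,
    "C<->T": 17.19,
}

#: published totals: 160 plastome mutations = 64 SNPs + 96 InDels
PLASTOME_TOTALS = {"mutations": 160, "snps": 64, "indels": 96}

#: published (SNPs, InDels) in the three hotspot intergenic spacers
PLASTOME_HOTSPOT_COUNTS = {
    "ndhD—ccsA": (15, 18),
    "rps4—rps16": (6, 6),
    "trnL(UAG)—ndhF": (6, 5),
}


def mt_snp_table() -> pd.DataFrame:
    """The published mitochondrial genotype matrix (16 samples x 8 SNPs)."""
    columns = [f"{c}:{p}" for c, p in MT_SNP_POSITIONS]
    return pd.DataFrame(
        [list(g) for g in _MT_GENOTYPES.values()],
        index=list(_MT_GENOTYPES),
        columns=columns,
    )


def mt_snp_positions() -> list[tuple[str, int]]:
    return list(MT_SNP_POSITIONS)


def mt_snp_genes() -> dict[tuple[str, int], str]:
    return dict(MT_SNP_GENES)


def population_roster() -> list[SampleRecord]:
    out = []
    for pop, _loc, samples, cp, m1, m2, m3 in _ROSTER:
        for i, s in enumerate(samples):
            out.append(
                SampleRecord(
                    s,
                    pop,
                    accessions={
                        "plastome": cp[i],
                        "chMt1": m1[i],
                        "chMt2": m2[i],
                        "chMt3": m3[i],
                    },
                )
            )
    return out


def population_map() -> dict[str, str]:
    return {r.sample_id: r.population_id for r in population_roster()}


def plastome_spectrum_percentages() -> dict[str, float]:
    return dict(PLASTOME_SPECTRUM_PERCENTAGES)


def plastome_totals() -> dict[str, int]:
    return dict(PLASTOME_TOTALS)


def plastome_hotspot_counts() -> dict[str, tuple[int, int]]:
    return dict(PLASTOME_HOTSPOT_COUNTS)
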