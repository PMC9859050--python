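"""Summary statistics of organellar variation.

Covers the substitution spectrum (the six unordered base-pair classes, two
transitions and four transversions), per-region variability under both
conventional metrics (share of all mutations, and mutations per bp of the
region), within-population polymorphism counts, and the overall
changes-per-bp density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .annotate import RegionInventory
from .variants import Variant

__all__ = [
    "SpectrumTable",
    "PAIR_CLASSES",
    "TRANSITIONS",
    "TRANSVERSIONS",
    "tstv_breakdown",
    "spectrum_counts_from_percentages",
    "per_region_summary",
    "per_population_counts",
    "changes_per_bp",
]

TRANSITIONS = ("A<->G", "C<->T")
TRANSVERSIONS = ("A<->C", "A<->T", "G<->C", "G<->T")
PAIR_CLASSES = TRANSITIONS + TRANSVERSIONS

_CLASS_OF = {
    frozenset(c.split("<->")): c for c in PAIR_CLASSES
}


@dataclass
class SpectrumTable:
    """Counts per substitution pair-class; multiallelic SNPs contribute one
    unit split equally across their alternative alleles' classes."""

    counts: dict[str, float] = field(
        default_factory=lambda: {c: 0.0 for c in PAIR_CLASSES}
    )

    @property
    def total(self) -> float:
        return sum(self.counts.values())

    @property
    def transitions(self) -> float:
        return sum(self.counts[c] for c in TRANSITIONS)

    @property
    def transversions(self) -> float:
        return sum(self.counts[c] for c in TRANSVERSIONS)

    @property
    def percentages(self) -> dict[str, float]:
        t = self.total
        return {c: (100.0 * v / t if t else 0.0) for c, v in self.counts.items()}

    def as_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {
                "pair_class": list(PAIR_CLASSES),
                "kind": ["transition"] * 2 + ["transversion"] * 4,
                "count": [self.counts[c] for c in PAIR_CLASSES],
                "percent": [pct[c] for c in PAIR_CLASSES],
            }
        )


def tstv_breakdown(variants: Sequence[Variant]) -> SpectrumTable:
    """Assign every SNP to its unordered substitution pair-class."""
    table = SpectrumTable()
    for v in variants:
        if v.vtype != "SNP":
            continue
        w = 1.0 / len(v.alt_alleles)
        for alt in v.alt_alleles:
            pair = frozenset((v.ref_allele, alt))
            if pair not in _CLASS_OF:
                raise ValueError(f"unclassifiable: {v.ref_allele}/{alt}")
            table.counts[_CLASS_OF[pair]] += w
    return table


def spectrum_counts_from_percentages(
    percentages: Mapping[str, float], total_snps: int, tol: float = 0.05
) -> dict[str, int]:
    """Reconstruct integer class counts from printed percentages.

    Each percentage times the SNP total must land within ``tol`` of an
    integer, and the reconstructed counts must sum to the total; otherwise
    the percentages are inconsistent and a ``ValueError`` is raised.
    """
    counts: dict[str, int] = {}
    for cls, pct in percentages.items():
        x = pct * total_snps / 100.0
        k = round(x)
        if abs(x - k) > tol:
            raise ValueError(f"inconsistent percentage for {cls}: {pct}")
        counts[cls] = int(k)
    if sum(counts.values()) != total_snps:
        raise ValueError(
            f"class counts sum to {sum(counts.values())}, expected {total_snps}"
        )
    return counts


def per_region_summary(
    variants: Sequence[Variant],
    inventory: RegionInventory | Sequence[RegionInventory] | pd.DataFrame,
    total_mutations: int | None = None,
) -> pd.DataFrame:
    """Per-region SNP/InDel counts with both variability metrics.

    ``share_of_total`` is (SNPs+InDels)/all mutations; ``per_bp_density``
    is (SNPs+InDels)/region length.  Regions split in two spans (a wrapped
    spacer on a circular genome) are aggregated under their single name.
    Rows are ranked by share, descending.
    """
    if isinstance(inventory, RegionInventory):
        inventories = [inventory]
    elif isinstance(inventory, pd.DataFrame):
        inventories = None
        regions = inventory
    else:
        inventories = list(inventory)
    if inventories is not None:
        regions = pd.DataFrame(
            [
                {"region_name": r.name, "region_class": r.rclass, "length": r.length}
                for inv in inventories
                for r in inv
            ]
        )
    regions = regions.groupby(["region_name", "region_class"], as_index=False)[
        "length"
    ].sum()

    counts = pd.DataFrame(
        [{"region_name": v.region_name, "vtype": v.vtype} for v in variants]
    )
    if len(counts):
        pivot = (
            counts.value_counts(["region_name", "vtype"])
            .unstack(fill_value=0)
            .reindex(columns=["SNP", "InDel"], fill_value=0)
        )
    else:
        pivot = pd.DataFrame(columns=["SNP", "InDel"])
    out = regions.merge(
        pivot.rename(columns={"SNP": "snp_count", "InDel": "indel_count"}),
        left_on="region_name",
        right_index=True,
        how="left",
    )
    for col in ("snp_count", "indel_count"):
        if col not in out:
            out[col] = 0
        out[col] = (
            pd.to_numeric(out[col], errors="coerce").fillna(0).astype(int)
        )
    total = total_mutations if total_mutations is not None else len(variants)
    mutations = out.snp_count + out.indel_count
    out["share_of_total"] = mutations / total if total else 0.0
    out["per_bp_density"] = mutations / out.length
    return out.sort_values(
        ["share_of_total", "region_name"], ascending=[False, True]
    ).reset_index(drop=True)


def per_population_counts(
    variants: Sequence[Variant], popmap: Mapping[str, str]
) -> pd.DataFrame:
    """Within-population polymorphism: a site/event counts for a population
    iff its members carry at least two distinct non-missing states there.

    Populations of a single sample cannot be polymorphic; they are counted
    as zero and flagged.
    """
    pops: dict[str, list[str]] = {}
    for sample, pop in popmap.items():
        pops.setdefault(pop, []).append(sample)
    rows = []
    for pop, members in pops.items():
        n_snp = n_indel = 0
        for v in variants:
            states = {
                v.alleles[m] for m in members if v.alleles.get(m, ".") != "."
            }
            if len(states) >= 2:
                if v.vtype == "SNP":
                    n_snp += 1
                else:
                    n_indel += 1
        rows.append(
            {
                "population": pop,
                "n_samples": len(members),
                "snp_polymorphisms": n_snp,
                "indel_polymorphisms": n_indel,
                "single_sample": len(members) == 1,
            }
        )
    return pd.DataFrame(rows).sort_values("population").reset_index(drop=True)


def changes_per_bp(total_mutations: int, dataset_length: int) -> float:
    """Overall mutation density; the length convention (full genome vs
    trimmed alignment) is the caller's explicit choice."""
    if dataset_length <= 0:
        raise ValueError("dataset length must be positive")
    return total_mutations / dataset_length
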