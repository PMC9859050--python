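"""SNP and InDel calling from a multiple sequence alignment.

SNPs are called per alignment column: any column with at least two distinct
canonical bases among the samples is a variant site; gaps, N and IUPAC
ambiguity codes are missing data and never called as alleles.

InDels are called as *events* (blocks): a maximal run of contiguous columns
sharing an identical per-sample gap/base pattern is one event, however long
— the "simple indel coding" convention, under which a 1 bp and a 300 bp
insertion each contribute a single mutational step.

Positions are projected onto a designated reference sample: the reference
position of an alignment column is the number of non-gap reference
characters at or before that column, so columns where the reference is
gapped map to the preceding reference base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .io import Alignment, Feature

__all__ = [
    "Variant",
    "call_snps",
    "call_indels",
    "call_variants",
    "project_to_reference",
    "trim_second_ir",
]

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class Variant:
    """One SNP (single column) or one coalesced InDel event (column block)."""

    vtype: str  # "SNP" | "InDel"
    columns: tuple[int, int]  # 1-based inclusive alignment column span
    ref_position: int  # on the reference sample; for InDels the last
    # reference base before the block (0 if the block opens the alignment)
    ref_allele: str  # SNP: majority base; InDel: majority state "+"/"-"
    alt_alleles: tuple[str, ...]
    alleles: dict[str, str] = field(default_factory=dict)  # sample -> state
    alt_count: int = 0
    ref_gapped: bool | None = None  # InDel: is the reference sample gapped?
    region_name: str = ""
    region_type: str = ""
    effect: str = ""

    @property
    def carriers(self) -> frozenset[str]:
        """Samples carrying a non-majority, non-missing state."""
        return frozenset(
            s for s, a in self.alleles.items() if a != "." and a != self.ref_allele
        )

    @property
    def anchor_position(self) -> int:
        """First reference base of the event (used for region lookup).

        For SNPs this is the site itself; for a block in which the
        reference has sequence (a deletion in other samples) it is the
        first deleted base; for a pure insertion it is the base preceding
        the insertion point.
        """
        if self.vtype == "SNP" or self.ref_gapped:
            return max(self.ref_position, 1)
        return self.ref_position + 1


def _reference_positions(alignment: "Alignment", reference_id: str) -> np.ndarray:
    """1-based reference position of every alignment column (gap -> preceding base)."""
    if reference_id not in alignment:
        raise ValueError(f"unknown reference: {reference_id}")
    ref = np.frombuffer(alignment[reference_id].encode("ascii"), dtype="S1")
    return np.cumsum(ref != b"-")


def project_to_reference(alignment: "Alignment", reference_id: str, column: int) -> int:
    """Map a 1-based alignment column onto the reference coordinate system."""
    if column < 1 or column > alignment.length:
        raise ValueError(f"out of range: column {column}")
    return int(_reference_positions(alignment, reference_id)[column - 1])


def trim_second_ir(
    alignment: "Alignment", ir_features: Sequence["Feature"], reference_id: str
) -> "Alignment":
    """Drop the alignment columns covering the later-starting inverted-repeat copy.

    Plastome alignments carry the IR twice; keeping both would double-count
    every variant inside it.  With no IR annotation the alignment is
    returned unchanged; a single IR feature is malformed ("unpaired IR").
    Gap columns are removed along with the repeat when their projected
    reference position falls inside it.
    """
    irs = [f for f in ir_features if f.ftype == "IR"]
    if not irs:
        return alignment
    if len(irs) != 2:
        raise ValueError("unpaired IR")
    second = max(irs, key=lambda f: f.start)
    refpos = _reference_positions(alignment, reference_id)
    keep = ~((refpos >= second.start) & (refpos <= second.end))
    return alignment.select_columns(keep)


def call_snps(
    alignment: "Alignment", reference_id: str, min_alt_count: int = 1
) -> list[Variant]:
    """Call one SNP per column with >=2 distinct canonical bases.

    Multiallelic columns yield a single variant carrying every alternative
    allele.  Alleles are counted against the majority base (ties broken in
    favour of the reference sample's base, then alphabetically); variants
    with fewer than ``min_alt_count`` non-majority samples are suppressed.
    """
    refpos = _reference_positions(alignment, reference_id)
    m = alignment.matrix()
    n = alignment.n_samples
    # fast pre-filter: map bases to codes, missing -> -1
    codes = np.full(m.shape, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        codes[m == b] = i
    valid = codes >= 0
    cmax = np.where(valid, codes, -1).max(axis=0)
    cmin = np.where(valid, codes, 4).min(axis=0)
    candidate = np.flatnonzero((cmax > cmin) & (cmax >= 0))

    ref_row = alignment.ids.index(reference_id)
    out: list[Variant] = []
    for c in candidate:
        col = codes[:, c]
        counts = np.bincount(col[col >= 0], minlength=4)
        top = counts.max()
        tied = [i for i in range(4) if counts[i] == top]
        if len(tied) > 1 and col[ref_row] in tied:
            major = int(col[ref_row])
        else:
            major = tied[0]
        alt = [i for i in range(4) if counts[i] > 0 and i != major]
        alt_count = int(counts[alt].sum())
        if alt_count < min_alt_count:
            continue
        base = "ACGT"
        alleles = {
            sid: (base[col[i]] if col[i] >= 0 else ".")
            for i, sid in enumerate(alignment.ids)
        }
        out.append(
            Variant(
                vtype="SNP",
                columns=(int(c) + 1, int(c) + 1),
                ref_position=int(refpos[c]),
                ref_allele=base[major],
                alt_alleles=tuple(base[i] for i in alt),
                alleles=alleles,
                alt_count=alt_count,
            )
        )
    return out


def call_indels(
    alignment: "Alignment", reference_id: str, min_alt_count: int = 1
) -> list[Variant]:
    """Group gap-containing columns into maximal identical-pattern blocks.

    Each block — a maximal run of contiguous columns whose per-sample
    gap/base pattern is identical — is one InDel event scored as
    presence ("-") / absence ("+") of the gap per sample.  A column gapped
    in every sample indicates a malformed alignment ("null column").
    """
    refpos = _reference_positions(alignment, reference_id)
    m = alignment.matrix()
    gap = m == b"-"
    if bool(gap.all(axis=0).any()):
        raise ValueError("null column")
    gapcols = np.flatnonzero(gap.any(axis=0))
    ref_row = alignment.ids.index(reference_id)

    out: list[Variant] = []
    i = 0
    while i < len(gapcols):
        c0 = gapcols[i]
        pattern = gap[:, c0]
        j = i + 1
        while (
            j < len(gapcols)
            and gapcols[j] == gapcols[j - 1] + 1
            and np.array_equal(gap[:, gapcols[j]], pattern)
        ):
            j += 1
        c1 = gapcols[j - 1]
        n_gapped = int(pattern.sum())
        major_gapped = n_gapped > len(pattern) - n_gapped
        major = "-" if major_gapped else "+"
        alt_count = int((pattern != major_gapped).sum())
        if alt_count >= min_alt_count:
            alleles = {
                sid: ("-" if pattern[k] else "+")
                for k, sid in enumerate(alignment.ids)
            }
            ref_gapped = bool(pattern[ref_row])
            # last reference base before the block
            ref_position = int(refpos[c0 - 1]) if c0 > 0 else 0
            out.append(
                Variant(
                    vtype="InDel",
                    columns=(int(c0) + 1, int(c1) + 1),
                    ref_position=ref_position,
                    ref_allele=major,
                    alt_alleles=("-" if major == "+" else "+",),
                    alleles=alleles,
                    alt_count=alt_count,
                    ref_gapped=ref_gapped,
                )
            )
        i = j
    return out


def call_variants(
    alignment: "Alignment", reference_id: str, min_alt_count: int = 1
) -> list[Variant]:
    """SNPs and InDel events together, sorted by alignment column."""
    snps = call_snps(alignment, reference_id, min_alt_count=min_alt_count)
    indels = call_indels(alignment, reference_id, min_alt_count=min_alt_count)
    return sorted(snps + indels, key=lambda v: v.columns)
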