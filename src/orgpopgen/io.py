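"""Readers and writers for the standard formats the pipeline touches.

Everything downstream of this module operates on in-memory domain types:
:class:`Alignment` (equal-length gapped sequences), :class:`Feature`
(1-based inclusive genome annotations), :class:`AnnotatedGenome`, sample
-> population maps, and variant tables.  All readers validate strictly and
raise :class:`ValueError` with a short diagnostic token rather than
silently coercing malformed input.

Coordinate convention: 1-based inclusive everywhere (the GFF3 convention),
including alignment columns.
"""

from __future__ import annotations

import csv
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
from Bio import SeqIO

from .variants import Variant

__all__ = [
    "Alignment",
    "AnnotatedGenome",
    "Feature",
    "SampleRecord",
    "read_alignment",
    "read_features",
    "write_features",
    "read_population_map",
    "write_population_map",
    "read_variant_table",
    "write_variant_table",
    "read_newick",
    "write_newick",
]

#: characters accepted in alignments: canonical bases, gap, and IUPAC
#: ambiguity codes (the latter are treated as missing data downstream).
ALIGNMENT_ALPHABET = frozenset("ACGTN-RYSWKMBDHV")

FEATURE_TYPES = frozenset({"gene", "CDS", "tRNA", "rRNA", "intron", "IR", "intergenic"})

# GFF3 feature types folded onto the internal vocabulary
_GFF_TYPE_MAP = {
    "gene": "gene",
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "intron": "intron",
    "inverted_repeat": "IR",
    "repeat_region": "IR",
    "IR": "IR",
    "intergenic": "intergenic",
    "intergenic_region": "intergenic",
}


@dataclass(frozen=True)
class Feature:
    """A typed annotation on the reference (1-based inclusive span)."""

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type: {self.ftype!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"malformed feature: {self.name} span {self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SampleRecord:
    """One sequenced individual and its population assignment."""

    sample_id: str
    population_id: str
    accessions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("empty sample_id")
        if not self.population_id:
            raise ValueError("empty population_id")


@dataclass
class AnnotatedGenome:
    """Reference sequence plus typed features."""

    name: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    circular: bool = False

    def __post_init__(self) -> None:
        self.sequence = _normalize(self.sequence)
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"malformed feature: {f.name} beyond sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


class Alignment:
    """Equal-length named gapped sequences, uppercased, with U folded to T.

    Row order is preserved from the input but never semantically relevant:
    all callers key on sample ids.
    """

    def __init__(self, ids: Sequence[str], rows: Sequence[str], normalize: bool = True):
        ids = list(ids)
        if len(ids) != len(rows):
            raise ValueError("ids/rows length mismatch")
        if not ids:
            raise ValueError("no records")
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample: {dup[0]}")
        rows = [(_normalize(r) if normalize else r) for r in rows]
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError("ragged alignment")
        bad = set("".join(rows)) - ALIGNMENT_ALPHABET
        if bad:
            raise ValueError(f"invalid character: {sorted(bad)[0]!r}")
        self.ids: tuple[str, ...] = tuple(ids)
        self._rows: dict[str, str] = dict(zip(ids, rows))
        self._matrix: np.ndarray | None = None

    # -- container protocol -------------------------------------------------
    @property
    def length(self) -> int:
        return len(next(iter(self._rows.values())))

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    def __getitem__(self, sample_id: str) -> str:
        return self._rows[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._rows

    def items(self):
        return ((i, self._rows[i]) for i in self.ids)

    def matrix(self) -> np.ndarray:
        """Byte matrix of shape (n_samples, length); rows follow ``self.ids``."""
        if self._matrix is None:
            self._matrix = np.frombuffer(
                "".join(self._rows[i] for i in self.ids).encode("ascii"), dtype="S1"
            ).reshape(self.n_samples, self.length)
        return self._matrix

    # -- derived alignments --------------------------------------------------
    def select_columns(self, keep: np.ndarray) -> "Alignment":
        """New alignment restricted to columns where ``keep`` (bool or index array) holds."""
        m = self.matrix()[:, keep]
        rows = [m[i].tobytes().decode("ascii") for i in range(self.n_samples)]
        return Alignment(self.ids, rows, normalize=False)

    def subset(self, ids: Sequence[str]) -> "Alignment":
        return Alignment(list(ids), [self._rows[i] for i in ids], normalize=False)

    def to_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for sid in self.ids:
                fh.write(f">{sid}\n")
                row = self._rows[sid]
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read a gapped multi-FASTA alignment.

    Raises ``ValueError`` on an empty file ("no records"), duplicated headers
    ("duplicate sample"), or unequal sequence lengths ("ragged alignment").
    """
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise ValueError("no records")
    return Alignment(ids, rows)


def _attr_name(attributes: str) -> str:
    fields = dict(
        kv.split("=", 1) for kv in attributes.strip().split(";") if "=" in kv
    )
    return fields.get("Name") or fields.get("ID") or ""


def read_features(path: str | Path) -> list[Feature]:
    """Read a GFF3 subset (seqid, type, start, end, strand, attributes).

    Feature names come from the ``Name`` (preferred) or ``ID`` attribute.
    Unknown feature types are skipped; the result is sorted by start.
    """
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed feature: expected 9 columns, got {len(cols)}")
            _, _, gtype, start, end, _, strand, _, attrs = cols
            if gtype not in _GFF_TYPE_MAP:
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand: {strand!r}")
            s, e = int(start), int(end)
            if e < s:
                raise ValueError(f"malformed feature: end {e} < start {s}")
            feats.append(
                Feature(_attr_name(attrs), _GFF_TYPE_MAP[gtype], s, e, strand)
            )
    feats.sort(key=lambda f: (f.start, f.end))
    return feats


_GFF_TYPE_OUT = {"gene": "gene", "CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                 "intron": "intron", "IR": "inverted_repeat",
                 "intergenic": "intergenic_region"}


def write_features(path: str | Path, features: Iterable[Feature], seqid: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in sorted(features, key=lambda f: (f.start, f.end)):
            fh.write(
                "\t".join(
                    [
                        seqid,
                        "orgpopgen",
                        _GFF_TYPE_OUT[f.ftype],
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"Name={f.name}",
                    ]
                )
                + "\n"
            )


def read_population_map(
    path: str | Path, samples: Iterable[str] | None = None
) -> dict[str, str]:
    """Read a 2+-column TSV mapping sample id -> population id.

    A header line is tolerated (detected by the literal first field
    ``sample`` or ``sample_id``).  When ``samples`` is given, every listed
    sample must be mapped, otherwise an "unmapped sample" error is raised.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError("malformed population map: need 2+ columns")
            if i == 0 and cols[0].lower() in ("sample", "sample_id"):
                continue
            mapping[cols[0]] = cols[1]
    if samples is not None:
        missing = [s for s in samples if s not in mapping]
        if missing:
            raise ValueError(f"unmapped sample: {missing[0]}")
    return mapping


def write_population_map(path: str | Path, mapping: Mapping[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation_id\n")
        for sid, pid in mapping.items():
            fh.write(f"{sid}\t{pid}\n")


# ---------------------------------------------------------------------------
# variant table (VCF-like TSV; one row per SNP or coalesced InDel event)
# ---------------------------------------------------------------------------

_VT_FIXED = [
    "ref_position",
    "columns",
    "type",
    "ref_allele",
    "alt_alleles",
    "ref_gapped",
    "region_name",
    "region_type",
    "effect",
]


def write_variant_table(
    path: str | Path, variants: Sequence[Variant], samples: Sequence[str] | None = None
) -> None:
    """Write variants as a TSV: fixed columns then one genotype column per sample.

    Row order is deterministic (by reference position, then column span).
    An empty variant list yields a header-only file.
    """
    if samples is None:
        seen: list[str] = []
        for v in variants:
            for s in v.alleles:
                if s not in seen:
                    seen.append(s)
        samples = seen
    variants = sorted(variants, key=lambda v: (v.ref_position, v.columns))
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_VT_FIXED + list(samples))
        for v in variants:
            cols = (
                str(v.columns[0])
                if v.columns[0] == v.columns[1]
                else f"{v.columns[0]}-{v.columns[1]}"
            )
            row = [
                v.ref_position,
                cols,
                v.vtype,
                v.ref_allele,
                ",".join(v.alt_alleles),
                {True: "1", False: "0", None: "."}[v.ref_gapped],
                v.region_name,
                v.region_type,
                v.effect,
            ]
            row += [v.alleles.get(s, ".") for s in samples]
            w.writerow(row)


def read_variant_table(path: str | Path) -> list[Variant]:
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header is None:
            raise ValueError("no records")
        if header[: len(_VT_FIXED)] != _VT_FIXED:
            raise ValueError("malformed variant table header")
        samples = header[len(_VT_FIXED) :]
        out: list[Variant] = []
        for row in r:
            fixed, geno = row[: len(_VT_FIXED)], row[len(_VT_FIXED) :]
            span = fixed[1].split("-")
            c0 = int(span[0])
            c1 = int(span[1]) if len(span) > 1 else c0
            alleles = {s: g for s, g in zip(samples, geno)}
            out.append(
                Variant(
                    vtype=fixed[2],
                    columns=(c0, c1),
                    ref_position=int(fixed[0]),
                    ref_allele=fixed[3],
                    alt_alleles=tuple(a for a in fixed[4].split(",") if a),
                    alleles=alleles,
                    alt_count=sum(
                        1 for g in alleles.values() if g != fixed[3] and g != "."
                    ),
                    ref_gapped={"1": True, "0": False, ".": None}[fixed[5]],
                    region_name=fixed[6],
                    region_type=fixed[7],
                    effect=fixed[8],
                )
            )
    return out


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a newick string or file into a tree.

    Branch lengths and internal-node labels (bootstrap supports) are
    preserved; underscores in labels are taken literally.
    """
    text = str(source)
    if "(" not in text:
        text = Path(source).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error classes
        raise ValueError(f"parse error: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    s = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    ).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s
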