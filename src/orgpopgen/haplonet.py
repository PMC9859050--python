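"""Haplotype collapsing, indel-block distances and randomized-MST networks.

Individuals sharing an identical state at every variant character (SNP
alleles plus InDel block presence/absence) form one haplotype.  Pairwise
distances follow the simple indel coding convention: substitutions count
per differing site, and each maximal gap block present in exactly one of
the two sequences counts once regardless of its length.

The haplotype network is the union of minimum spanning trees obtained
under repeated random tie-breaking of equal-weight edges (randomized MST).
An edge's support is the fraction of iterations whose MST contained it;
edges with support below 1 are "alternative pathways" in the genealogy.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
from networkx.utils import UnionFind

from .variants import Variant

__all__ = [
    "DistanceMatrix",
    "Haplotype",
    "collapse_haplotypes",
    "character_matrix",
    "character_distance",
    "gap_blocks",
    "indelblock_distance",
    "distance_matrix",
    "rmst_network",
    "mst_union_oracle",
]


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative distances with labelled rows."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.values < 0):
            raise ValueError("negative distance")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


@dataclass(frozen=True)
class Haplotype:
    """A distinct multi-site state, labelled by its first member."""

    label: str
    members: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.members)


def collapse_haplotypes(characters: Mapping[str, str]) -> list[Haplotype]:
    """Group samples with identical character strings; first-seen order."""
    lengths = {len(s) for s in characters.values()}
    if len(lengths) > 1:
        raise ValueError("ragged character matrix")
    groups: dict[str, list[str]] = {}
    for sample, chars in characters.items():
        groups.setdefault(chars, []).append(sample)
    return [Haplotype(members[0], tuple(members)) for members in groups.values()]


def character_matrix(
    variants: Sequence[Variant], samples: Sequence[str]
) -> dict[str, str]:
    """Per-sample string over all variant characters (SNP base, InDel +/-)."""
    ordered = sorted(variants, key=lambda v: (v.columns, v.vtype))
    return {
        s: "".join(v.alleles.get(s, ".") for v in ordered) for s in samples
    }


def character_distance(a: str, b: str) -> int:
    """Differing characters over an event-coded matrix ('.' is missing).

    On strings from :func:`character_matrix` — one character per SNP site
    or InDel *block* — this is exactly the indel-block distance: each
    differing SNP state and each differing block presence counts one step.
    """
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    return sum(1 for x, y in zip(a, b) if x != "." and y != "." and x != y)


def gap_blocks(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as 0-based half-open (start, end) spans."""
    blocks = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-" and start is None:
            start = i
        elif ch != "-" and start is not None:
            blocks.append((start, i))
            start = None
    if start is not None:
        blocks.append((start, len(seq)))
    return blocks


def indelblock_distance(a: str, b: str) -> int:
    """Substitution count plus the number of gap blocks private to one sequence.

    A gap block shared with an identical span contributes nothing; any
    block, however long, contributes one step.  Sites where either
    sequence is gapped do not count as substitutions.
    """
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    subs = sum(
        1 for x, y in zip(a, b) if x != "-" and y != "-" and x != y
    )
    blocks_a, blocks_b = set(gap_blocks(a)), set(gap_blocks(b))
    return subs + len(blocks_a ^ blocks_b)


def distance_matrix(
    sequences: Mapping[str, str],
    metric: Callable[[str, str], float] = indelblock_distance,
) -> DistanceMatrix:
    labels = tuple(sequences)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = metric(sequences[labels[i]], sequences[labels[j]])
    return DistanceMatrix(labels, d)


def _kruskal(
    edges: list[tuple[float, int, int]], n: int, rng: np.random.Generator
) -> frozenset[tuple[int, int]]:
    """One MST under a random permutation of equal-weight edges."""
    order = rng.permutation(len(edges))
    shuffled = [edges[k] for k in order]
    shuffled.sort(key=lambda e: e[0])  # stable: random order within ties
    uf = UnionFind(range(n))
    chosen = []
    for w, i, j in shuffled:
        if uf[i] != uf[j]:
            uf.union(i, j)
            chosen.append((i, j) if i < j else (j, i))
            if len(chosen) == n - 1:
                break
    return frozenset(chosen)


def rmst_network(
    dmat: DistanceMatrix,
    iterations: int = 200,
    seed: int | None = None,
    haplotypes: Sequence[Haplotype] | None = None,
    popmap: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Randomized minimum-spanning-tree haplotype network.

    Runs Kruskal ``iterations`` times with equal-weight edges processed in
    random order and returns the union graph.  Edge attributes: ``weight``
    (the distance), ``support`` (inclusion fraction over iterations) and
    ``alternative`` (present in some but not all iterations).  Node
    attributes carry member samples, size and per-population composition
    when haplotypes/popmap are supplied.
    """
    labels = dmat.labels
    n = len(labels)
    g = nx.Graph()
    by_label = {h.label: h for h in (haplotypes or [])}
    for lab in labels:
        h = by_label.get(lab)
        members = h.members if h else (lab,)
        attrs = {"members": list(members), "size": len(members)}
        if popmap is not None:
            attrs["populations"] = dict(Counter(popmap[m] for m in members))
        g.add_node(lab, **attrs)
    if n < 2:
        return g
    rng = np.random.default_rng(seed)
    edges = [
        (float(dmat.values[i, j]), i, j)
        for i, j in itertools.combinations(range(n), 2)
    ]
    hits: Counter = Counter()
    for _ in range(iterations):
        for e in _kruskal(edges, n, rng):
            hits[e] += 1
    for (i, j), c in sorted(hits.items()):
        support = c / iterations
        g.add_edge(
            labels[i],
            labels[j],
            weight=float(dmat.values[i, j]),
            support=support,
            alternative=support < 1.0,
        )
    return g


def mst_union_oracle(dmat: DistanceMatrix) -> set[frozenset]:
    """Union of *all* minimum spanning trees, by exhaustive enumeration.

    Spanning trees are enumerated in increasing total weight; enumeration
    stops once the weight exceeds the minimum.  Restricted to at most 8
    nodes to keep the enumeration a test-scale oracle.
    """
    n = len(dmat)
    if n > 8:
        raise ValueError("oracle refused: more than 8 nodes")
    g = nx.Graph()
    for i, j in itertools.combinations(range(n), 2):
        g.add_edge(i, j, weight=float(dmat.values[i, j]))
    union: set[frozenset] = set()
    best: float | None = None
    for tree in nx.SpanningTreeIterator(g, weight="weight", minimum=True):
        w = tree.size(weight="weight")
        if best is None:
            best = w
        if w > best + 1e-12:
            break
        union.update(
            frozenset((dmat.labels[u], dmat.labels[v])) for u, v in tree.edges
        )
    return union
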