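"""Distance-based phylogenetics with JC/HKY substitution models.

Neighbor-joining (Saitou-Nei Q-criterion) with deterministic tie-breaking,
column-bootstrap supports mapped onto the full-data tree's bipartitions,
Felsenstein pruning likelihoods under Jukes-Cantor and
Hasegawa-Kishino-Yano rate matrices, AIC model selection, outgroup
rooting, and Robinson-Foulds tree comparison.

Trees are :class:`dendropy.Tree` objects throughout; bootstrap supports
are stored as internal-node labels (percentages).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .haplonet import DistanceMatrix
from .io import Alignment

__all__ = [
    "SubstitutionModel",
    "ModelFit",
    "ModelSelection",
    "jc_distance",
    "hky_distance",
    "pairwise_counts",
    "alignment_distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "pruning_loglik",
    "select_model",
    "root_with_outgroup",
    "compare_trees",
    "bipartitions",
    "evolve_alignment",
    "random_tree",
    "tree_distance_matrix",
]

_BASE_ORDER = "ACGT"
_PURINES = (0, 2)  # A, G


@dataclass
class SubstitutionModel:
    """A nucleotide substitution model (JC or HKY).

    ``kappa`` is the transition/transversion *rate* ratio; base
    frequencies are in ACGT order and sum to 1.  The rate matrix is
    normalized to one expected substitution per unit branch length.
    """

    name: str
    kappa: float = 1.0
    freqs: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.name not in ("JC", "HKY"):
            raise ValueError(f"unknown model: {self.name}")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if abs(self.freqs.sum() - 1.0) > 1e-8 or np.any(self.freqs < 0):
            raise ValueError("frequencies must be a distribution")

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        return cls("JC")

    @classmethod
    def hky(cls, kappa: float, freqs: Sequence[float]) -> "SubstitutionModel":
        return cls("HKY", kappa=kappa, freqs=np.asarray(freqs, dtype=float))

    @property
    def n_free_params(self) -> int:
        return 0 if self.name == "JC" else 4  # kappa + 3 free frequencies

    def rate_matrix(self) -> np.ndarray:
        pi = self.freqs
        q = np.empty((4, 4))
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                transition = (i in _PURINES) == (j in _PURINES)
                q[i, j] = pi[j] * (self.kappa if transition else 1.0)
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        if not math.isfinite(t) or t < 0:
            raise ValueError(f"nonfinite branch length: {t}")
        return expm(self.rate_matrix() * t)


# ---------------------------------------------------------------------------
# pairwise distances
# ---------------------------------------------------------------------------


def jc_distance(p: float) -> float:
    """Jukes-Cantor correction -(3/4) ln(1 - 4p/3) of a raw mismatch proportion."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise ValueError("saturated")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class PairCounts:
    """Site-pattern summary of one gap-free pairwise comparison."""

    n: int  # compared sites (both bases canonical)
    p_ag: float  # proportion of A<->G transitions
    p_ct: float  # proportion of C<->T transitions
    q: float  # proportion of transversions
    freqs: tuple[float, float, float, float]  # ACGT, pooled over the pair


def _encode_codes(alignment: Alignment) -> np.ndarray:
    """int8 matrix in alignment row order: A,C,G,T -> 0..3, anything else -1."""
    m = alignment.matrix()
    codes = np.full(m.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[m == bytes([b])] = i
    return codes


def _pair_counts_from_codes(ci: np.ndarray, cj: np.ndarray) -> PairCounts:
    valid = (ci >= 0) & (cj >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable sites")
    a, b = ci[valid], cj[valid]
    diff = a != b
    # transition iff both purines (0,2) or both pyrimidines (1,3)
    purine_a, purine_b = (a % 2 == 0), (b % 2 == 0)
    ts = diff & (purine_a == purine_b)
    ag = int((ts & purine_a).sum())
    ct = int((ts & ~purine_a).sum())
    tv = int(diff.sum()) - ag - ct
    base_counts = np.bincount(a, minlength=4) + np.bincount(b, minlength=4)
    return PairCounts(
        n=n,
        p_ag=ag / n,
        p_ct=ct / n,
        q=tv / n,
        freqs=tuple(base_counts / base_counts.sum()),
    )


def pairwise_counts(a: str, b: str) -> PairCounts:
    if len(a) != len(b):
        raise ValueError("unequal lengths")
    pair = Alignment(["a", "b"], [a, b], normalize=False)
    codes = _encode_codes(pair)
    return _pair_counts_from_codes(codes[0], codes[1])


def hky_distance(counts: PairCounts) -> float:
    """Model-corrected distance for transition-biased, unequal-frequency data.

    This is the closed-form distance of the TN93 family evaluated at the
    single-kappa (HKY) constraint; with equal frequencies and
    JC-proportioned mismatches it reduces to the Jukes-Cantor distance.
    """
    pa, pc, pg, pt = counts.freqs
    g_r, g_y = pa + pg, pc + pt
    if min(pa, pc, pg, pt) <= 0:
        # degenerate composition: fall back to the JC correction
        return jc_distance(counts.p_ag + counts.p_ct + counts.q)
    k1 = 2 * pa * pg / g_r
    k2 = 2 * pc * pt / g_y
    k3 = 2 * (g_r * g_y - pa * pg * g_y / g_r - pc * pt * g_r / g_y)
    w1 = 1 - counts.p_ag / k1 - counts.q / (2 * g_r)
    w2 = 1 - counts.p_ct / k2 - counts.q / (2 * g_y)
    w3 = 1 - counts.q / (2 * g_r * g_y)
    if min(w1, w2, w3) <= 0:
        raise ValueError("saturated")
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def alignment_distance_matrix(
    alignment: Alignment, model: str = "JC", _codes: np.ndarray | None = None
) -> DistanceMatrix:
    """Pairwise distances under ``model`` in {"p", "JC", "HKY"}.

    Gaps and ambiguity codes are excluded pairwise (pairwise deletion).
    """
    labels = alignment.ids
    codes = _encode_codes(alignment) if _codes is None else _codes
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        counts = _pair_counts_from_codes(codes[i], codes[j])
        p = counts.p_ag + counts.p_ct + counts.q
        if model == "p":
            dist = p
        elif model == "JC":
            dist = jc_distance(p)
        elif model == "HKY":
            dist = hky_distance(counts)
        else:
            raise ValueError(f"unknown distance model: {model}")
        d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


def nj_tree(dmat: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining.

    Ties in the Q-criterion are broken deterministically by the smallest
    leaf label contained in each candidate cluster.  A negative branch
    length is clamped to zero with the deficit moved to its sister branch
    (their sum, the joined pair's distance, is preserved); the result is
    unrooted (trifurcating seed node).
    """
    n = len(dmat)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    ns = dendropy.TaxonNamespace(list(dmat.labels))
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in dmat.labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(node)
    minlab = list(dmat.labels)  # smallest leaf label per active cluster
    d = dmat.values.astype(float).copy()
    active = list(range(n))

    def join(i: int, j: int) -> int:
        """Join active clusters i and j; return the new cluster's index."""
        nonlocal d
        m = len(active)
        di = d[i, :].copy()
        dj = d[j, :].copy()
        dij = d[i, j]
        ri = di[active].sum()
        rj = dj[active].sum()
        li = 0.5 * dij + (ri - rj) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        nodes.append(parent)
        minlab.append(min(minlab[i], minlab[j]))
        new = np.zeros(d.shape[0] + 1)
        newd = np.zeros((d.shape[0] + 1, d.shape[0] + 1))
        newd[:-1, :-1] = d
        for k in active:
            if k in (i, j):
                continue
            new[k] = 0.5 * (di[k] + dj[k] - dij)
        newd[-1, :-1] = new[:-1]
        newd[:-1, -1] = new[:-1]
        d = newd
        active.remove(i)
        active.remove(j)
        active.append(d.shape[0] - 1)
        return d.shape[0] - 1

    while len(active) > 3:
        m = len(active)
        r = {i: d[i, active].sum() for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            qv = (m - 2) * d[i, j] - r[i] - r[j]
            lab = tuple(sorted((minlab[i], minlab[j])))
            key = (qv, lab)
            if best is None or key < best[0]:
                best = (key, i, j)
        join(best[1], best[2])

    # final trifurcation: three-point formulas
    a, b, c = sorted(active, key=lambda i: minlab[i])
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for idx, length in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(length, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# bipartitions, bootstrap, comparison
# ---------------------------------------------------------------------------


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(l.taxon.label for l in tree.leaf_node_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalized to the side not
    containing the alphabetically first leaf."""
    leaves = leaf_labels(tree)
    first = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        out.add(side if first not in side else leaves - side)
    return out


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 1000,
    model: str = "JC",
    seed: int | None = None,
    tree: dendropy.Tree | None = None,
    distance_fn: Callable[[Alignment], DistanceMatrix] | None = None,
) -> tuple[dendropy.Tree, dict[frozenset[str], float]]:
    """Column bootstrap: supports of the full-data NJ tree's bipartitions.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    alignment is rebuilt into an NJ tree and the support of a bipartition
    is the percentage of replicate trees containing it.  Supports are
    written onto the internal-node labels of the returned tree.
    """
    codes = _encode_codes(alignment)
    if distance_fn is None:
        dist = lambda a, c=None: alignment_distance_matrix(a, model=model, _codes=c)
    else:
        dist = lambda a, c=None: distance_fn(a)
    if tree is None:
        tree = nj_tree(dist(alignment, codes))
    target = bipartitions(tree)
    rng = np.random.default_rng(seed)
    counts = {bp: 0 for bp in target}
    for _ in range(n_reps):
        cols = rng.integers(0, alignment.length, alignment.length)
        if distance_fn is None:
            rep, rep_codes = alignment, codes[:, cols]
        else:
            rep, rep_codes = alignment.select_columns(cols), None
        try:
            rep_tree = nj_tree(dist(rep, rep_codes))
        except ValueError:  # saturated replicate distances: skip it
            continue
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / n_reps for bp, c in counts.items()}
    leaves = leaf_labels(tree)
    first = min(leaves)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(side) > len(leaves) - 2:
            continue
        canon = side if first not in side else leaves - side
        node.label = f"{supports[canon]:.0f}"
    return tree, supports


def root_with_outgroup(tree: dendropy.Tree, leaf: str) -> dendropy.Tree:
    """Root on the midpoint of the outgroup's pendant edge (in place)."""
    node = tree.find_node_with_taxon_label(leaf)
    if node is None:
        raise ValueError(f"unknown leaf: {leaf}")
    el = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=el / 2.0, length2=el / 2.0)
    tree.is_rooted = True
    return tree


def compare_trees(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[int, pd.DataFrame]:
    """Robinson-Foulds distance plus the leaf association table used for
    tanglegram-style side-by-side comparison."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise ValueError("leaf-set mismatch")
    rf = len(bipartitions(t1) ^ bipartitions(t2))
    assoc = pd.DataFrame({"left": sorted(l1), "right": sorted(l1)})
    return rf, assoc


# ---------------------------------------------------------------------------
# likelihood, model selection
# ---------------------------------------------------------------------------


def _encode(alignment: Alignment) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Site-pattern compression: (patterns [npat x n], weights, sample ids)."""
    m = alignment.matrix()
    codes = np.full(m.shape, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        codes[m == bytes([b])] = i
    patterns, weights = np.unique(codes.T, axis=0, return_counts=True)
    return patterns.T, weights.astype(float), list(alignment.ids)


def pruning_loglik(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    scale: float = 1.0,
    _encoded=None,
) -> float:
    """Felsenstein pruning log-likelihood.

    Gap and ambiguous states are missing data at the tips (partial
    likelihood 1 for every base).  The root prior is the model's
    stationary distribution, so the value is invariant to the placement of
    the root of an unrooted tree (pulley principle).
    """
    patterns, weights, ids = _encoded or _encode(alignment)
    npat = patterns.shape[1]
    idx = {sid: k for k, sid in enumerate(ids)}
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            states = patterns[idx[node.taxon.label]]
            part = np.zeros((npat, 4))
            part[states < 0] = 1.0
            seen = states >= 0
            part[np.flatnonzero(seen), states[seen]] = 1.0
        else:
            part = np.ones((npat, 4))
            for child in node.child_nodes():
                t = child.edge.length
                if t is None or not math.isfinite(t):
                    raise ValueError(f"nonfinite branch length: {t}")
                pmat = model.transition_matrix(t * scale)
                part = part * (partials.pop(id(child)) @ pmat.T)
        partials[id(node)] = part
    root_part = partials[id(tree.seed_node)]
    site_lik = root_part @ model.freqs
    if np.any(site_lik <= 0):
        return -math.inf
    return float(weights @ np.log(site_lik))


@dataclass
class ModelFit:
    model: SubstitutionModel
    loglik: float
    scale: float
    aic: float
    converged: bool = True


@dataclass
class ModelSelection:
    best: ModelFit
    fits: dict[str, ModelFit]

    @property
    def name(self) -> str:
        return self.best.model.name


def _empirical_freqs(alignment: Alignment) -> np.ndarray:
    m = alignment.matrix()
    counts = np.array([(m == b).sum() for b in (b"A", b"C", b"G", b"T")], dtype=float)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


def select_model(
    alignment: Alignment,
    tree: dendropy.Tree | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ModelSelection:
    """Choose between JC and HKY by AIC on a fixed NJ topology.

    Branch lengths are rescaled by one global maximum-likelihood factor per
    model; HKY additionally optimizes kappa and the base frequencies
    (initialized at the empirical composition).  AIC = 2k - 2 logL with
    k=0 for JC and k=4 for HKY (kappa plus three free frequencies), so the
    models are properly nested and logL(HKY) >= logL(JC) at the optima.
    """
    if tree is None:
        tree = nj_tree(alignment_distance_matrix(alignment, model="JC"))
    encoded = _encode(alignment)

    def fit_scale(model: SubstitutionModel) -> tuple[float, float]:
        res = minimize_scalar(
            lambda s: -pruning_loglik(tree, alignment, model, scale=s, _encoded=encoded),
            bounds=(1e-4, 100.0),
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        return float(res.x), -float(res.fun)

    jc_model = SubstitutionModel.jc()
    jc_scale, jc_loglik = fit_scale(jc_model)
    jc_fit = ModelFit(jc_model, jc_loglik, jc_scale, aic=-2 * jc_loglik)

    # HKY: maximize over (log kappa, frequency logits, log scale)
    def unpack(x: np.ndarray) -> tuple[SubstitutionModel, float]:
        kappa = math.exp(x[0])
        logits = np.concatenate([x[1:4], [0.0]])
        freqs = np.exp(logits - logits.max())
        freqs = freqs / freqs.sum()
        return SubstitutionModel.hky(kappa, freqs), math.exp(x[4])

    def neg(x: np.ndarray) -> float:
        model, s = unpack(x)
        return -pruning_loglik(tree, alignment, model, scale=s, _encoded=encoded)

    emp = np.clip(_empirical_freqs(alignment), 1e-6, None)
    starts = [
        np.array(
            [math.log(2.0), *np.log(emp[:3] / emp[3]), math.log(jc_scale)]
        ),
        np.array([0.0, 0.0, 0.0, 0.0, math.log(jc_scale)]),  # the JC point
    ]
    best_res = None
    for x0 in starts:
        res = minimize(
            neg, x0, method="L-BFGS-B", options={"maxiter": max_iter, "ftol": tol * 1e-3}
        )
        if best_res is None or res.fun < best_res.fun:
            best_res = res
    hky_model, hky_scale = unpack(best_res.x)
    hky_loglik = -float(best_res.fun)
    if hky_loglik < jc_loglik:  # the JC point is in the HKY family
        hky_loglik = jc_loglik
        hky_model, hky_scale = SubstitutionModel.hky(1.0, np.full(4, 0.25)), jc_scale
    hky_fit = ModelFit(
        hky_model,
        hky_loglik,
        hky_scale,
        aic=2 * 4 - 2 * hky_loglik,
        converged=bool(best_res.success),
    )
    fits = {"JC": jc_fit, "HKY": hky_fit}
    best = min(fits.values(), key=lambda f: f.aic)
    return ModelSelection(best=best, fits=fits)


# ---------------------------------------------------------------------------
# simulation utilities (test oracles and parameter-recovery checks)
# ---------------------------------------------------------------------------


def evolve_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed: int | None = None,
) -> Alignment:
    """Simulate sequences down a tree under the model (root at stationarity)."""
    rng = np.random.default_rng(seed)
    states: dict[int, np.ndarray] = {
        id(tree.seed_node): rng.choice(4, size=n_sites, p=model.freqs)
    }
    rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            pmat = model.transition_matrix(node.edge.length or 0.0)
            cum = pmat.cumsum(axis=1)
            parent_states = states[id(node.parent_node)]
            u = rng.random(n_sites)
            child = np.empty(n_sites, dtype=np.int64)
            for s in range(4):
                sel = parent_states == s
                child[sel] = np.searchsorted(cum[s], u[sel], side="right")
            states[id(node)] = np.minimum(child, 3)
        if node.is_leaf():
            rows[node.taxon.label] = "".join(
                _BASE_ORDER[k] for k in states[id(node)]
            )
    ids = sorted(rows)
    return Alignment(ids, [rows[i] for i in ids], normalize=False)


def random_tree(
    labels: Sequence[str],
    seed: int | None = None,
    min_bl: float = 0.1,
    max_bl: float = 1.0,
) -> dendropy.Tree:
    """Random unrooted binary topology with uniform branch lengths."""
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    ns = dendropy.TaxonNamespace(list(labels))
    subtrees = []
    for lab in labels:
        node = dendropy.Node(taxon=ns.get_taxon(lab))
        subtrees.append(node)
    while len(subtrees) > 3:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        parent = dendropy.Node()
        for k in (i, j):
            parent.add_child(subtrees[k])
            subtrees[k].edge.length = float(rng.uniform(min_bl, max_bl))
        subtrees = [s for k, s in enumerate(subtrees) if k not in (i, j)]
        subtrees.append(parent)
    center = dendropy.Node()
    for s in subtrees:
        center.add_child(s)
        s.edge.length = float(rng.uniform(min_bl, max_bl))
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path distances (an additive matrix by construction)."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = tuple(sorted(leaf_labels(tree)))
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)
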