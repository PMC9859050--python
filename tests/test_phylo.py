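import math

import dendropy
import numpy as np
import pytest

from orgpopgen.haplonet import DistanceMatrix
from orgpopgen.io import Alignment, read_newick, write_newick
from orgpopgen.phylo import (
    PairCounts,
    SubstitutionModel,
    alignment_distance_matrix,
    bipartitions,
    bootstrap_support,
    compare_trees,
    evolve_alignment,
    hky_distance,
    jc_distance,
    nj_tree,
    pairwise_counts,
    pruning_loglik,
    random_tree,
    root_with_outgroup,
    select_model,
    tree_distance_matrix,
)


class TestJcDistance:
    def test_zero(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        # independent evaluation of -(3/4) ln(1 - 4p/3)
        assert jc_distance(0.01) == pytest.approx(0.010067, abs=1e-6)

    def test_monotone(self):
        xs = [jc_distance(p) for p in np.linspace(0, 0.7, 50)]
        assert all(b > a for a, b in zip(xs, xs[1:]))

    def test_saturated(self):
        with pytest.raises(ValueError, match="saturated"):
            jc_distance(0.75)


class TestHkyDistance:
    def test_identical_pair(self):
        c = PairCounts(100, 0.0, 0.0, 0.0, (0.25, 0.25, 0.25, 0.25))
        assert hky_distance(c) == 0.0

    def test_reduces_to_jc_under_equal_frequencies(self):
        for p in (0.03, 0.12, 0.3):
            c = PairCounts(600, p / 6, p / 6, 4 * p / 6, (0.25,) * 4)
            assert hky_distance(c) == pytest.approx(jc_distance(p), abs=1e-10)

    def test_recovers_generating_branch_length(self):
        model = SubstitutionModel.hky(4.0, [0.3, 0.2, 0.2, 0.3])
        two = dendropy.Tree.get(data="(A:0.05,B:0.05);", schema="newick")
        aln = evolve_alignment(two, model, 10_000, seed=11)
        d = hky_distance(pairwise_counts(aln["A"], aln["B"]))
        assert d == pytest.approx(0.1, rel=0.10)

    def test_saturated(self):
        c = PairCounts(100, 0.3, 0.3, 0.4, (0.25,) * 4)
        with pytest.raises(ValueError, match="saturated"):
            hky_distance(c)


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = nj_tree(DistanceMatrix(("A", "B", "C"), d))
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]], float)))

    def test_recovers_known_quartet(self):
        # ((A:1,B:2):1,(C:3,D:1)) as an additive matrix
        t = read_newick("((A:1,B:2):1,(C:3,D:1));")
        dm = tree_distance_matrix(t)
        rec = nj_tree(dm)
        assert bipartitions(rec) == {frozenset({"C", "D"})} or bipartitions(rec) == {
            frozenset({"A", "B"})
        }
        assert np.allclose(tree_distance_matrix(rec).values, dm.values, atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_matrix_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        truth = random_tree([f"t{i}" for i in range(n)], seed=seed + 500)
        dm = tree_distance_matrix(truth)
        rec = nj_tree(dm)
        assert bipartitions(rec) == bipartitions(truth)
        assert np.allclose(tree_distance_matrix(rec).values, dm.values, atol=1e-8)

    def test_negative_branch_clamped(self):
        # a slightly non-additive matrix that drives one NJ branch negative
        d = np.array(
            [[0, 0.1, 0.5, 0.5], [0.1, 0, 0.45, 0.45], [0.5, 0.45, 0, 0.05],
             [0.5, 0.45, 0.05, 0]],
        )
        tree = nj_tree(DistanceMatrix(("A", "B", "C", "D"), d))
        for e in tree.preorder_edge_iter():
            if e.length is not None:
                assert e.length >= 0


class TestBootstrap:
    def _blocks_alignment(self):
        # every variable column supports the same split {A,B} | {C,D}
        rows = {
            "A": "A" * 20,
            "B": "A" * 20,
            "C": "C" * 20,
            "D": "C" * 20,
        }
        constant = "G" * 100
        return Alignment(list(rows), [v + constant for v in rows.values()])

    def test_compatible_signal_full_support(self):
        tree, supports = bootstrap_support(
            self._blocks_alignment(), n_reps=100, seed=0
        )
        assert supports[frozenset({"C", "D"})] == 100.0

    def test_supports_bounded_and_deterministic(self, plastome_truth):
        _, truth = plastome_truth
        sub = truth.alignment.subset(list(truth.alignment.ids)[:8])
        _, s1 = bootstrap_support(sub, n_reps=50, seed=9)
        _, s2 = bootstrap_support(sub, n_reps=50, seed=9)
        assert s1 == s2
        assert all(0.0 <= v <= 100.0 for v in s1.values())

    def test_supports_survive_newick_roundtrip(self):
        tree, supports = bootstrap_support(
            self._blocks_alignment(), n_reps=20, seed=1
        )
        back = read_newick(write_newick(tree))
        labels = [
            n.label for n in back.preorder_node_iter() if not n.is_leaf() and n.label
        ]
        assert "100" in labels


class TestPruningLoglik:
    def test_star_tree_identical_sequences_closed_form(self):
        tree = dendropy.Tree.get(data="(A:0,B:0,C:0);", schema="newick")
        aln = Alignment(["A", "B", "C"], ["ACGT", "ACGT", "ACGT"])
        model = SubstitutionModel.hky(2.0, [0.4, 0.1, 0.2, 0.3])
        expected = sum(math.log(f) for f in (0.4, 0.1, 0.2, 0.3))
        assert pruning_loglik(tree, aln, model) == pytest.approx(expected, abs=1e-10)

    def test_two_taxon_jc_closed_form(self):
        t = 0.17
        tree = dendropy.Tree.get(data=f"(A:{t / 2},B:{t / 2});", schema="newick")
        aln = evolve_alignment(tree, SubstitutionModel.jc(), 2000, seed=3)
        ll = pruning_loglik(tree, aln, SubstitutionModel.jc())
        same = sum(1 for x, y in zip(aln["A"], aln["B"]) if x == y)
        diff = 2000 - same
        p_same = 0.25 + 0.75 * math.exp(-4 * t / 3)
        p_diff = 0.25 * (1 - math.exp(-4 * t / 3))
        closed = same * math.log(0.25 * p_same) + diff * math.log(0.25 * p_diff)
        assert ll == pytest.approx(closed, abs=1e-8)

    @pytest.mark.parametrize("seed", range(3))
    def test_reroot_invariance(self, seed):
        truth = random_tree([f"x{i}" for i in range(6)], seed=seed)
        model = SubstitutionModel.hky(3.0, [0.3, 0.2, 0.3, 0.2])
        aln = evolve_alignment(truth, model, 300, seed=seed + 50)
        base = pruning_loglik(truth, aln, model)
        for leaf in ("x0", "x3"):
            clone = truth.clone(depth=1)
            root_with_outgroup(clone, leaf)
            assert pruning_loglik(clone, aln, model) == pytest.approx(base, abs=1e-8)

    def test_missing_data_at_tips(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        aln = Alignment(["A", "B"], ["ACG-", "ACGN"])
        ll = pruning_loglik(tree, aln, SubstitutionModel.jc())
        # the all-missing column contributes log(1) = 0
        aln3 = Alignment(["A", "B"], ["ACG", "ACG"])
        assert ll == pytest.approx(pruning_loglik(tree, aln3, SubstitutionModel.jc()))

    def test_nonfinite_branch_rejected(self):
        tree = dendropy.Tree.get(data="(A:0.1,B:0.1);", schema="newick")
        tree.leaf_nodes()[0].edge.length = math.nan
        aln = Alignment(["A", "B"], ["ACG", "ACG"])
        with pytest.raises(ValueError, match="nonfinite"):
            pruning_loglik(tree, aln, SubstitutionModel.jc())


class TestModelSelection:
    def test_hky_never_worse_than_jc(self):
        tr = random_tree([f"s{i}" for i in range(5)], seed=1, min_bl=0.02, max_bl=0.2)
        aln = evolve_alignment(tr, SubstitutionModel.jc(), 1500, seed=2)
        sel = select_model(aln)
        assert sel.fits["HKY"].loglik >= sel.fits["JC"].loglik - 1e-6

    def test_recovers_generating_model(self):
        # AIC selection of the generating model; occasional misselection of
        # the richer model on JC data is expected (chi-square tail), so the
        # check is on the recovery rate, not on every replicate
        jc_hits = hky_hits = 0
        n = 10
        for seed in range(n):
            tr = random_tree(
                [f"s{i}" for i in range(6)], seed=seed, min_bl=0.02, max_bl=0.12
            )
            aln_jc = evolve_alignment(tr, SubstitutionModel.jc(), 2000, seed=seed * 2 + 1)
            aln_hky = evolve_alignment(
                tr, SubstitutionModel.hky(8.0, [0.3, 0.2, 0.2, 0.3]), 2000, seed=seed * 2
            )
            jc_hits += select_model(aln_jc).name == "JC"
            hky_hits += select_model(aln_hky).name == "HKY"
        assert jc_hits >= 8
        assert hky_hits >= 9

    @pytest.mark.parametrize("kappa", [2.0, 8.0])
    def test_kappa_recovered_within_15_percent(self, kappa):
        tr = random_tree([f"s{i}" for i in range(6)], seed=4, min_bl=0.02, max_bl=0.12)
        model = SubstitutionModel.hky(kappa, [0.28, 0.22, 0.22, 0.28])
        aln = evolve_alignment(tr, model, 10_000, seed=21)
        sel = select_model(aln)
        assert sel.fits["HKY"].model.kappa == pytest.approx(kappa, rel=0.15)


class TestRooting:
    def test_three_taxon_outgroup(self):
        tree = nj_tree(
            DistanceMatrix(
                ("A", "B", "C"), np.array([[0, 2, 2], [2, 0, 1], [2, 1, 0]], float)
            )
        )
        root_with_outgroup(tree, "A")
        kids = tree.seed_node.child_nodes()
        assert len(kids) == 2
        labels = {
            frozenset(l.taxon.label for l in k.leaf_iter()) for k in kids
        }
        assert frozenset({"A"}) in labels and frozenset({"B", "C"}) in labels

    def test_bipartitions_preserved(self):
        truth = random_tree([f"t{i}" for i in range(8)], seed=17)
        before = bipartitions(truth)
        root_with_outgroup(truth, "t5")
        assert bipartitions(truth) == before

    def test_unknown_leaf(self):
        tree = random_tree(["a", "b", "c", "d"], seed=0)
        with pytest.raises(ValueError, match="unknown leaf"):
            root_with_outgroup(tree, "zz")


class TestCompareTrees:
    def test_identical_trees(self):
        t = random_tree([f"t{i}" for i in range(6)], seed=3)
        rf, assoc = compare_trees(t, t.clone(depth=1))
        assert rf == 0
        assert list(assoc.columns) == ["left", "right"]
        assert (assoc.left == assoc.right).all()

    def test_conflicting_quartets(self):
        t1 = read_newick("((A:1,B:1):1,(C:1,D:1));")
        t2 = read_newick("((A:1,C:1):1,(B:1,D:1));")
        rf, _ = compare_trees(t1, t2)
        assert rf == 2

    def test_rf_upper_bound(self):
        for seed in range(5):
            n = 4 + seed
            t1 = random_tree([f"t{i}" for i in range(n)], seed=seed)
            t2 = random_tree([f"t{i}" for i in range(n)], seed=seed + 99)
            rf, _ = compare_trees(t1, t2)
            assert rf <= 2 * (n - 3)

    def test_leaf_set_mismatch(self):
        t1 = random_tree(["a", "b", "c", "d"], seed=0)
        t2 = random_tree(["a", "b", "c", "e"], seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            compare_trees(t1, t2)


class TestDistancesFromAlignment:
    def test_jc_equals_manual_correction(self):
        aln = Alignment(["a", "b", "c"], ["AAAA" * 5, "AAAT" * 5, "AAAA" * 5])
        dm = alignment_distance_matrix(aln, model="JC")
        assert dm[("a", "b")] == pytest.approx(jc_distance(0.25))
        assert dm[("a", "c")] == 0

    def test_pairwise_deletion(self):
        aln = Alignment(["a", "b"], ["AC-T", "ACNT"])
        dm = alignment_distance_matrix(aln, model="p")
        assert dm[("a", "b")] == 0
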