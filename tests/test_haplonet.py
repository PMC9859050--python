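import itertools
import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orgpopgen import datasets
from orgpopgen.haplonet import (
    DistanceMatrix,
    character_distance,
    collapse_haplotypes,
    distance_matrix,
    gap_blocks,
    indelblock_distance,
    mst_union_oracle,
    rmst_network,
)


class TestCollapse:
    def test_all_identical(self):
        haps = collapse_haplotypes({"a": "ACG", "b": "ACG", "c": "ACG"})
        assert len(haps) == 1 and haps[0].members == ("a", "b", "c")

    def test_published_p13_trio_is_one_haplotype(self):
        df = datasets.mt_snp_table()
        trio = {s: "".join(df.loc[s]) for s in ("P13-1", "P13-2", "P13-3")}
        assert len(collapse_haplotypes(trio)) == 1

    def test_published_matrix_gives_seven_snp_haplotypes(self):
        df = datasets.mt_snp_table()
        chars = {s: "".join(df.loc[s]) for s in df.index}
        haps = collapse_haplotypes(chars)
        # independent oracle: exact string deduplication
        assert len(haps) == len(set(chars.values())) == 7

    def test_labelled_by_first_member(self):
        haps = collapse_haplotypes({"x": "A", "y": "C", "z": "A"})
        assert {h.label for h in haps} == {"x", "y"}


class TestIndelblockDistance:
    def test_identical(self):
        assert indelblock_distance("AC-GT", "AC-GT") == 0

    def test_block_counts_once(self):
        assert indelblock_distance("AC--GT", "ACTTGT") == 1

    def test_private_blocks_count_separately(self):
        # overlapping but non-identical gap spans are two private blocks
        assert indelblock_distance("A---GT", "A--CGT") == 2

    def test_substitutions_plus_blocks(self):
        assert indelblock_distance("AC--GTA", "ATTTGTC") == 3  # 2 subs + 1 block

    def test_published_rows_hamming(self):
        df = datasets.mt_snp_table()
        a = "".join(df.loc["P9-133"])
        b = "".join(df.loc["P13-1"])
        assert indelblock_distance(a, b) == 5

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="unequal lengths"):
            indelblock_distance("AC", "ACG")

    @settings(max_examples=200, deadline=None)
    @given(
        st.tuples(
            st.text(alphabet="AC-", min_size=1, max_size=12),
            st.text(alphabet="AC-", min_size=1, max_size=12),
        ).filter(lambda p: len(p[0]) == len(p[1]))
    )
    def test_symmetric_and_zero_iff_identical(self, pair):
        a, b = pair
        assert indelblock_distance(a, b) == indelblock_distance(b, a)
        assert (indelblock_distance(a, b) == 0) == (a == b)

    def test_equals_hamming_on_gapfree_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 30))
            b = "".join(rng.choice(list("ACGT"), 30))
            hamming = sum(1 for x, y in zip(a, b) if x != y)
            assert indelblock_distance(a, b) == hamming

    def test_agrees_with_ape_reference_implementation(self, tmp_path):
        """Cross-check both components against ape's dist.dna."""
        rng = np.random.default_rng(3)
        seqs = {}
        for i in range(6):
            s = list(rng.choice(list("ACGT"), 60))
            for _ in range(rng.integers(0, 4)):
                start = int(rng.integers(0, 55))
                width = int(rng.integers(1, 5))
                s[start : start + width] = ["-"] * width
            seqs[f"s{i}"] = "".join(s)
        fasta = tmp_path / "seqs.fa"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        script = tmp_path / "dist.R"
        script.write_text(
            textwrap.dedent(
                f"""
                library(ape)
                x <- read.dna("{fasta}", format="fasta", as.matrix=TRUE)
                blocks <- dist.dna(x, model="indelblock")
                subs <- dist.dna(x, model="N", pairwise.deletion=TRUE)
                m <- as.matrix(blocks + subs)
                write.csv(m, "{tmp_path}/d.csv")
                """
            )
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        import pandas as pd

        ref = pd.read_csv(tmp_path / "d.csv", index_col=0)
        for a, b in itertools.combinations(seqs, 2):
            assert indelblock_distance(seqs[a], seqs[b]) == ref.loc[a, b]


class TestGapBlocks:
    def test_blocks(self):
        assert gap_blocks("--A-C--") == [(0, 2), (3, 4), (5, 7)]
        assert gap_blocks("ACGT") == []


class TestCharacterDistance:
    def test_missing_ignored(self):
        assert character_distance("A+.", "C-.") == 2
        assert character_distance("A.", "A-") == 0


class TestRmstNetwork:
    def test_two_haplotypes_single_edge(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        g = rmst_network(dm, iterations=50, seed=0)
        assert list(g.edges(data=True))[0][2]["support"] == 1.0
        assert g.number_of_edges() == 1

    def test_single_node_valid_empty_network(self):
        g = rmst_network(DistanceMatrix(("A",), np.zeros((1, 1))), seed=0)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_equilateral_triangle_all_edges_support_two_thirds(self):
        dm = DistanceMatrix(("A", "B", "C"), np.ones((3, 3)) - np.eye(3))
        g = rmst_network(dm, iterations=3000, seed=1)
        assert g.number_of_edges() == 3
        for *_, d in g.edges(data=True):
            assert d["support"] == pytest.approx(2 / 3, abs=0.05)
            assert d["alternative"]

    def test_unique_mst_no_alternatives(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        )
        g = rmst_network(dm, iterations=300, seed=2)
        assert {frozenset(e) for e in g.edges} == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }
        assert all(d["support"] == 1.0 for *_, d in g.edges(data=True))

    def test_contains_a_minimum_spanning_tree(self):
        import networkx as nx

        rng = np.random.default_rng(5)
        n = 7
        vals = rng.integers(1, 5, size=(n, n)).astype(float)
        d = np.triu(vals, 1)
        d = d + d.T
        dm = DistanceMatrix(tuple(f"h{i}" for i in range(n)), d)
        g = rmst_network(dm, iterations=200, seed=6)
        full = nx.Graph()
        for i, j in itertools.combinations(range(n), 2):
            full.add_edge(f"h{i}", f"h{j}", weight=d[i, j])
        mst_weight = nx.minimum_spanning_tree(full, weight="weight").size(
            weight="weight"
        )
        sub = nx.Graph(
            (u, v, {"weight": dd["weight"]}) for u, v, dd in g.edges(data=True)
        )
        assert nx.is_connected(sub)
        assert nx.minimum_spanning_tree(sub, weight="weight").size(
            weight="weight"
        ) == pytest.approx(mst_weight)


class TestMstUnionOracle:
    def test_path_graph_unique_mst(self):
        dm = DistanceMatrix(
            ("A", "B", "C"), np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], float)
        )
        assert mst_union_oracle(dm) == {
            frozenset({"A", "B"}),
            frozenset({"B", "C"}),
        }

    def test_equilateral_triangle_all_edges(self):
        dm = DistanceMatrix(("A", "B", "C"), np.ones((3, 3)) - np.eye(3))
        assert len(mst_union_oracle(dm)) == 3

    def test_refuses_large_inputs(self):
        n = 9
        dm = DistanceMatrix(
            tuple(f"h{i}" for i in range(n)), np.ones((n, n)) - np.eye(n)
        )
        with pytest.raises(ValueError, match="refused"):
            mst_union_oracle(dm)


class TestDistanceMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="not symmetric"):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix(("a", "b"), np.array([[0.0, -1.0], [-1.0, 0.0]]))

    def test_from_sequences(self):
        dm = distance_matrix({"a": "AC-G", "b": "ACTG", "c": "ACTG"})
        assert dm[("a", "b")] == 1 and dm[("b", "c")] == 0
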