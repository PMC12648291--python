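"""Alignment handling, neighbor joining and the cophenetic symmetry statistic."""

import math

import dendropy
import networkx as nx
import numpy as np
import pytest

from semidox import (
    Alignment,
    DESIGN_PEPTIDES,
    DistanceMatrix,
    HalfPair,
    SequenceRecord,
    cophenetic_distance,
    cophenetic_matrix,
    nj_tree,
    paired_symmetry,
    pairwise_distance,
    read_alignment,
    read_newick,
    remove_gappy_columns,
    simulate_duplication_divergence,
    split_halves,
    stack_halves,
    SimConfig,
    write_alignment,
    write_newick,
)


def path_length_oracle(tree: dendropy.Tree):
    """Brute-force leaf-to-leaf path sums through an explicit edge graph."""
    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is not None:
            g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length or 0.0)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}

    def dist(a, b):
        return nx.shortest_path_length(g, leaves[a], leaves[b], weight="weight")

    return dist


def random_tree(rng, n_leaves):
    """A random binary tree with positive branch lengths (by random joins)."""
    taxa = dendropy.TaxonNamespace([f"L{i}" for i in range(n_leaves)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = [dendropy.Node(taxon=t) for t in taxa]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = float(rng.uniform(0.05, 2.0))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    return tree


class TestAlignmentIO:
    def test_read_basic(self, tmp_path):
        f = tmp_path / "aln.fasta"
        f.write_text(">a\nACDEFGHIK-\n>b\nACDEFGH--L\n")
        aln = read_alignment(f)
        assert aln.n_cols == 10
        assert aln.n_rows == 2

    def test_roundtrip_identity(self, tmp_path):
        aln = Alignment(
            ids=[f"s{i}" for i in range(5)],
            rows=["ACD-E", "ACDFE", "A-DFE", "GCDFE", "ACDF-"],
        )
        out = tmp_path / "x.fasta"
        write_alignment(aln, out)
        back = read_alignment(out)
        assert back.ids == aln.ids and back.rows == aln.rows

    def test_ragged_error_names_row(self, tmp_path):
        f = tmp_path / "ragged.fasta"
        f.write_text(">a\nACDE\n>bad\nACD\n")
        with pytest.raises(ValueError, match="bad"):
            read_alignment(f)


class TestGapFiltering:
    def test_column_over_threshold_removed(self):
        rows = ["A" * 5 for _ in range(10)]
        rows = [("-" if i < 2 else "A") + r[1:] for i, r in enumerate(rows)]  # col 0: 20% gaps
        aln = Alignment(ids=[f"s{i}" for i in range(10)], rows=rows)
        filtered, mapping = remove_gappy_columns(aln)
        assert filtered.n_cols == 4
        assert 0 not in mapping

    def test_column_at_threshold_kept(self):
        rows = [("-" if i == 0 else "A") + "AAAA" for i in range(10)]  # col 0: exactly 10%
        aln = Alignment(ids=[f"s{i}" for i in range(10)], rows=rows)
        filtered, mapping = remove_gappy_columns(aln)
        assert filtered.n_cols == 5
        assert mapping[0] == 0

    def test_gapless_unchanged_and_idempotent(self):
        aln = Alignment(ids=["a", "b"], rows=["ACDE", "ACDF"])
        once, _ = remove_gappy_columns(aln)
        twice, _ = remove_gappy_columns(once)
        assert once.rows == aln.rows
        assert twice.rows == once.rows

    def test_all_columns_gappy_error(self):
        aln = Alignment(ids=["a", "b"], rows=["-A", "A-"])
        with pytest.raises(ValueError):
            remove_gappy_columns(aln, max_gap_frac=0.4)


class TestSplitHalves:
    def test_even_split(self):
        aln = Alignment(ids=["a"], rows=["ACDEFGHIKL"])
        n, c, pairs = split_halves(aln)
        assert n.rows == ["ACDEF"] and c.rows == ["GHIKL"]
        assert pairs == [HalfPair(parent_id="a")]
        assert pairs[0].n_half_id == "a_N" and pairs[0].c_half_id == "a_C"

    def test_odd_split_floor(self):
        aln = Alignment(ids=["a"], rows=["ACDEFGHIKLM"])
        n, c, _ = split_halves(aln)
        assert n.n_cols == 5 and c.n_cols == 6

    def test_symdoxin_halves_share_repeat(self):
        ann = DESIGN_PEPTIDES["ANN"]  # repeat(26) + VKK + repeat(25)
        repeat = ann[:26]
        aln = Alignment(ids=["ANN"], rows=[ann])
        n, c, _ = split_halves(aln, split_col=(26, 29))
        assert n.rows[0].replace("-", "") == repeat
        assert c.rows[0].replace("-", "") == repeat[:25]

    def test_empty_half_excluded_with_warning(self):
        aln = Alignment(ids=["ok", "gappy"], rows=["ACDEFG", "ACD---"])
        with pytest.warns(UserWarning, match="gappy"):
            n, c, pairs = split_halves(aln)
        assert [p.parent_id for p in pairs] == ["ok"]

    def test_degapped_halves_reconstruct_parent(self, rng):
        letters = np.array(list("ACDEFG-"))
        ids = [f"s{i}" for i in range(6)]
        rows = ["".join(rng.choice(letters, size=20)) or "A" for _ in ids]
        rows = [r if r.replace("-", "") else "A" * 20 for r in rows]
        aln = Alignment(ids=ids, rows=rows)
        n, c, pairs = split_halves(aln)
        for p in pairs:
            parent = aln.degapped(p.parent_id)
            assert n.degapped(p.n_half_id) + c.degapped(p.c_half_id) == parent


class TestPairwiseDistance:
    def test_identical_rows_zero(self):
        aln = Alignment(ids=["a", "b"], rows=["ACDEF", "ACDEF"])
        for model in ("p", "poisson"):
            assert pairwise_distance(aln, model).get("a", "b") == 0.0

    def test_two_of_ten_mismatches(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAAAAAAAA", "AAAAAAAACD"])
        assert pairwise_distance(aln, "p").get("a", "b") == pytest.approx(0.2)
        assert pairwise_distance(aln, "poisson").get("a", "b") == pytest.approx(
            -math.log(0.8)
        )

    def test_disjoint_gap_patterns_error(self):
        aln = Alignment(ids=["a", "b"], rows=["AC--", "--AC"])
        with pytest.raises(ValueError, match="no .*ungapped"):
            pairwise_distance(aln)

    def test_saturated_pair_poisson_error(self):
        aln = Alignment(ids=["a", "b"], rows=["AAAA", "CCCC"])
        with pytest.raises(ValueError, match="Poisson"):
            pairwise_distance(aln, "poisson")


class TestNeighborJoining:
    def test_additive_four_leaf_recovery(self):
        # path distances of ((A:1,B:2):1,(C:3,D:4));
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels=labels, values=d))
        cm = cophenetic_matrix(tree)
        np.testing.assert_allclose(cm.values, d, atol=1e-12)

    def test_equidistant_three_leaves(self):
        d = np.full((3, 3), 2.0) - 2.0 * np.eye(3)
        tree = nj_tree(DistanceMatrix(labels=["A", "B", "C"], values=d))
        for leaf in tree.leaf_node_iter():
            assert leaf.edge.length == pytest.approx(1.0)

    def test_duplicate_label_error(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["A", "A", "B"], values=np.zeros((3, 3)))

    def test_too_few_labels_error(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["A", "B"], values=np.zeros((2, 2))))

    def test_random_additive_matrices_reproduced(self, rng):
        for _ in range(5):
            tree = random_tree(rng, 10)
            oracle = path_length_oracle(tree)
            labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
            d = np.zeros((10, 10))
            for i in range(10):
                for j in range(i + 1, 10):
                    d[i, j] = d[j, i] = oracle(labels[i], labels[j])
            rebuilt = nj_tree(DistanceMatrix(labels=labels, values=d))
            np.testing.assert_allclose(
                cophenetic_matrix(rebuilt).values, d, atol=1e-9
            )

    def test_deterministic_under_ties(self):
        d = np.full((4, 4), 1.0) - np.eye(4)
        dm = DistanceMatrix(labels=["A", "B", "C", "D"], values=d)
        first = cophenetic_matrix(nj_tree(dm)).values
        second = cophenetic_matrix(nj_tree(dm)).values
        np.testing.assert_array_equal(first, second)


class TestNewick:
    def test_two_leaf_parse(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("(A:1,B:2);\n")
        tree = read_newick(f)
        assert {l.taxon.label for l in tree.leaf_node_iter()} == {"A", "B"}

    def test_roundtrip_preserves_path_distances(self, tmp_path, rng):
        tree = random_tree(rng, 50)
        f = tmp_path / "big.nwk"
        write_newick(tree, f)
        back = read_newick(f)
        np.testing.assert_allclose(
            cophenetic_matrix(back).values,
            cophenetic_matrix(tree).values,
            rtol=1e-6,
        )

    def test_malformed_error(self, tmp_path):
        f = tmp_path / "bad.nwk"
        f.write_text("((A:1,B:2;\n")
        with pytest.raises(ValueError):
            read_newick(f)


class TestCophenetic:
    def test_same_leaf_zero(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("(A:1.5,B:2.5);\n")
        tree = read_newick(f)
        assert cophenetic_distance(tree, "A", "A") == 0.0

    def test_two_edge_path(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("(A:1.5,B:2.5);\n")
        tree = read_newick(f)
        assert cophenetic_distance(tree, "A", "B") == pytest.approx(4.0)

    def test_unknown_leaf_error(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("(A:1,B:2);\n")
        with pytest.raises(KeyError):
            cophenetic_distance(read_newick(f), "A", "Z")

    def test_matches_brute_force_on_random_trees(self, rng):
        tree = random_tree(rng, 20)
        oracle = path_length_oracle(tree)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                assert cophenetic_distance(tree, labels[i], labels[j]) == pytest.approx(
                    oracle(labels[i], labels[j])
                )

    def test_metric_properties(self, rng):
        tree = random_tree(rng, 12)
        cm = cophenetic_matrix(tree)
        d = cm.values
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert (d[~np.eye(len(d), dtype=bool)] > 0).all()
        n = len(d)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPairedSymmetry:
    def test_sister_leaves(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("((p_N:0.1,p_C:0.2):0.5,(x_N:1,x_C:2):0.5);\n")
        tree = read_newick(f)
        results, mean = paired_symmetry(tree, [HalfPair("p"), HalfPair("x")])
        by_id = {r.parent_id: r for r in results}
        assert by_id["p"].cophenetic_distance == pytest.approx(0.3)
        assert by_id["p"].symmetric_at(1.0)
        assert by_id["x"].cophenetic_distance == pytest.approx(3.0)
        assert not by_id["x"].symmetric_at(1.0)
        assert mean == pytest.approx(1.65)

    def test_missing_leaf_names_parent(self, tmp_path):
        f = tmp_path / "t.nwk"
        f.write_text("(a_N:1,a_C:1,b_N:1);\n")
        tree = read_newick(f)
        with pytest.raises(KeyError, match="b"):
            paired_symmetry(tree, [HalfPair("b")])

    def test_zero_divergence_families_symmetric(self):
        cfg = SimConfig(seed=3, n_families=8, rate_per_half=0.0)
        records, truth = simulate_duplication_divergence(cfg)
        aln = Alignment(ids=[r.id for r in records], rows=[r.residues for r in records])
        bounds = (int(truth.n_end[0]), int(truth.c_start[0]))
        n, c, pairs = split_halves(aln, split_col=bounds)
        tree = nj_tree(pairwise_distance(stack_halves(n, c)))
        results, mean = paired_symmetry(tree, pairs)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert all(r.symmetric_at(1.0) for r in results)

    def test_mean_distance_increases_with_rate(self):
        def mean_distance(rate, seed=7):
            cfg = SimConfig(seed=seed, n_families=30, rate_per_half=rate)
            records, truth = simulate_duplication_divergence(cfg)
            aln = Alignment(
                ids=[r.id for r in records], rows=[r.residues for r in records]
            )
            bounds = (int(truth.n_end[0]), int(truth.c_start[0]))
            n, c, pairs = split_halves(aln, split_col=bounds)
            tree = nj_tree(pairwise_distance(stack_halves(n, c)))
            _, mean = paired_symmetry(tree, pairs)
            return mean

        assert mean_distance(0.3) > mean_distance(0.05)
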