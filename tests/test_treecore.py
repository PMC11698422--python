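import numpy as np
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from clonotangle.treecore import (Dendrogram, DistanceMatrix,
                                  NewickParseError, cophenetic, hclust,
                                  read_newick, upgma, write_newick)

from conftest import (all_rotations, merge_table, naive_linkage_trace,
                      random_distance_matrix, random_tree)


class TestUpgma:
    def test_hand_trace_three_leaves(self, three_leaf_dm):
        """d(A,B)=2, d(A,C)=d(B,C)=4: (A,B) joins at 1, C joins at 2."""
        t = upgma(three_leaf_dm)
        assert t.leaf_order == ["A", "B", "C"]
        assert merge_table(t) == [(frozenset("AB"), 1.0),
                                  (frozenset("ABC"), 2.0)]

    def test_two_leaves_merge_at_half_distance(self):
        dm = DistanceMatrix(["X", "Y"], np.array([[0.0, 6.0], [6.0, 0.0]]))
        t = upgma(dm)
        assert t.root.height == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", [7] + list(range(5)))
    def test_matches_naive_oracle(self, seed):
        """Merge sets and heights agree with a from-scratch O(n^3) oracle."""
        dm = random_distance_matrix(8, seed)
        got = merge_table(upgma(dm))
        want = naive_linkage_trace(dm, "average", height_scale=0.5)
        assert [m for m, _ in got] == [m for m, _ in want]
        assert np.allclose([h for _, h in got], [h for _, h in want])

    def test_size_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            upgma(DistanceMatrix(["A"], np.zeros((1, 1))))

    def test_nonfinite_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError, match="finite"):
            DistanceMatrix(["A", "B"], d)

    @pytest.mark.parametrize("seed", range(10))
    def test_ultrametric_three_point_condition(self, seed):
        """The two largest of any cophenetic triple are equal."""
        t = upgma(random_distance_matrix(9, seed))
        cd = cophenetic(t)
        n = len(cd.labels)
        for i in range(n):
            for j in range(i + 1, n):
                for k in range(j + 1, n):
                    trip = sorted([cd.d[i, j], cd.d[i, k], cd.d[j, k]])
                    assert trip[1] == pytest.approx(trip[2], abs=1e-9)


class TestHclust:
    def test_ward_two_points(self):
        dm = DistanceMatrix(["X", "Y"], np.array([[0.0, 3.0], [3.0, 0.0]]))
        assert hclust(dm, "ward").root.height == pytest.approx(3.0)

    def test_average_collinear_points(self):
        """1-D points {0, 1, 10}: the (0, 1) pair merges first."""
        pts = np.array([0.0, 1.0, 10.0])
        d = np.abs(pts[:, None] - pts[None, :])
        t = hclust(DistanceMatrix(["p0", "p1", "p10"], d), "average")
        table = merge_table(t)
        assert (frozenset({"p0", "p1"}), 1.0) in table
        # second merge at mean(10, 9) = 9.5
        assert table[-1] == (frozenset({"p0", "p1", "p10"}),
                             pytest.approx(9.5))

    @pytest.mark.parametrize("seed", range(5))
    def test_average_heights_double_upgma(self, seed):
        """Raw-criterion average heights are exactly 2x UPGMA heights."""
        dm = random_distance_matrix(7, seed)
        h_av = dict(merge_table(hclust(dm, "average")))
        h_up = dict(merge_table(upgma(dm)))
        assert h_av.keys() == h_up.keys()
        for clade in h_av:
            assert h_av[clade] == pytest.approx(2.0 * h_up[clade])

    @pytest.mark.parametrize("linkage", ["ward", "average", "complete"])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle(self, linkage, seed):
        dm = random_distance_matrix(9, seed)
        got = merge_table(hclust(dm, linkage))
        want = naive_linkage_trace(dm, linkage)
        assert [m for m, _ in got] == [m for m, _ in want]
        assert np.allclose([h for _, h in got], [h for _, h in want])

    @pytest.mark.parametrize("seed", range(5))
    def test_average_matches_scipy(self, seed):
        """Cross-check against scipy's engine (tie-free random input)."""
        dm = random_distance_matrix(8, seed)
        ours = {clade: h for clade, h in merge_table(hclust(dm, "average"))}
        Z = hierarchy.linkage(squareform(dm.d), method="average")
        members: list[set] = [{lab} for lab in dm.labels]
        for a, b, h, _ in Z:
            merged = members[int(a)] | members[int(b)]
            members.append(merged)
            assert ours[frozenset(merged)] == pytest.approx(h)

    def test_unknown_linkage(self):
        dm = random_distance_matrix(4, 0)
        with pytest.raises(ValueError, match="unknown linkage"):
            hclust(dm, "single")


class TestCophenetic:
    def test_recovers_ultrametric_input(self, three_leaf_dm):
        cd = cophenetic(upgma(three_leaf_dm))
        assert cd[("A", "B")] == pytest.approx(2.0)
        assert cd[("A", "C")] == pytest.approx(4.0)
        assert cd[("B", "C")] == pytest.approx(4.0)

    def test_two_leaf_tree(self):
        dm = DistanceMatrix(["X", "Y"], np.array([[0.0, 6.0], [6.0, 0.0]]))
        assert cophenetic(upgma(dm))[("X", "Y")] == pytest.approx(6.0)


class TestNewick:
    def test_parse_three_leaves(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert t.leaf_order == ["A", "B", "C"]
        assert t.root.height == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [7, 11, 23])
    def test_round_trip_preserves_everything(self, seed):
        t = random_tree(8, seed)
        s1 = write_newick(t)
        t2 = read_newick(s1)
        assert t2.leaf_order == t.leaf_order
        got, want = merge_table(t2), merge_table(t)
        assert [c for c, _ in got] == [c for c, _ in want]
        assert np.allclose([h for _, h in got], [h for _, h in want],
                           atol=1e-9)

    def test_unbalanced_reports_offset(self):
        with pytest.raises(NewickParseError) as exc:
            read_newick("((A:1,B:1)")
        assert exc.value.offset == 10

    def test_nonbinary_rejected_then_binarized(self):
        txt = "(A:1,B:1,C:1);"
        with pytest.raises(NewickParseError, match="non-binary"):
            read_newick(txt)
        t = read_newick(txt, binarize=True)
        assert sorted(t.leaf_order) == ["A", "B", "C"]
        assert all(len(n.children) == 2 for n in t.internal_nodes())

    def test_support_round_trip(self):
        t = random_tree(5, 3)
        for node in t.internal_nodes():
            node.support = 0.75
        s = write_newick(t, include_support=True)
        t2 = read_newick(s)
        assert all(n.support == pytest.approx(0.75)
                   for n in t2.internal_nodes()
                   if n is not t2.root or "0.75" in s)


class TestDendrogramStructure:
    def test_child_swap_exchanges_child_blocks_in_place(self):
        """A swap touches only the node's contiguous leaf block, inside
        which the two child blocks exchange places."""
        t = random_tree(9, 5)
        before = t.leaf_order
        for k, node in enumerate(t.internal_nodes()):
            left_block = [lf.label for lf in node.children[0].leaves()]
            right_block = [lf.label for lf in node.children[1].leaves()]
            block = left_block + right_block
            i = before.index(block[0])
            tt = t.copy()
            tt.internal_nodes()[k].swap()
            after = tt.leaf_order
            assert after[:i] == before[:i]
            assert after[i:i + len(block)] == right_block + left_block
            assert after[i + len(block):] == before[i + len(block):]

    def test_swapping_whole_subtree_reverses_leaf_order(self):
        t = random_tree(8, 3)
        before = t.leaf_order
        for node in t.internal_nodes():
            node.swap()
        assert t.leaf_order == before[::-1]

    def test_duplicate_labels_rejected(self):
        from clonotangle.treecore import Node
        leaf = lambda lab: Node(0.0, None, lab)
        root = Node(1.0, [Node(0.5, [leaf("A"), leaf("A")]), leaf("C")])
        with pytest.raises(ValueError, match="duplicate"):
            Dendrogram(root)
        with pytest.raises(NewickParseError):
            read_newick("((A:1,A:1):1,C:2);")

    def test_cut_recovers_heights_partition(self, three_leaf_dm):
        t = upgma(three_leaf_dm)
        two = t.cut(2)
        assert two["A"] == two["B"] != two["C"]
        assert len(set(t.cut(3).values())) == 3

    def test_distance_matrix_tsv_round_trip(self, tmp_path):
        dm = random_distance_matrix(5, 1)
        p = tmp_path / "d.tsv"
        dm.to_tsv(p)
        dm2 = DistanceMatrix.from_tsv(p)
        assert dm2.labels == dm.labels
        assert np.allclose(dm2.d, dm.d)
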