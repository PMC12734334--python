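"""Simple matching, UPGMA construction, cuts and exports."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average, cophenet
from scipy.spatial.distance import squareform

from conftest import make_bands
from ssrcore.clustering import (
    SimilarityMatrix,
    UndefinedPairError,
    cut_at_similarity,
    simple_matching,
    to_newick,
    upgma,
    upgma_from_similarity,
)


class TestSimpleMatching:
    def test_identical_rows(self):
        b = make_bands({"x": [1, 0, 1, 0], "y": [1, 0, 1, 0]})
        assert simple_matching(b).values[0, 1] == 1.0

    def test_complementary_rows(self):
        b = make_bands({"x": [1] * 5 + [0] * 5, "y": [0] * 5 + [1] * 5})
        assert simple_matching(b).values[0, 1] == 0.0

    def test_half_agreement_counts_shared_absence(self):
        b = make_bands({"x": [1, 1, 0, 0], "y": [1, 0, 1, 0]})
        assert simple_matching(b).values[0, 1] == 0.5

    def test_missing_marker_excluded_pairwise(self):
        b = make_bands(
            {"x": [1, 0, 1, 1], "y": [1, 0, 0, 0], "z": [1, 0, 1, 1]},
            markers=["M1", "M1", "M2", "M2"],
            missing={"y": ["M2"]},
        )
        s = simple_matching(b)
        # x-y compares only M1's two columns (both agree)
        assert s.values[0, 1] == 1.0
        # x-z compares all four columns
        assert s.values[0, 2] == 1.0

    def test_no_comparable_columns_is_an_error(self):
        b = make_bands(
            {"x": [1, 0], "y": [1, 0]},
            markers=["M1", "M1"],
            missing={"y": ["M1"]},
        )
        with pytest.raises(UndefinedPairError):
            simple_matching(b)

    def test_diagonal_and_symmetry(self, default_bands):
        s = simple_matching(default_bands)
        assert np.allclose(np.diag(s.values), 1.0)
        assert np.allclose(s.values, s.values.T)
        assert s.values.min() >= 0.0 and s.values.max() <= 1.0


class TestUPGMA:
    def test_three_taxon_hand_example(self):
        # D(A,B)=0.2, D(A,C)=D(B,C)=0.6: merge (A,B) at 0.2, C at 0.6
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        t = upgma(d, ["A", "B", "C"])
        assert t.root.height == pytest.approx(0.6)
        ab = [c for c in t.root.children if len(c.leaves) == 2][0]
        assert sorted(ab.leaves) == ["A", "B"]
        assert ab.height == pytest.approx(0.2)

    def test_all_equal_distances_merge_at_one_height(self):
        d = 0.4 * (1 - np.eye(4))
        t = upgma(d, list("abcd"))
        heights = [n.height for n in t.nodes() if not n.is_leaf]
        assert all(h == pytest.approx(0.4) for h in heights)

    def test_tie_rule_is_deterministic_under_label_order(self):
        d = 0.4 * (1 - np.eye(3))
        t1 = upgma(d, ["b", "a", "c"])
        t2 = upgma(d, ["c", "a", "b"])
        first1 = next(n for n in t1.nodes() if len(n.leaves) == 2)
        first2 = next(n for n in t2.nodes() if len(n.leaves) == 2)
        assert sorted(first1.leaves) == sorted(first2.leaves) == ["a", "b"]

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (12, 2)])
    def test_cophenetic_matches_scipy_average_linkage(self, n, seed):
        """Merge heights equal SciPy's average-linkage cophenetic distances."""
        rng = np.random.default_rng(seed)
        condensed = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
        d = squareform(condensed)
        labels = [f"t{i}" for i in range(n)]
        mine = upgma(d, labels).cophenetic().to_numpy()
        theirs = squareform(cophenet(average(condensed)))
        assert np.allclose(mine, theirs)

    def test_ultrametric_three_point_condition(self, default_bands):
        t = upgma_from_similarity(simple_matching(default_bands))
        c = t.cophenetic().to_numpy()
        rng = np.random.default_rng(0)
        n = c.shape[0]
        for _ in range(200):
            i, j, k = rng.choice(n, 3, replace=False)
            assert c[i, j] <= max(c[i, k], c[j, k]) + 1e-12

    def test_invariant_under_label_permutation(self):
        rng = np.random.default_rng(3)
        d = squareform(rng.uniform(0.1, 1.0, size=15))
        labels = list("abcdef")
        t = upgma(d, labels)
        perm = [3, 0, 5, 1, 4, 2]
        d2 = d[np.ix_(perm, perm)]
        t2 = upgma(d2, [labels[i] for i in perm])
        c1 = t.cophenetic()
        c2 = t2.cophenetic().loc[c1.index, c1.columns]
        assert np.allclose(c1.to_numpy(), c2.to_numpy())

    def test_non_finite_distances_rejected(self):
        d = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(ValueError):
            upgma(d, ["a", "b"])


class TestCuts:
    def test_threshold_one_gives_singletons_unless_duplicates(self):
        b = make_bands({"x": [1, 0, 1], "y": [1, 0, 1], "z": [0, 1, 0]})
        t = upgma_from_similarity(simple_matching(b))
        groups = cut_at_similarity(t, 1.0)
        assert groups["x"] == groups["y"] != groups["z"]

    def test_threshold_zero_gives_one_group(self, default_bands):
        t = upgma_from_similarity(simple_matching(default_bands))
        assert set(cut_at_similarity(t, 0.0).values()) == {1}

    def test_group_count_monotone_in_threshold(self, default_bands):
        t = upgma_from_similarity(simple_matching(default_bands))
        counts = [
            len(set(cut_at_similarity(t, thr).values()))
            for thr in np.linspace(0, 1, 21)
        ]
        assert counts == sorted(counts)

    def test_groups_numbered_by_first_leaf_input_order(self):
        b = make_bands({"x": [1, 0, 1], "y": [0, 1, 0], "z": [1, 0, 1]})
        groups = cut_at_similarity(
            upgma_from_similarity(simple_matching(b)), 1.0
        )
        assert groups["x"] == 1  # x appears first in input order
        assert groups["y"] == 2


class TestExports:
    def test_newick_branch_lengths_are_height_differences(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        nwk = to_newick(upgma(d, ["A", "B", "C"]))
        assert "C:0.6" in nwk
        assert "A:0.2" in nwk
        assert ":0.4" in nwk  # internal (A,B) node sits 0.4 below root
        assert nwk.endswith(";")

    def test_newick_parses_with_dendropy_and_is_ultrametric(self, default_bands):
        import dendropy

        t = upgma_from_similarity(simple_matching(default_bands))
        tree = dendropy.Tree.get(data=to_newick(t), schema="newick")
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert len(depths) == len(default_bands.accessions)
        assert max(depths) - min(depths) < 1e-6

    def test_similarity_matrix_validation(self):
        with pytest.raises(ValueError):
            SimilarityMatrix(labels=["a", "b"], values=np.array([[1.0, 0.5]]))
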