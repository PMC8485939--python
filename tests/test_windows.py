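from itertools import product

import numpy as np
import pytest

from hlpatterns.errors import ValidationError
from hlpatterns.normalize import ExpressionMatrix
from hlpatterns.windows import (
    hierarchical_cluster,
    interval_changed_genes,
    max_change_window,
    sample_distance_matrix,
)

from oracles import naive_agglomerate


def expr_from(values, labels=None):
    values = np.asarray(values, dtype=float)
    labels = labels or tuple(f"s{j}" for j in range(values.shape[1]))
    genes = tuple(f"g{i}" for i in range(values.shape[0]))
    return ExpressionMatrix(genes, labels, values)


class TestIntervalChangedGenes:
    def test_boundary_inclusive_up_and_zero_delta(self):
        e = expr_from([[3.0, 4.0], [2.0, 2.0], [5.0, 3.5]])
        up, down = interval_changed_genes(e, "s0", "s1", fold=2.0)
        assert up == {"g0"}
        assert down == {"g2"}
        assert "g1" not in up | down

    def test_disjoint_and_monotone_in_fold(self):
        rng = np.random.default_rng(2)
        e = expr_from(rng.normal(scale=2, size=(200, 4)))
        previous = None
        for fold in (1.5, 2.0, 4.0, 8.0):
            up, down = interval_changed_genes(e, "s1", "s2", fold=fold)
            assert not up & down
            union = up | down
            if previous is not None:
                assert union <= previous
            previous = union

    def test_unknown_label_rejected(self):
        e = expr_from([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            interval_changed_genes(e, "s0", "nope")


class TestSampleDistance:
    def test_duplicated_column_distance_zero(self):
        e = expr_from([[1.0, 1.0, 4.0], [2.0, 2.0, 0.0]])
        d = sample_distance_matrix(e, center=False)
        assert d[0, 1] == 0.0
        assert d[0, 2] > 0

    def test_single_gene_euclidean(self):
        e = expr_from([[0.0, 3.0]])
        d = sample_distance_matrix(e, center=False)
        assert d[0, 1] == pytest.approx(3.0)

    def test_triangle_inequality_random(self):
        rng = np.random.default_rng(8)
        e = expr_from(rng.normal(size=(30, 5)))
        d = sample_distance_matrix(e)
        for i, j, k in product(range(5), repeat=3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_empty_subset_rejected(self):
        e = expr_from([[1.0, 2.0]])
        with pytest.raises(ValidationError):
            sample_distance_matrix(e, gene_subset=[])

    def test_invariant_under_gene_order_and_gene_constant(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=(20, 4))
        shifted = values + rng.normal(size=(20, 1))  # per-gene constants
        d0 = sample_distance_matrix(expr_from(values), center=True)
        d1 = sample_distance_matrix(expr_from(values[::-1]), center=True)
        d2 = sample_distance_matrix(expr_from(shifted), center=True)
        np.testing.assert_allclose(d0, d1)
        np.testing.assert_allclose(d0, d2)


class TestHierarchicalCluster:
    def test_two_tight_pairs_hand_trace(self):
        # within-pair distance 1, between-pair 10: the pairs merge first,
        # final complete-linkage merge at height 10
        d = np.array(
            [
                [0, 1, 10, 10],
                [1, 0, 10, 10],
                [10, 10, 0, 1],
                [10, 10, 1, 0],
            ],
            dtype=float,
        )
        dendro = hierarchical_cluster(d, "abcd")
        np.testing.assert_allclose(sorted(dendro.heights), [1, 1, 10])
        assert set(dendro.cut(2)) == {frozenset("ab"), frozenset("cd")}

    def test_two_samples_single_merge(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        dendro = hierarchical_cluster(d, ("x", "y"))
        assert dendro.heights.tolist() == [2.5]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(19)
        points = rng.normal(size=(8, 3))
        d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
        for linkage in ("complete", "average", "single"):
            dendro = hierarchical_cluster(d, range(8), linkage=linkage)
            assert np.all(np.diff(dendro.heights) >= -1e-12)

    def test_rejects_asymmetric_matrix(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]), "ab")

    @pytest.mark.parametrize("linkage", ["complete", "average", "single"])
    def test_exhaustive_four_leaf_oracle(self, linkage):
        """Agreement with naive agglomeration on all {1,2,3}-entry matrices.

        When the naive agglomeration never faces a tied merge choice the
        result is unique, and the full cophenetic matrices must agree
        exactly.  Under ties, different valid tie-breaks can change the
        tree (even its height multiset, for complete/average linkage), so
        only tie-invariant facts are asserted there: the first merge sits
        at the global minimum distance and heights are non-decreasing.
        """
        checked_exact = 0
        for entries in product((1.0, 2.0, 3.0), repeat=6):
            d = np.zeros((4, 4))
            d[np.triu_indices(4, 1)] = entries
            d = d + d.T
            dendro = hierarchical_cluster(d, range(4), linkage=linkage)
            heights, coph, tie_free = naive_agglomerate(d, linkage)
            assert dendro.heights[0] == d[np.triu_indices(4, 1)].min()
            assert np.all(np.diff(dendro.heights) >= -1e-12)
            if tie_free:
                np.testing.assert_allclose(sorted(dendro.heights), sorted(heights))
                np.testing.assert_allclose(dendro.cophenetic(), coph)
                checked_exact += 1
        assert checked_exact > 30  # the tie-free stratum is non-trivial

    def test_newick_contains_all_leaves(self):
        d = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        newick = hierarchical_cluster(d, ("a", "b", "c")).to_newick()
        assert newick.endswith(";")
        for leaf in "abc":
            assert leaf in newick


class TestMaxChangeWindow:
    def test_planted_shift_between_second_and_third(self):
        from hlpatterns.simulate import SimConfig, generate_counts
        from hlpatterns.normalize import rlog_like_transform
        from hlpatterns.patterns import filter_fold_variation

        cfg = SimConfig(
            seed=5, n_noise=500, planted={"HHLL": 50, "LLHH": 50}, dispersion=0.0
        )
        m, _ = generate_counts(cfg)
        expr = rlog_like_transform(m)
        survivors = filter_fold_variation(expr, 2.0)
        report = max_change_window(expr, survivors)
        assert report.max_window == ("BEC20W", "BEC40W")
        assert set(report.two_cluster_cut) == {
            frozenset({"BEC0W", "BEC20W"}),
            frozenset({"BEC40W", "BEC60W"}),
        }

    def test_constant_expression_ties_to_earliest_with_warning(self):
        e = expr_from(np.ones((5, 4)))
        with pytest.warns(UserWarning, match="tied"):
            report = max_change_window(e, center=True)
        assert report.max_window == ("s0", "s1")
        assert all(d == 0 for d in report.consecutive_distances.values())

    def test_up_down_sets_cover_full_expression_matrix(self):
        # the subset steers the distance profile only; change sets use all genes
        values = np.zeros((3, 4))
        values[0] = [0, 0, 5, 5]   # big shift, in subset
        values[1] = [0, 2, 2, 2]   # shifts early, outside subset
        values[2] = [3, 3, 3, 1]   # shifts late, outside subset
        e = expr_from(values)
        report = max_change_window(e, gene_subset=["g0"], fold=2.0)
        assert report.up_sets[("s0", "s1")] == {"g1"}
        assert report.down_sets[("s2", "s3")] == {"g2"}
        assert report.max_window == ("s1", "s2")

    def test_single_sample_rejected(self):
        e = ExpressionMatrix(("g0",), ("only",), np.zeros((1, 1)))
        with pytest.raises(ValidationError):
            max_change_window(e)
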