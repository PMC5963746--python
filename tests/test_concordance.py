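"""Agreement diagnostics: correlations, UPGMA phenograms, cluster counts, range."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import morphoerror as me
from morphoerror.procrustes import ShapeDistanceMatrix


class TestSizeCorrelation:
    def test_identical_and_negated_series(self):
        idx = [f"i{j}" for j in range(10)]
        a = pd.Series(np.arange(10.0), index=idx)
        mat, mean = me.pairwise_size_correlation({"OP1": a, "OP2": a.copy()})
        assert mat.loc["OP1", "OP2"] == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)
        neg = a.mean() - (a - a.mean())
        mat2, _ = me.pairwise_size_correlation({"OP1": a, "OP2": neg})
        assert mat2.loc["OP1", "OP2"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        idx = [f"i{j}" for j in range(20)]
        a = pd.Series(rng.normal(size=20), index=idx)
        b = pd.Series(rng.normal(size=20), index=idx)
        mat, _ = me.pairwise_size_correlation({"OP1": a, "OP2": b})
        cov = ((a - a.mean()) * (b - b.mean())).sum() / 19
        oracle = cov / (a.std(ddof=1) * b.std(ddof=1))
        assert mat.loc["OP1", "OP2"] == pytest.approx(oracle, rel=1e-12)

    def test_too_few_shared_individuals(self):
        a = pd.Series([1.0, 2.0, 3.0], index=["x", "y", "z"])
        b = pd.Series([1.0, 2.0], index=["x", "q"])
        with pytest.raises(ValueError, match="share"):
            me.pairwise_size_correlation({"OP1": a, "OP2": b})


class TestMatrixCorrelation:
    def _dm(self, values, labels=None):
        labels = labels or tuple(f"r{i}" for i in range(values.shape[0]))
        return ShapeDistanceMatrix(labels=tuple(labels), values=values)

    def test_self_correlation_and_affine_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 4))
        v = squareform(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))[
            np.triu_indices(20, 1)])
        dm = self._dm(v)
        assert me.distance_matrix_correlation(dm, dm) == pytest.approx(1.0)
        affine = self._dm(np.where(np.eye(20), 0.0, 2.0 * v + 3.0))
        assert me.distance_matrix_correlation(dm, affine) == pytest.approx(1.0)

    def test_uses_190_lower_triangle_entries_for_n20(self):
        n = 20
        tri = np.tril_indices(n, k=-1)
        assert len(tri[0]) == n * (n - 1) // 2 == 190

    def test_label_mismatch_rejected(self):
        v = np.zeros((4, 4))
        a = self._dm(v, labels=("a", "b", "c", "d"))
        b = self._dm(v, labels=("a", "b", "d", "c"))
        with pytest.raises(ValueError, match="labels"):
            me.distance_matrix_correlation(a, b)


def _random_dm(n, rng):
    pts = rng.normal(size=(n, 3))
    v = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    np.fill_diagonal(v, 0.0)
    labels = tuple(chr(ord("A") + i) for i in range(n))
    return ShapeDistanceMatrix(labels=labels, values=v)


def _tree_heights(tree):
    """Leaf-pair cophenetic distances (2 x merge height) from a TreeNode."""
    tips = sorted(t.name for t in tree.tips())
    out = {}
    for i, a in enumerate(tips):
        for b in tips[i + 1:]:
            lca = tree.lca([a, b])
            h = 0.0
            node = tree.find(a)
            while node is not lca:
                h += node.length
                node = node.parent
            out[(a, b)] = 2 * h
    return out


class TestUpgma:
    def test_three_leaf_hand_example(self):
        v = np.array([[0, 2, 10], [2, 0, 10], [10, 10, 0]], float)
        tree = me.upgma_tree(ShapeDistanceMatrix(labels=("A", "B", "C"), values=v))
        ab = tree.lca(["A", "B"])
        assert ab.count(tips=True) == 2
        assert tree.find("A").length == pytest.approx(1.0)
        assert tree.find("B").length == pytest.approx(1.0)
        assert tree.find("C").length == pytest.approx(5.0)
        assert ab.length == pytest.approx(4.0)  # joins root at height 5

    def test_heights_nondecreasing_to_root(self, replica_fit):
        dm = me.shape_distance_matrix(replica_fit)
        tree = me.upgma_tree(dm)
        for tip in tree.tips():
            heights = []
            h = 0.0
            node = tip
            while node.parent is not None:
                h += node.length
                heights.append(h)
                node = node.parent
            assert (np.diff(heights) >= -1e-9).all()

    def test_reconstructs_ultrametric_matrix_exactly(self):
        # build an ultrametric matrix from a known tree, then recover it
        rng = np.random.default_rng(2)
        dm = _random_dm(6, rng)
        z = linkage(squareform(dm.values, checks=False), method="average")
        ultra = squareform(cophenet(z))
        udm = ShapeDistanceMatrix(labels=dm.labels, values=ultra)
        tree = me.upgma_tree(udm)
        got = _tree_heights(tree)
        for (a, b), d in got.items():
            i, j = udm.labels.index(a), udm.labels.index(b)
            assert d == pytest.approx(ultra[i, j], abs=1e-9)

    @pytest.mark.parametrize("seed", [3, 4, 5, 6])
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        dm = _random_dm(6, rng)
        tree = me.upgma_tree(dm)
        got = _tree_heights(tree)
        z = linkage(squareform(dm.values, checks=False), method="average")
        ref = squareform(cophenet(z))
        for (a, b), d in got.items():
            i, j = dm.labels.index(a), dm.labels.index(b)
            assert d == pytest.approx(ref[i, j], abs=1e-9)

    def test_tie_break_is_deterministic(self):
        v = np.array(
            [[0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float
        )
        dm = ShapeDistanceMatrix(labels=("D", "C", "B", "A"), values=v)
        newicks = {str(me.upgma_tree(dm)) for _ in range(5)}
        assert len(newicks) == 1

    def test_asymmetric_input_rejected(self):
        v = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            ShapeDistanceMatrix(labels=("a", "b"), values=v)


class TestClusterCounts:
    def test_zero_noise_all_triplets(self, zero_noise_replica):
        ds, _ = zero_noise_replica
        fit = me.gpa_align(ds)
        tree = me.upgma_tree(me.shape_distance_matrix(fit))
        mapping = dict(zip(fit.labels, fit.meta["individual_id"]))
        counts = me.replica_cluster_counts(tree, mapping)
        assert counts.n_triplets == counts.n_pairs_or_better == 20

    def test_hand_constructed_tree_counts(self):
        # i1 intact triplet; i2 broken by an i3 leaf grafted inside its clade
        newick = "(((i1a:1,i1b:1):1,i1c:2):5,((i2a:1,(i2b:0.5,i3a:0.5):0.5):1," \
                 "(i2c:1,(i3b:0.5,i3c:0.5):0.5):1):5);"
        from skbio.tree import TreeNode
        from io import StringIO

        tree = TreeNode.read(StringIO(newick))
        mapping = {
            "i1a": "i1", "i1b": "i1", "i1c": "i1",
            "i2a": "i2", "i2b": "i2", "i2c": "i2",
            "i3a": "i3", "i3b": "i3", "i3c": "i3",
        }
        counts = me.replica_cluster_counts(tree, mapping)
        assert counts.n_individuals == 3
        assert counts.n_triplets == 1  # only i1
        # i1 (triplet), i3 has sister pair (i3b,i3c); i2 has no exclusive pair
        assert counts.n_pairs_or_better == 2

    def test_pairs_never_fewer_than_triplets(self, replica_fit):
        tree = me.upgma_tree(me.shape_distance_matrix(replica_fit))
        mapping = dict(zip(replica_fit.labels, replica_fit.meta["individual_id"]))
        counts = me.replica_cluster_counts(tree, mapping)
        assert counts.n_pairs_or_better >= counts.n_triplets

    def test_unmapped_leaf_rejected(self, replica_fit):
        tree = me.upgma_tree(me.shape_distance_matrix(replica_fit))
        with pytest.raises(ValueError, match="not mapped"):
            me.replica_cluster_counts(tree, {})

    def test_triplet_count_nonincreasing_in_noise(self):
        zero_bias = {op: np.zeros((15, 3)) for op in ("OP1", "OP2", "OP3")}
        trip = []
        for sd in (0.05, 0.4, 1.2, 3.0):
            vals = []
            for seed in (21, 22):
                spec = me.replica_spec(
                    seed=seed, operator_bias=zero_bias,
                    noise_sd_soft=sd, noise_sd_bone=1.65 * sd,
                )
                ds, _ = me.generate_replica_study(spec)
                fit = me.gpa_align(ds)
                tree = me.upgma_tree(me.shape_distance_matrix(fit))
                mapping = dict(zip(fit.labels, fit.meta["individual_id"]))
                vals.append(me.replica_cluster_counts(tree, mapping).n_triplets)
            trip.append(np.mean(vals))
        assert (np.diff(trip) <= 0).all()


class TestRelativeRange:
    def test_hand_examples(self):
        r = me.relative_range([1.0, 2.0, 4.0], trim_fraction=0.0)
        assert r.ratio == pytest.approx(4.0)
        c = me.relative_range([2.0, 2.0, 2.0], trim_fraction=0.0)
        assert c.ratio == pytest.approx(1.0) and c.trimmed_ratio == pytest.approx(1.0)

    def test_trimmed_matches_sort_slice_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.uniform(0.5, 5.0, size=100)
        r = me.relative_range(d, trim_fraction=0.05)
        s = np.sort(d)
        m = int(np.ceil(0.025 * 100))
        assert r.trimmed_ratio == pytest.approx(s[-m - 1] / s[m], rel=1e-12)
        assert r.ratio == pytest.approx(s[-1] / s[0], rel=1e-12)
        assert r.ratio >= r.trimmed_ratio >= 1.0

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            me.relative_range([0.0, 1.0, 2.0])
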