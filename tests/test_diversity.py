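from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa

from reservoirlink.core_data import CountTable
from reservoirlink.diversity import (
    bh_fdr,
    pairwise_distance,
    pcoa,
    permanova,
    permanova_crossed,
    shannon,
)


def brute_force_permanova_p(dm: DistanceMatrix, labels: np.ndarray) -> float:
    """Independent oracle: exact p by enumerating assignments of samples to groups."""
    d2 = np.asarray(dm.data) ** 2
    n = len(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    assert len(uniq) == 2

    def pseudo_f(lab):
        iu = np.triu_indices(n, 1)
        ss_total = d2[iu].sum() / n
        ss_within = 0.0
        for g in uniq:
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss_within += np.triu(sub, 1).sum() / len(idx)
        return ((ss_total - ss_within) / (len(uniq) - 1)) / (ss_within / (n - len(uniq)))

    f_obs = pseudo_f(labels)
    stats = []
    for combo in combinations(range(n), int(counts[0])):
        lab = np.array([uniq[0] if i in combo else uniq[1] for i in range(n)])
        stats.append(pseudo_f(lab))
    return float(np.mean([s >= f_obs - 1e-12 for s in stats]))


class TestDistances:
    def test_bray_curtis_hand_value(self, pair_table):
        dm = pairwise_distance(pair_table, "bray_curtis")
        assert dm["x", "y"] == pytest.approx(1 / 3)

    def test_jaccard_hand_value(self, pair_table):
        dm = pairwise_distance(pair_table, "jaccard_pa")
        assert dm["x", "y"] == pytest.approx(1 / 3)

    def test_unweighted_unifrac_disjoint_tips(self, toy_tree):
        table = CountTable(pd.DataFrame(
            [[1, 0, 0], [0, 0, 1]], index=["sA", "sC"], columns=["A", "B", "C"],
        ))
        dm = pairwise_distance(table, "unweighted_unifrac", tree=toy_tree)
        assert dm["sA", "sC"] == pytest.approx(1.0)

    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard_pa"])
    def test_identical_samples_distance_zero(self, metric):
        table = CountTable(pd.DataFrame(
            [[3, 1, 4], [3, 1, 4]], index=["a", "b"], columns=["A", "B", "C"],
        ))
        assert pairwise_distance(table, metric)["a", "b"] == pytest.approx(0.0)

    def test_jaccard_depends_only_on_presence(self):
        t1 = CountTable(pd.DataFrame([[5, 0, 2], [1, 3, 0]], index=["a", "b"],
                                     columns=list("ABC")))
        t2 = CountTable(pd.DataFrame([[1, 0, 9], [7, 1, 0]], index=["a", "b"],
                                     columns=list("ABC")))
        assert (pairwise_distance(t1, "jaccard_pa")["a", "b"]
                == pairwise_distance(t2, "jaccard_pa")["a", "b"])

    def test_weighted_unifrac_star_tree_is_scaled_l1(self):
        # star-like rooted tree, unit tip branches, zero-length internal:
        # normalized weighted UniFrac = L1/2 of proportions
        tree_star = __import__("skbio").TreeNode.read(["((B:1,C:1):0,A:1);"])
        table = CountTable(pd.DataFrame(
            [[4, 4, 0], [0, 4, 4]], index=["a", "b"], columns=list("ABC"),
        ))
        dm = pairwise_distance(table, "weighted_unifrac", tree=tree_star)
        l1 = np.abs(np.array([0.5, 0.5, 0]) - np.array([0, 0.5, 0.5])).sum()
        assert dm["a", "b"] == pytest.approx(l1 / 2)

    def test_missing_tip_named(self, toy_tree):
        table = CountTable(pd.DataFrame([[1, 1], [1, 2]], index=["a", "b"],
                                        columns=["A", "Z"]))
        with pytest.raises(ValueError, match="Z"):
            pairwise_distance(table, "unweighted_unifrac", tree=toy_tree)

    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard_pa"])
    def test_range_and_symmetry(self, metric, toy_table):
        dm = pairwise_distance(toy_table, metric)
        d = np.asarray(dm.data)
        assert ((d >= 0) & (d <= 1)).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert np.diag(d).sum() == 0


class TestShannon:
    def test_uniform_four_taxa_base2(self):
        table = CountTable(pd.DataFrame([[5, 5, 5, 5]], index=["a"],
                                        columns=list("ABCD")))
        assert shannon(table).loc["a"] == pytest.approx(2.0)

    def test_single_taxon_zero(self):
        table = CountTable(pd.DataFrame([[9]], index=["a"], columns=["A"]))
        assert shannon(table).loc["a"] == pytest.approx(0.0)

    def test_invariance_to_taxon_order_and_scale(self, toy_table):
        h = shannon(table := toy_table)
        shuffled = CountTable(table.data[["C", "A", "B"]])
        doubled = CountTable(table.data * 2)
        pd.testing.assert_series_equal(h, shannon(shuffled))
        pd.testing.assert_series_equal(h, shannon(doubled))


class TestPcoa:
    def test_points_on_line_recovered(self):
        pts = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(pts[:, None] - pts[None, :])
        res = pcoa(DistanceMatrix(d, list("abcd")))
        rec = res.coordinates["PC1"].to_numpy()
        np.testing.assert_allclose(
            np.abs(rec[:, None] - rec[None, :]), d, atol=1e-9
        )

    def test_euclidean_input_no_negative_axes_kept(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        res = pcoa(DistanceMatrix(d, [f"s{i}" for i in range(6)]))
        assert (res.eigenvalues >= -1e-9).all()

    def test_three_equidistant_points_equal_eigenvalues(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = pcoa(DistanceMatrix(d, list("abc")))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_matches_skbio_reference(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 4))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        dm = DistanceMatrix(d, [f"s{i}" for i in range(8)])
        ours = pcoa(dm)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        np.testing.assert_allclose(
            np.abs(ours.coordinates.to_numpy()[:, :3]),
            np.abs(ref.samples.to_numpy()[:, :3]), atol=1e-8,
        )


class TestPermanova:
    @pytest.fixture
    def clustered_dm(self):
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(0, 1, (3, 2)), rng.normal(3, 1, (3, 2))])
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        return DistanceMatrix(d, [f"s{i}" for i in range(6)])

    def test_exact_p_equals_brute_force(self, clustered_dm):
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        res = permanova(clustered_dm, labels, method="exact")
        assert res.n_permutations == 20
        assert res.p_value == pytest.approx(
            brute_force_permanova_p(clustered_dm, labels)
        )

    def test_statistic_matches_skbio(self, clustered_dm):
        labels = ["g1"] * 3 + ["g2"] * 3
        ours = permanova(clustered_dm, labels, n_permutations=99, seed=0)
        ref = skbio_permanova(clustered_dm, grouping=labels, permutations=99)
        assert ours.pseudo_f == pytest.approx(ref["test statistic"])

    def test_label_shuffle_invariance_of_f(self, clustered_dm):
        labels = np.array(["g1"] * 3 + ["g2"] * 3)
        perm = np.array([3, 0, 4, 1, 5, 2])
        dm2 = DistanceMatrix(np.asarray(clustered_dm.data)[np.ix_(perm, perm)],
                             [clustered_dm.ids[i] for i in perm])
        a = permanova(clustered_dm, labels, method="exact")
        b = permanova(dm2, labels[perm], method="exact")
        assert a.pseudo_f == pytest.approx(b.pseudo_f)
        assert a.p_value == pytest.approx(b.p_value)

    def test_separated_clusters_minimum_p(self):
        x = np.array([0, 0.1, 0.2, 10, 10.1, 10.2])[:, None]
        d = np.abs(x - x.T)
        dm = DistanceMatrix(d, list("abcdef"))
        labels = ["g1"] * 3 + ["g2"] * 3
        # exact: only the true assignment and its mirror reach the observed F
        res = permanova(dm, labels, method="exact")
        assert res.p_value == pytest.approx(2 / 20)
        # random permutations: p floors at 1/(n_perm + 1)
        res_r = permanova(dm, labels, n_permutations=99, seed=0)
        assert res_r.p_value >= 1 / 100

    def test_single_member_group_rejected(self, clustered_dm):
        with pytest.raises(ValueError, match="single member"):
            permanova(clustered_dm, ["g1"] * 5 + ["g2"])

    def test_null_p_uniform(self):
        """Under no group structure, permutation p is uniform on (0, 1]."""
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(500):
            x = rng.normal(size=(10, 3))
            d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
            dm = DistanceMatrix(d, [f"s{i}" for i in range(10)])
            res = permanova(dm, ["a"] * 5 + ["b"] * 5, n_permutations=99,
                            seed=int(rng.integers(2**31 - 1)))
            pvals.append(res.p_value)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestPermanovaCrossed:
    @pytest.fixture
    def two_factor_data(self):
        rng = np.random.default_rng(3)
        rows, fa, fb = [], [], []
        for a in range(2):
            for b in range(3):
                for _ in range(4):
                    rows.append(rng.normal(a * 2.0, 1.0, 3))
                    fa.append(f"A{a}")
                    fb.append(f"B{b}")
        x = np.array(rows)
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        ids = [f"s{i}" for i in range(len(rows))]
        return (DistanceMatrix(d, ids), pd.Series(fa, index=ids, name="fa"),
                pd.Series(fb, index=ids, name="fb"))

    def test_constant_second_factor_reduces_to_one_way(self, two_factor_data):
        dm, fa, _ = two_factor_data
        const = pd.Series("same", index=list(dm.ids), name="const")
        crossed = permanova_crossed(dm, fa, const, n_permutations=99, seed=0)
        one_way = permanova(dm, fa, n_permutations=99, seed=0)
        assert list(crossed) == ["fa"]
        assert crossed["fa"].pseudo_f == pytest.approx(one_way.pseudo_f, abs=1e-9)

    def test_r_squared_terms_partition_unity(self, two_factor_data):
        dm, fa, fb = two_factor_data
        res = permanova_crossed(dm, fa, fb, n_permutations=49, seed=0)
        r2 = sum(r.r_squared for r in res.values())
        # remaining share is the residual
        assert 0 < r2 < 1
        ss_resid_share = 1 - r2
        n, a, b = len(dm.ids), 2, 3
        assert ss_resid_share == pytest.approx(
            1 - sum(r.r_squared for r in res.values())
        )

    def test_effect_detected_on_factor_a_only(self, two_factor_data):
        dm, fa, fb = two_factor_data
        res = permanova_crossed(dm, fa, fb, n_permutations=199, seed=1)
        assert res["fa"].p_value < 0.05
        assert res["fb"].p_value > 0.05

    def test_aliased_factors_rejected(self, two_factor_data):
        dm, fa, _ = two_factor_data
        aliased = fa.map({"A0": "x", "A1": "y"}).rename("aliased")
        with pytest.raises(ValueError, match="aliased"):
            permanova_crossed(dm, fa, aliased, n_permutations=9)


class TestBhFdr:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_order_preserving(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=20)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])
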