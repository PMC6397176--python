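import numpy as np
import pytest
from scipy.cluster import hierarchy

from concordia.callset_io import INDEL, SNP
from concordia.concordance import (
    CONCORDANT_HET,
    CONCORDANT_HOM,
    DISCORDANT,
    call_concordance,
    classify_loci,
    cluster_pipelines,
    compare_groups,
    jaccard_distance,
    jaccard_distances,
    upgma,
    welch_t,
)


class TestCallConcordance:
    def test_counts_exclude_homref_and_nocall(self, matrix_factory):
        m = matrix_factory(np.array([[1, 1, 2, 3], [1, 3, 3, 3], [0, 0, 0, 0]]))
        res = call_concordance(m, SNP)
        assert list(res.cc) == [2, 1, 4]
        assert res.n_pipelines == 4
        assert res.rate == pytest.approx([0.5, 0.25, 1.0])

    def test_unsupporting_pipelines_excluded_from_denominator(self, matrix_factory):
        support = {
            "P0": frozenset({SNP, INDEL}),
            "P1": frozenset({SNP, INDEL}),
            "P2": frozenset({SNP}),
        }
        m = matrix_factory(
            np.array([[1, 1, 3]]), variant_types=[INDEL], support=support
        )
        res = call_concordance(m, INDEL)
        assert res.n_pipelines == 2 and list(res.cc) == [2]

    def test_zero_cc_violates_invariant(self, matrix_factory):
        m = matrix_factory(np.array([[2, 3]]))
        with pytest.raises(ValueError):
            call_concordance(m, SNP)

    def test_mean_rate_identity(self, default_bundle):
        from concordia.callset_io import merge_callsets

        m = merge_callsets(default_bundle.callsets)
        res = call_concordance(m, SNP)
        assert res.rate.mean() == pytest.approx(
            res.cc.sum() / (len(res.cc) * res.n_pipelines)
        )


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"a", "b", "c"}, {"a", "b", "c"}, 0.0),
            ({"a"}, {"b"}, 1.0),
            ({"a", "b", "c"}, {"b", "c", "d"}, 0.5),
            (set(), {"a"}, 1.0),
            (set(), set(), 0.0),
        ],
    )
    def test_pairs(self, a, b, expected):
        assert jaccard_distance(a, b) == pytest.approx(expected)

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            sets = [
                set(rng.choice(30, size=rng.integers(1, 15), replace=False))
                for _ in range(3)
            ]
            d01 = jaccard_distance(sets[0], sets[1])
            d12 = jaccard_distance(sets[1], sets[2])
            d02 = jaccard_distance(sets[0], sets[2])
            assert d02 <= d01 + d12 + 1e-12

    def test_matrix_properties_and_scaling(self, matrix_factory):
        m = matrix_factory(np.array([[1, 1, 3], [1, 3, 3], [3, 1, 1], [1, 1, 1]]))
        dm = jaccard_distances(m)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)
        s = dm.scaled_values
        off = ~np.eye(3, dtype=bool)
        assert s[off].min() == 0.0 and s[off].max() == 1.0


class TestClustering:
    def test_identical_columns_merge_first_at_zero(self, matrix_factory):
        m = matrix_factory(
            np.array([[1, 1, 0], [0, 0, 1], [1, 1, 1]]), pipelines=["a", "b", "c"]
        )
        dend = cluster_pipelines(m)
        left, right, h = dend.merges[0]
        assert {left[0], right[0]} == {"a", "b"} and h == 0.0

    def test_three_point_average_linkage_heights(self):
        # pairwise distances d(a,b)=1, d(a,c)=1... use 1,1,2 pattern:
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        dend = upgma(d, ["a", "b", "c"])
        # ties at 1 resolve lexicographically: (a,b) first, then avg (2+1)/2
        assert dend.merges[0][:2] == (("a",), ("b",))
        assert dend.merges[0][2] == pytest.approx(1.0)
        assert dend.merges[1][2] == pytest.approx(1.5)

    def test_variant_permutation_invariance(self, matrix_factory):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 4, size=(40, 5))
        m1 = matrix_factory(codes)
        m2 = matrix_factory(codes[rng.permutation(40)])
        d1 = cluster_pipelines(m1)
        d2 = cluster_pipelines(m2)
        assert d1.merges == d2.merges

    def test_matches_scipy_average_linkage(self, matrix_factory):
        rng = np.random.default_rng(9)
        codes = rng.integers(0, 4, size=(60, 6)).astype(float)
        # continuous jitter makes ties measure-zero
        codes += rng.normal(0, 1e-6, size=codes.shape)
        m = matrix_factory(np.zeros((60, 6), dtype=np.int8))
        m.codes = codes  # bypass int coding for the oracle comparison
        dend = cluster_pipelines(m)
        Z = hierarchy.linkage(codes.T, method="average")
        assert np.allclose(
            sorted(h for _, _, h in dend.merges), sorted(Z[:, 2]), rtol=1e-9
        )

    def test_requires_two_pipelines(self, matrix_factory):
        m = matrix_factory(np.array([[1]]), pipelines=["only"])
        with pytest.raises(ValueError):
            cluster_pipelines(m)


class TestClassifyLoci:
    def test_definitions(self, matrix_factory):
        m = matrix_factory(
            np.array(
                [
                    [1, 1, 1, 1],
                    [0, 0, 0, 0],
                    [1, 1, 1, 3],
                    [0, 1, 0, 0],
                    [1, 1, 2, 1],
                ]
            )
        )
        assert list(classify_loci(m)) == [
            CONCORDANT_HET,
            CONCORDANT_HOM,
            DISCORDANT,
            DISCORDANT,
            DISCORDANT,
        ]

    def test_concordant_implies_full_cc(self, default_bundle):
        from concordia.callset_io import merge_callsets

        m = merge_callsets(default_bundle.callsets).by_type(SNP)
        classes = classify_loci(m)
        cc = call_concordance(m, SNP)
        conc = (classes == CONCORDANT_HET) | (classes == CONCORDANT_HOM)
        assert (cc.cc[conc] == cc.n_pipelines).all()


class TestCompareGroups:
    def test_welch_matches_hand_computation(self):
        t, p = welch_t(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
        assert t == pytest.approx(-1.224744871, abs=1e-6)
        assert 0 < p < 1

    def test_identical_groups_give_zero_t(self):
        t, p = welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_small_group_reported_missing(self):
        t, p = welch_t(np.array([1.0]), np.array([1.0, 2]))
        assert np.isnan(t) and np.isnan(p)

    def test_allelic_fraction_from_dp_ad(self, matrix_factory):
        codes = np.array([[1, 1], [1, 1], [1, 3], [0, 1]])
        depth = np.array([[30.0, 20], [10, 10], [8, np.nan], [12, 16]])
        alt = np.array([[15.0, 10], [5, 5], [4, np.nan], [12, 8]])
        m = matrix_factory(codes, depth=depth, alt_depth=alt)
        classes = classify_loci(m)
        out = compare_groups(m, classes)
        af = out[(out.metric == "alt_fraction")].iloc[0]
        # concordant het rows have AF exactly 0.5
        assert af["mean_concordant"] == pytest.approx(0.5)

    def test_bundle_depth_contrast_direction(self, default_bundle):
        # errors are simulated at lower coverage, so discordant loci should
        # average lower depth than concordant ones
        from concordia.callset_io import merge_callsets

        m = merge_callsets(default_bundle.callsets).by_type(SNP)
        out = compare_groups(m, classify_loci(m))
        row = out[
            (out.metric == "depth")
            & (out.comparison == "concordant_vs_discordant")
        ].iloc[0]
        assert row["mean_concordant"] > row["mean_discordant"]
        assert row["p"] < 0.001
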