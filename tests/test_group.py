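"""Group inference: one-sample t, t->z, sign-flip permutation, clustering, FDR."""

import numpy as np
import pytest
from scipy import stats

import fmriverse as fv
from fmriverse.group import InferenceError

from _oracles import bh_reject_brute, label_brute


def _zmap(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool) if mask is None else mask
    return fv.StatMap(values, "z", None, mask)


class TestOneSampleT:
    def test_hand_arithmetic(self):
        maps = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)]
        out = fv.one_sample_ttest(maps)
        assert out.df == 2
        assert out.values[0, 0, 0] == pytest.approx(2 * np.sqrt(3))

    def test_zero_variance_voxels_excluded(self):
        maps = [np.ones((3, 3, 3)) for _ in range(4)]
        maps[0][0, 0, 0] = 1.0  # all subjects identical everywhere
        out = fv.one_sample_ttest(maps)
        assert not out.mask.any()

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(0)
        maps = list(rng.standard_normal((8, 22, 22, 22)))
        out = fv.one_sample_ttest(maps)
        crit = stats.t.isf(0.025, out.df)
        rate = np.mean(np.abs(out.in_mask) > crit)
        assert abs(rate - 0.05) < 0.01


class TestTToZ:
    def test_zero_maps_to_zero(self):
        tmap = fv.StatMap(np.zeros((2, 2, 2)), "t", 5.0, np.ones((2, 2, 2), bool))
        assert np.all(fv.t_to_z(tmap).values == 0)

    def test_known_value_df10(self):
        # independent evaluation: probit(T_10(2)) = 1.7904
        tmap = fv.StatMap(np.full((1, 1, 1), 2.0), "t", 10.0, np.ones((1, 1, 1), bool))
        assert fv.t_to_z(tmap).values[0, 0, 0] == pytest.approx(1.7904, abs=1e-3)

    def test_large_df_limit(self):
        tmap = fv.StatMap(np.full((1, 1, 1), 2.0), "t", 1e4, np.ones((1, 1, 1), bool))
        assert abs(fv.t_to_z(tmap).values[0, 0, 0] - 2.0) < 0.01

    def test_monotone_and_p_preserving(self):
        t = np.linspace(-6, 6, 25).reshape(25, 1, 1)
        z = fv.t_to_z(fv.StatMap(t, "t", 12.0, np.ones(t.shape, bool))).values
        assert np.all(np.diff(z.ravel()) > 0)
        np.testing.assert_allclose(
            stats.norm.sf(z.ravel()), stats.t.sf(t.ravel(), 12), rtol=1e-6
        )

    def test_extreme_t_stays_finite(self):
        tmap = fv.StatMap(np.full((1, 1, 1), 80.0), "t", 14.0, np.ones((1, 1, 1), bool))
        z = fv.t_to_z(tmap).values[0, 0, 0]
        assert np.isfinite(z) and z > 8

    def test_requires_positive_df(self):
        tmap = fv.StatMap(np.zeros((1, 1, 1)), "z", None, np.ones((1, 1, 1), bool))
        with pytest.raises(InferenceError):
            fv.t_to_z(tmap)


class TestSignFlipPermutation:
    def _blob_data(self, n, seed=0, strength=3.0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 6, 6, 6))
        data[:, 2:4, 2:4, 2:4] += strength
        return list(data)

    def test_exhaustive_at_n3_has_8_entries_and_min_p(self):
        res = fv.sign_flip_permutation(self._blob_data(3), cluster_forming_p=0.05, seed=0)
        assert res.null.exhaustive
        assert res.null.n_permutations == 8
        assert min(c.p_fwe for c in res.clusters) == pytest.approx(1 / 8)

    def test_identity_included_so_p_never_zero(self):
        res = fv.sign_flip_permutation(self._blob_data(6, strength=6.0), seed=1)
        assert all(c.p_fwe > 0 for c in res.clusters)

    def test_sampling_switches_to_exhaustive_when_cheaper(self, caplog):
        import logging

        data = self._blob_data(13)
        with caplog.at_level(logging.INFO):
            res = fv.sign_flip_permutation(data, n_permutations=10_000, seed=2)
        assert res.null.exhaustive
        assert res.null.n_permutations == 2**13

    def test_exact_validity_by_full_enumeration_at_n5(self):
        """Exhaustive sign-flip p-values are multiples of 1/32 and valid:
        the null CDF satisfies P(p <= alpha) <= alpha at every alpha."""
        rng = np.random.default_rng(3)
        data = list(rng.standard_normal((5, 6, 6, 6)))
        res = fv.sign_flip_permutation(data, cluster_forming_p=0.05, seed=3)
        assert res.null.n_permutations == 32
        # p-values of all clusters are multiples of 1/32
        for c in res.clusters:
            assert (c.p_fwe * 32) == pytest.approx(round(c.p_fwe * 32))
        # validity: for the max-statistic null, the p-value of each null
        # draw is its rank-based tail probability; check P(p <= a) <= a
        null = res.null.max_cluster_sizes
        pvals = np.array([(null >= s).mean() for s in null])
        for alpha in np.unique(pvals):
            assert (pvals <= alpha).mean() <= alpha + 1e-12

    def test_cluster_table_summarises_records(self):
        res = fv.sign_flip_permutation(self._blob_data(6, strength=5.0), seed=5)
        table = res.cluster_table()
        assert list(table.columns) == [
            "label", "sign", "size", "peak_stat", "peak_index", "p_fwe",
        ]
        assert len(table) == len(res.clusters)
        assert (table["size"].diff().dropna() <= 0).all()  # sorted by extent

    def test_deterministic_given_seed(self):
        data = self._blob_data(14)
        a = fv.sign_flip_permutation(data, n_permutations=200, seed=9)
        b = fv.sign_flip_permutation(data, n_permutations=200, seed=9)
        np.testing.assert_array_equal(a.null.max_cluster_sizes, b.null.max_cluster_sizes)


class TestClusterThreshold:
    def _tmap(self, values):
        values = np.asarray(values, dtype=float)
        return fv.StatMap(values, "t", 10.0, np.ones(values.shape, bool))

    def test_subthreshold_map_gives_empty_masks(self):
        recipe = fv.ClusterRecipe(cluster_forming_p=0.001, extent_threshold=1)
        out = fv.cluster_threshold(self._tmap(np.zeros((4, 4, 4))), recipe)
        assert not out.positive_mask.any() and not out.negative_mask.any()

    def test_two_disjoint_blobs_found_with_sizes(self):
        vals = np.zeros((8, 8, 8))
        vals[1:2, 1:6, 1] = 9.0  # 5-voxel line
        vals[6, 2:7, 6] = 9.0  # another 5-voxel line
        recipe = fv.ClusterRecipe(cluster_forming_p=0.01, extent_threshold=5)
        out = fv.cluster_threshold(self._tmap(vals), recipe)
        comps = label_brute(out.positive_mask, 26)
        assert sorted(len(c) for c in comps) == [5, 5]

    def test_extent_threshold_filters_small_clusters(self):
        vals = np.zeros((8, 8, 8))
        vals[1, 1:6, 1] = 9.0  # size 5 survives
        vals[6, 1:4, 6] = 9.0  # size 3 dropped
        recipe = fv.ClusterRecipe(cluster_forming_p=0.01, extent_threshold=5)
        out = fv.cluster_threshold(self._tmap(vals), recipe)
        assert out.positive_mask.sum() == 5

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(4)
        vals = rng.standard_normal((6, 6, 6)) * 4
        recipe = fv.ClusterRecipe(cluster_forming_p=0.05, extent_threshold=2)
        a = fv.cluster_threshold(self._tmap(vals), recipe)
        b = fv.cluster_threshold(self._tmap(-vals), recipe)
        np.testing.assert_array_equal(a.positive_mask, b.negative_mask)
        np.testing.assert_array_equal(a.negative_mask, b.positive_mask)

    def test_labeling_matches_flood_fill_oracle(self):
        rng = np.random.default_rng(5)
        recipe = fv.ClusterRecipe(cluster_forming_p=0.05, extent_threshold=1)
        for _ in range(25):
            vals = np.where(rng.random((6, 6, 6)) < 0.25, 9.0, 0.0)
            out = fv.cluster_threshold(self._tmap(vals), recipe)
            assert {
                frozenset(c) for c in label_brute(vals > 0, 26)
            } == {
                frozenset(c) for c in label_brute(out.positive_mask, 26)
            }
            np.testing.assert_array_equal(out.positive_mask, vals > 0)


class TestFdrThreshold:
    def test_hand_bh_stepup(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.6])
        z = stats.norm.isf(p).reshape(5, 1, 1)
        out = fv.fdr_threshold(_zmap(z), q=0.05, side="greater")
        np.testing.assert_array_equal(
            out.positive_mask.ravel(), [True, True, False, False, False]
        )

    def test_all_unit_pvalues_reject_nothing(self):
        z = np.full((3, 3, 3), -8.0)
        out = fv.fdr_threshold(_zmap(z), q=0.05, side="greater")
        assert not out.positive_mask.any()

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = rng.integers(3, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            z = stats.norm.isf(p).reshape(m, 1, 1)
            out = fv.fdr_threshold(_zmap(z), q=0.05, side="greater")
            np.testing.assert_array_equal(
                out.positive_mask.ravel(), bh_reject_brute(p, 0.05)
            )

    def test_less_side_populates_negative_mask(self):
        z = np.array([-5.0, 0.0, 5.0]).reshape(3, 1, 1)
        out = fv.fdr_threshold(_zmap(z), q=0.05, side="less")
        assert out.negative_mask.ravel().tolist() == [True, False, False]
        assert not out.positive_mask.any()

    def test_fdp_controlled_under_independent_nulls(self):
        """Empirical false-discovery proportion stays below q + 0.02."""
        rng = np.random.default_rng(7)
        m, m1 = 400, 80
        fdps = []
        for _ in range(150):
            z = rng.standard_normal(m)
            z[:m1] += 3.5
            out = fv.fdr_threshold(_zmap(z.reshape(m, 1, 1)), q=0.05, side="greater")
            rej = out.positive_mask.ravel()
            if rej.any():
                fdps.append(rej[m1:].sum() / rej.sum())
            else:
                fdps.append(0.0)
        assert np.mean(fdps) <= 0.05 + 0.02

    def test_empty_mask_rejected(self):
        with pytest.raises(InferenceError, match="mask"):
            fv.fdr_threshold(
                fv.StatMap(np.zeros((2, 2, 2)), "z", None, np.zeros((2, 2, 2), bool)),
                q=0.05,
            )
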