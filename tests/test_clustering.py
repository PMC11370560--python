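import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm
from sklearn.decomposition import PCA as SkPCA

from sipflow import phenotype_clustering as pc
from sipflow.phenotype_clustering import (
    BEHAVIOR_PARAMS,
    agreement_metrics,
    cluster_by_group_table,
    kmeans_fit,
    pca_reduce,
    select_components,
    stability_table,
    standardize,
)


def behavior_frame(values, tags=None):
    df = pd.DataFrame(np.asarray(values, dtype=float), columns=list(BEHAVIOR_PARAMS))
    df.insert(0, "tag", tags or [f"a{i}" for i in range(len(df))])
    return df


class TestStandardize:
    def test_columns_zero_mean_unit_sd(self, rng):
        table = behavior_frame(rng.uniform(1, 50, size=(20, 12)))
        z, _ = standardize(table)
        assert np.abs(z.mean(axis=0)).max() < 1e-9
        assert np.abs(z.std(axis=0) - 1).max() < 1e-9

    def test_constant_column_names_parameter(self, rng):
        vals = rng.uniform(1, 5, size=(10, 12))
        vals[:, 3] = 2.0
        with pytest.raises(ValueError, match="OFB CE"):
            standardize(behavior_frame(vals))

    def test_inverse_transform_round_trip(self, rng):
        table = behavior_frame(rng.uniform(1, 50, size=(15, 12)))
        z, model = standardize(table)
        back = z * model.sds + model.means
        assert np.allclose(back, table[list(BEHAVIOR_PARAMS)].to_numpy(), atol=1e-9)


class TestPCA:
    def test_rank_one_data_explained_by_first_component(self, rng):
        t = rng.normal(size=30)
        z = np.column_stack([t, 2 * t])
        z = (z - z.mean(0)) / z.std(0)
        model, _ = pca_reduce(z)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_ratios_match_independent_eigendecomposition(self, rng):
        z, _ = standardize(behavior_frame(rng.uniform(0, 10, size=(10, 12))))
        model, scores = pca_reduce(z)
        evals = np.sort(np.linalg.eigvalsh(np.cov(z.T, bias=True)))[::-1]
        assert np.allclose(model.explained_variance_ratio, evals / evals.sum(), atol=1e-8)
        assert model.explained_variance_ratio.sum() == pytest.approx(1.0)
        # orthonormal loadings
        assert np.allclose(model.loadings.T @ model.loadings, np.eye(12), atol=1e-8)

    def test_matches_sklearn_up_to_sign(self, rng):
        z, _ = standardize(behavior_frame(rng.uniform(0, 10, size=(25, 12))))
        model, scores = pca_reduce(z)
        sk = SkPCA(n_components=12).fit(z)
        assert np.allclose(
            model.explained_variance_ratio, sk.explained_variance_ratio_, atol=1e-8
        )
        for j in range(3):
            ours, theirs = model.loadings[:, j], sk.components_[j]
            assert min(np.abs(ours - theirs).max(), np.abs(ours + theirs).max()) < 1e-8

    def test_ratio_invariant_to_row_order(self, rng):
        z, _ = standardize(behavior_frame(rng.uniform(0, 10, size=(25, 12))))
        m1, _ = pca_reduce(z)
        m2, _ = pca_reduce(z[rng.permutation(25)])
        assert np.allclose(m1.explained_variance_ratio, m2.explained_variance_ratio)


class TestSelectComponents:
    @pytest.mark.parametrize(
        "ratios,threshold,expected",
        [
            ((0.5, 0.2, 0.1, 0.1, 0.1), 0.75, 3),
            ((0.8, 0.1, 0.1), 0.75, 1),
            ((0.4, 0.3, 0.3), 0.0, 1),
            ((0.25, 0.25, 0.25, 0.25), 0.75, 4),
        ],
    )
    def test_smallest_m_exceeding_threshold(self, ratios, threshold, expected):
        assert select_components(ratios, threshold) == expected

    def test_empty_ratios_rejected(self):
        with pytest.raises(ValueError):
            select_components([])


class TestKMeans:
    def test_k1_centroid_is_mean_inertia_total_ss(self, rng):
        x = rng.normal(size=(30, 3))
        fit = kmeans_fit(x, 1, seed=0)
        assert np.allclose(fit.centroids[0], x.mean(axis=0))
        assert fit.inertia == pytest.approx(((x - x.mean(0)) ** 2).sum())

    def test_two_separated_pairs_found_exactly(self):
        fit = kmeans_fit(np.array([0.0, 0.0, 10.0, 10.0]), 2, seed=0)
        assert sorted(fit.centroids.ravel()) == [0.0, 10.0]
        assert fit.inertia == pytest.approx(0.0)
        assert fit.labels[0] == fit.labels[1] != fit.labels[2] == fit.labels[3]

    def test_matches_exhaustive_partition_oracle(self, rng):
        # best 2-partition of 8 1-D points by brute force
        from itertools import combinations

        x = rng.normal(size=8)
        best = np.inf
        for r in range(1, 8):
            for subset in combinations(range(8), r):
                a = x[list(subset)]
                b = np.delete(x, list(subset))
                ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
                best = min(best, ss)
        fit = kmeans_fit(x, 2, n_init=20, seed=0)
        assert fit.inertia == pytest.approx(best, rel=1e-9)

    def test_every_cluster_nonempty(self, rng):
        x = rng.normal(size=(12, 2))
        fit = kmeans_fit(x, 5, seed=3)
        assert set(fit.labels) == set(range(5))

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValueError):
            kmeans_fit(np.zeros((3, 2)), 4)


class TestAgreementMetrics:
    def test_identical_labelings_all_one(self):
        s = agreement_metrics([0, 1, 2, 0, 1, 2], [2, 0, 1, 2, 0, 1])
        assert all(v == pytest.approx(1.0) for v in s)

    def test_crossed_pairs_ari_is_minus_half(self):
        assert agreement_metrics([0, 0, 1, 1], [0, 1, 0, 1]).ari == pytest.approx(-0.5)

    def test_single_cluster_has_zero_homogeneity(self):
        s = agreement_metrics([0, 0, 1, 1], [0, 0, 0, 0])
        assert s.homogeneity == pytest.approx(0.0)

    def test_matches_sklearn_on_random_labelings(self, rng):
        for _ in range(5):
            a = rng.integers(0, 4, size=60)
            b = rng.integers(0, 3, size=60)
            ours = agreement_metrics(a, b)
            assert ours.homogeneity == pytest.approx(skm.homogeneity_score(a, b))
            assert ours.completeness == pytest.approx(skm.completeness_score(a, b))
            assert ours.v_measure == pytest.approx(skm.v_measure_score(a, b))
            assert ours.ari == pytest.approx(skm.adjusted_rand_score(a, b))
            assert ours.ami == pytest.approx(
                skm.adjusted_mutual_info_score(a, b), abs=1e-9
            )

    def test_independent_labelings_near_zero_ari(self, rng):
        a = rng.integers(0, 3, size=1000)
        b = rng.integers(0, 3, size=1000)
        assert abs(agreement_metrics(a, b).ari) < 0.05

    def test_label_renumbering_gives_ari_one(self, rng):
        a = rng.integers(0, 3, size=50)
        assert agreement_metrics(a, 2 - a).ari == pytest.approx(1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            agreement_metrics([0, 1], [0, 1, 2])


class TestStability:
    @staticmethod
    def _blobs(rng, n_per=30, sep=20.0):
        centers = np.array([[0, 0], [sep, 0], [0, sep]])
        pts = np.vstack([c + rng.normal(size=(n_per, 2)) for c in centers])
        return pts

    def test_separated_blobs_stable_at_k3(self, rng):
        scores = self._blobs(rng)
        res = stability_table(scores, k_range=range(3, 5), n_boot=10, n_init=5, seed=0)
        assert res.recommended_k == 3
        assert (res.table.loc[3] >= 0.99).all()

    def test_same_seed_identical_table(self, rng):
        scores = self._blobs(rng, n_per=15)
        t1 = stability_table(scores, k_range=range(3, 5), n_boot=5, n_init=3, seed=7)
        t2 = stability_table(scores, k_range=range(3, 5), n_boot=5, n_init=3, seed=7)
        pd.testing.assert_frame_equal(t1.table, t2.table)
        assert t1.recommended_k == t2.recommended_k

    def test_metric_column_order(self, rng):
        res = stability_table(
            self._blobs(rng, n_per=10), k_range=range(3, 4), n_boot=3, n_init=2, seed=0
        )
        assert list(res.table.columns) == [
            "homogeneity", "completeness", "v_measure", "ari", "ami"
        ]


class TestClusterBySex:
    def test_reported_contingency_table_chi2(self):
        """Cluster-by-sex composition 7/4, 1/5, 24/15 gives chi2 4.5, p 0.1."""
        roster = pd.DataFrame(
            {
                "tag": [f"a{i}" for i in range(56)],
                "sex": ["M"] * 7 + ["F"] * 4 + ["M"] * 1 + ["F"] * 5
                + ["M"] * 24 + ["F"] * 15,
                "body_weight_g": 25.0,
                "cage": "c",
            }
        )
        labels = pd.Series([0] * 11 + [1] * 6 + [2] * 39, index=roster["tag"])
        table, res = cluster_by_group_table(labels, roster)
        assert round(res.statistic, 1) == 4.5
        assert res.df == 2
        assert round(res.p, 1) == 0.1

    def test_single_sex_degenerate(self):
        from sipflow.stats_engine import DegenerateTableError

        roster = pd.DataFrame(
            {"tag": ["a", "b", "c", "d"], "sex": ["M"] * 4,
             "body_weight_g": 25.0, "cage": "c"}
        )
        labels = pd.Series([0, 0, 1, 1], index=roster["tag"])
        with pytest.raises(DegenerateTableError):
            cluster_by_group_table(labels, roster)

    def test_proportional_rows_give_zero(self):
        roster = pd.DataFrame(
            {"tag": [f"a{i}" for i in range(8)],
             "sex": ["M", "F"] * 4, "body_weight_g": 25.0, "cage": "c"}
        )
        labels = pd.Series([0, 0, 0, 0, 1, 1, 1, 1], index=roster["tag"])
        _, res = cluster_by_group_table(labels, roster)
        assert res.statistic == pytest.approx(0.0)
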