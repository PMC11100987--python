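import io

import numpy as np
import pytest

import mlgmsim as m
from mlgmsim.model_spec import InvalidDesignError
from mlgmsim.simulator import dataset_csv_bytes


class TestDesignCondition:
    @pytest.mark.parametrize(
        "ng,small,large,n_total",
        [(50, 5, 15, 500), (100, 10, 30, 2000), (200, 25, 75, 10000)],
    )
    def test_study_grid_counts_and_cv(self, ng, small, large, n_total):
        cond = m.DesignCondition(ng, small, large)
        assert cond.n_total == n_total
        assert cond.size_cv == pytest.approx(0.5, abs=1e-15)

    def test_draw_cluster_sizes(self):
        sizes = m.draw_cluster_sizes(m.DesignCondition(50, 5, 15))
        assert list(sizes[:25]) == [5] * 25 and list(sizes[25:]) == [15] * 25
        np.testing.assert_array_equal(m.draw_cluster_sizes(m.DesignCondition(2, 1, 3)), [1, 3])

    def test_odd_group_count_rejected(self):
        with pytest.raises(InvalidDesignError):
            m.DesignCondition(51, 5, 15)

    def test_default_grid_has_nine_cells(self):
        conds = m.study_conditions()
        assert len(conds) == 9
        assert all(c.large_size == 3 * c.small_size for c in conds)


class TestSimulateDataset:
    def test_degenerate_model_reproduces_mean_curve(self, basis):
        zero_w = m.LevelParams(np.zeros(3), np.zeros((3, 3)), np.zeros(5))
        between = m.LevelParams(np.array([49.96, 4.32, -0.13]), np.zeros((3, 3)), np.zeros(5))
        spec0 = m.MLGMSpec(basis=basis, within=zero_w, between=between)
        ds = m.simulate_dataset(spec0, m.DesignCondition(4, 2, 6), seed=0)
        expected = basis.loading_matrix @ between.latent_mean
        np.testing.assert_allclose(ds.y, np.tile(expected, (ds.n_total, 1)), atol=1e-12)

    def test_same_seed_byte_identical_csv(self, spec):
        cond = m.DesignCondition(10, 5, 15)
        a = dataset_csv_bytes(m.simulate_dataset(spec, cond, 99))
        b = dataset_csv_bytes(m.simulate_dataset(spec, cond, 99))
        c = dataset_csv_bytes(m.simulate_dataset(spec, cond, 100))
        assert a == b and a != c

    def test_cluster_sizes_match_condition(self, spec):
        cond = m.DesignCondition(6, 2, 6)
        ds = m.simulate_dataset(spec, cond, 1)
        sizes = np.bincount(ds.cluster_ids)[1:]
        assert sorted(sizes) == [2, 2, 2, 6, 6, 6]

    def test_total_variance_matches_population(self, spec):
        mom = m.implied_moments(spec)
        ds = m.simulate_dataset(spec, m.DesignCondition(2000, 25, 75), seed=5)
        total = mom.within_cov[0, 0] + mom.between_cov[0, 0]
        assert ds.y[:, 0].var() == pytest.approx(total, rel=0.02)


class TestMomentMatrices:
    def test_pooled_within_zero_when_members_equal_cluster_mean(self):
        y = np.repeat(np.array([[1.0, 2.0], [3.0, 4.0]]), 3, axis=0)
        ds = m.ClusteredDataset(np.repeat([1, 2], 3), np.tile([1, 2, 3], 2), y)
        np.testing.assert_allclose(m.pooled_within_cov(ds), 0, atol=1e-12)

    def test_pooled_within_hand_example(self):
        # clusters {0,2} and {1,3} on one wave: scatter 2+2 over N-G=2
        ds = m.ClusteredDataset(
            np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2]), np.array([[0.0], [2.0], [1.0], [3.0]])
        )
        assert m.pooled_within_cov(ds)[0, 0] == pytest.approx(2.0)

    def test_between_cov_hand_example(self):
        # 2 clusters of size 2 with means 0 and 2, grand mean 1 -> 4
        ds = m.ClusteredDataset(
            np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2]), np.array([[-1.0], [1.0], [1.0], [3.0]])
        )
        assert m.between_cov(ds)[0, 0] == pytest.approx(4.0)

    def test_between_cov_zero_when_cluster_means_equal(self):
        y = np.array([[-1.0], [1.0], [-2.0], [2.0]])
        ds = m.ClusteredDataset(np.array([1, 1, 2, 2]), np.array([1, 2, 1, 2]), y)
        np.testing.assert_allclose(m.between_cov(ds), 0, atol=1e-12)

    def test_balanced_between_expectation(self, spec):
        # E[S*_B] = n Sigma_B + Sigma_W for balanced clusters of size n
        mom = m.implied_moments(spec)
        n = 20
        ds = m.simulate_dataset(spec, m.DesignCondition(16000, n, n), seed=3)
        expected = n * mom.between_cov + mom.within_cov
        np.testing.assert_allclose(m.between_cov(ds), expected, rtol=0.05, atol=0.5)


class TestSufficientStats:
    def test_two_singleton_classes(self, spec):
        ds = m.simulate_dataset(spec, m.DesignCondition(2, 1, 3), seed=2)
        st = m.sufficient_stats(ds)
        assert [(c.size, c.count) for c in st.size_classes] == [(1, 1), (3, 1)]
        for c in st.size_classes:
            np.testing.assert_allclose(c.scatter, 0, atol=1e-12)

    def test_class_decomposition_matches_direct_scatter(self, spec):
        # per class: C_d + G_d (m_d - mu)(m_d - mu)' == sum_g (ybar_g - mu)(..)'
        ds = m.simulate_dataset(spec, m.DesignCondition(10, 5, 15), seed=21)
        st = m.sufficient_stats(ds)
        mu = np.linspace(-1, 1, ds.n_waves)
        sizes = np.bincount(ds.cluster_ids)[1:]
        means = np.array([ds.y[ds.cluster_ids == g + 1].mean(axis=0) for g in range(10)])
        for cls in st.size_classes:
            sel = sizes == cls.size
            direct = sum(np.outer(mm - mu, mm - mu) for mm in means[sel])
            viaclass = cls.scatter + cls.count * np.outer(cls.mean - mu, cls.mean - mu)
            np.testing.assert_allclose(viaclass, direct, atol=1e-10)

    def test_counts_and_grand_mean(self, spec):
        ds = m.simulate_dataset(spec, m.DesignCondition(200, 25, 75), seed=8)
        st = m.sufficient_stats(ds)
        assert sum(c.count for c in st.size_classes) == st.n_groups == 200
        assert sum(c.size * c.count for c in st.size_classes) == st.n_total == 10000
        np.testing.assert_allclose(st.grand_mean(), ds.y.mean(axis=0), atol=1e-10)


class TestCsvRoundTrip:
    def test_round_trip(self, spec):
        ds = m.simulate_dataset(spec, m.DesignCondition(4, 2, 6), seed=13)
        buf = io.StringIO()
        m.write_dataset_csv(ds, buf)
        buf.seek(0)
        back = m.read_dataset_csv(buf)
        np.testing.assert_allclose(back.y, ds.y, atol=1e-12)
        np.testing.assert_array_equal(back.cluster_ids, ds.cluster_ids)

    def test_bad_header_rejected(self):
        with pytest.raises(InvalidDesignError):
            m.read_dataset_csv(io.StringIO("a,b,V1\n1,1,0.5\n"))
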