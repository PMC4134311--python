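import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from icanet.physio import pooled_ttest_from_summaries
from icanet.stats import (
    StatMap,
    StatsConfig,
    behavioral_group_tests,
    montecarlo_min_cluster,
    roi_behavior_correlation,
    roi_group_ttest,
    threshold_and_label,
    voxelwise_group_anova,
)
from icanet.volume import Grid


def _small_mask(n=16, radius=6.5):
    grid = np.arange(n) - (n - 1) / 2
    X, Y, Z = np.meshgrid(grid, grid, grid, indexing="ij")
    return X**2 + Y**2 + Z**2 <= radius**2


def _statmap_from_t(t_vol, mask, df2=33):
    grid = Grid(origin=(0.0, 0.0, 0.0), voxel_mm=3.0, shape=t_vol.shape)
    return StatMap(
        t=t_vol, f=t_vol**2, df=(1, df2), grid=grid, mask=mask,
        zero_variance=np.zeros(t_vol.shape, dtype=bool),
    )


class TestStatsConfig:
    def test_defaults_valid(self):
        cfg = StatsConfig()
        assert cfg.voxel_p == 0.005
        assert cfg.sim_fwhm_vox == pytest.approx(1.842)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            StatsConfig(voxel_p=0.5, alpha=0.05)
        with pytest.raises(ValueError):
            StatsConfig(n_iterations=10)
        with pytest.raises(ValueError):
            StatsConfig(connectivity=10)


class TestVoxelwiseAnova:
    def test_identical_groups_give_zero_f(self):
        rng = np.random.default_rng(0)
        mask = np.ones((4, 4, 4), dtype=bool)
        grid = Grid(origin=(0, 0, 0), voxel_mm=3.0, shape=(4, 4, 4))
        z = rng.standard_normal((5, 64))
        sm = voxelwise_group_anova(z, z.copy(), mask, grid)
        assert np.allclose(sm.f, 0.0, atol=1e-12)

    def test_f_equals_t_squared_and_matches_scipy(self):
        rng = np.random.default_rng(1)
        mask = np.ones((3, 3, 3), dtype=bool)
        grid = Grid(origin=(0, 0, 0), voxel_mm=3.0, shape=(3, 3, 3))
        a = rng.standard_normal((6, 27)) + 0.5
        b = rng.standard_normal((8, 27))
        sm = voxelwise_group_anova(a, b, mask, grid)
        assert np.allclose(sm.f, sm.t**2, atol=1e-8)
        ref = sps.ttest_ind(a, b, axis=0, equal_var=True)
        assert np.allclose(sm.t[mask], ref.statistic, atol=1e-10)
        assert sm.df == (1, 12)

    def test_zero_variance_flagged(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        grid = Grid(origin=(0, 0, 0), voxel_mm=3.0, shape=(2, 2, 2))
        a = np.ones((3, 8))
        b = np.zeros((3, 8))
        with pytest.warns(UserWarning, match="zero within-group variance"):
            sm = voxelwise_group_anova(a, b, mask, grid)
        assert np.all(sm.zero_variance[mask])
        assert np.allclose(sm.t, 0.0)

    def test_small_groups_rejected(self):
        mask = np.ones((2, 2, 2), dtype=bool)
        grid = Grid(origin=(0, 0, 0), voxel_mm=3.0, shape=(2, 2, 2))
        with pytest.raises(ValueError):
            voxelwise_group_anova(np.ones((1, 8)), np.ones((4, 8)), mask, grid)


class TestMonteCarloMinCluster:
    def test_tiny_voxel_p_gives_min_cluster_one(self):
        mask = _small_mask()
        cfg = StatsConfig(voxel_p=1e-12, n_iterations=100, sim_seed=0)
        res = montecarlo_min_cluster(mask, cfg)
        assert res.min_cluster_size == 1
        assert res.attained_alpha == 0.0

    def test_monotone_in_voxel_p(self):
        mask = _small_mask()
        sizes = []
        for voxel_p in (0.02, 0.005, 0.001):
            cfg = StatsConfig(voxel_p=voxel_p, n_iterations=500, sim_seed=1)
            sizes.append(montecarlo_min_cluster(mask, cfg).min_cluster_size)
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_deterministic_given_seed(self):
        mask = _small_mask()
        cfg = StatsConfig(n_iterations=200, sim_seed=2)
        r1 = montecarlo_min_cluster(mask, cfg)
        r2 = montecarlo_min_cluster(mask, cfg)
        assert r1.min_cluster_size == r2.min_cluster_size
        assert np.array_equal(r1.max_cluster_sizes, r2.max_cluster_sizes)

    def test_attained_alpha_below_alpha(self):
        mask = _small_mask()
        cfg = StatsConfig(n_iterations=300, sim_seed=3)
        res = montecarlo_min_cluster(mask, cfg)
        assert res.attained_alpha <= cfg.alpha
        assert res.mask_voxels == int(mask.sum())

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            montecarlo_min_cluster(np.zeros((4, 4, 4), dtype=bool), StatsConfig())


class TestThresholdAndLabel:
    def test_empty_suprathreshold_set(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        table = threshold_and_label(_statmap_from_t(np.zeros((6, 6, 6)), mask),
                                    voxel_p=0.005, min_cluster=5)
        assert len(table) == 0

    def test_cube_of_27_survives_min_22(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        t = np.zeros((9, 9, 9))
        t[3:6, 3:6, 3:6] = 5.0
        table = threshold_and_label(_statmap_from_t(t, mask), 0.005, 22)
        assert len(table) == 1
        row = table.clusters.iloc[0]
        assert row["size_voxels"] == 27
        assert row["sign"] == 1
        assert row["peak_t"] == pytest.approx(5.0)

    def test_corner_joined_blobs_connectivity(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 5.0
        t[3:5, 3:5, 3:5] = 5.0  # touches the first block only at a corner
        one = threshold_and_label(_statmap_from_t(t, mask), 0.005, 1, connectivity=26)
        two = threshold_and_label(_statmap_from_t(t, mask), 0.005, 1, connectivity=6)
        assert len(one) == 1
        assert len(two) == 2

    def test_signs_labelled_separately(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        t = np.zeros((8, 8, 8))
        t[1:3, 1:3, 1:3] = 5.0
        t[5:7, 5:7, 5:7] = -5.0
        table = threshold_and_label(_statmap_from_t(t, mask), 0.005, 1)
        assert sorted(table.clusters["sign"]) == [-1, 1]

    def test_min_cluster_filters(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        t = np.zeros((8, 8, 8))
        t[1, 1, 1] = 5.0  # singleton cluster
        table = threshold_and_label(_statmap_from_t(t, mask), 0.005, 2)
        assert len(table) == 0


class TestRoiGroupTtest:
    def test_identical_groups(self):
        rng = np.random.default_rng(4)
        z = rng.standard_normal((5, 50))
        roi = np.zeros(50, dtype=bool)
        roi[:10] = True
        res = roi_group_ttest(z, z.copy(), roi)
        assert res["t"] == pytest.approx(0.0)

    def test_left_ipl_row_summaries(self):
        # Printed group means 1 and 2.15 with SEM 0.28 in groups of 16 and 19;
        # converting SEM to SD gives a pooled |t| in the high-2 range.
        t, _ = pooled_ttest_from_summaries(
            1.0, 0.28 * np.sqrt(16), 16, 2.15, 0.28 * np.sqrt(19), 19
        )
        assert 2.7 <= abs(t) <= 3.1

    def test_planted_deficit_detected(self):
        rng = np.random.default_rng(5)
        roi = np.zeros(200, dtype=bool)
        roi[:40] = True
        a = rng.standard_normal((16, 200))
        b = rng.standard_normal((19, 200))
        b[:, roi] += 1.0  # HC exceed EDp inside the ROI
        res = roi_group_ttest(a, b, roi)
        assert res["t"] < 0
        assert res["p"] < 0.05
        assert res["mean_HC"] > res["mean_EDp"]

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            roi_group_ttest(np.ones((3, 10)), np.ones((3, 10)), np.zeros(10, bool))


class TestBehavioralGroupTests:
    @staticmethod
    def _table():
        rng = np.random.default_rng(6)
        rows = []
        for g, n, shift in (("EDp", 16, 0.0), ("HC", 19, 1.0)):
            for i in range(n):
                rows.append({
                    "subject_id": f"{g}{i}",
                    "group": g,
                    "score": rng.standard_normal() + shift,
                    "flat": 1.0,
                })
        return pd.DataFrame(rows)

    def test_matches_scipy(self):
        df = self._table()
        out = behavioral_group_tests(df, columns=["score"])
        a = df.loc[df.group == "EDp", "score"]
        b = df.loc[df.group == "HC", "score"]
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert out.loc[0, "t"] == pytest.approx(ref.statistic)
        assert out.loc[0, "p"] == pytest.approx(ref.pvalue)

    def test_printed_summary_rows(self):
        t_age, _ = pooled_ttest_from_summaries(33.87, 11.2, 16, 33.57, 11.4, 19)
        assert t_age == pytest.approx(0.08, abs=0.05)
        t_iief, _ = pooled_ttest_from_summaries(14.5, 5.5, 16, 24.0, 0.93, 19)
        assert t_iief == pytest.approx(-7.4, abs=0.2)

    def test_missing_column_warns(self):
        with pytest.warns(UserWarning, match="missing"):
            out = behavioral_group_tests(self._table(), columns=["absent_score"])
        assert len(out) == 0

    def test_missing_group_rejected(self):
        df = self._table()
        with pytest.raises(ValueError):
            behavioral_group_tests(df[df.group == "HC"])


class TestRoiBehaviorCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = roi_behavior_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            roi_behavior_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            roi_behavior_correlation(np.arange(2.0), np.arange(2.0))

    def test_type_one_rate_near_five_percent(self):
        rng = np.random.default_rng(7)
        n_reps, n = 1000, 16
        hits = 0
        for _ in range(n_reps):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            _, p = roi_behavior_correlation(x, y)
            hits += p < 0.05
        rate = hits / n_reps
        se = np.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) <= 3 * se
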