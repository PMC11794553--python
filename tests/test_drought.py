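import numpy as np
import pytest

from paleoiso.drought import (
    build_drought_index,
    default_con_rule,
    default_wcon_rule,
    monthly_con,
    quantile_classes,
    validate_rule,
    weighted_con,
)
from paleoiso.hydrology import fill_sinks, flow_accumulation
from paleoiso.raster import MonthlyClimate, RasterGrid, minmax_rescale
from paleoiso.synthetic import SyntheticConfig, generate_climate, generate_terrain


def grid_of(values):
    return RasterGrid(values=np.asarray(values, dtype=float))


def make_climate(p_fields, t_fields):
    return MonthlyClimate(
        p=[grid_of(f) for f in p_fields], t=[grid_of(f) for f in t_fields]
    )


class TestQuantileClasses:
    def test_1_to_100_rank_classification(self):
        vals = np.arange(1, 101, dtype=float).reshape(10, 10)
        classes = quantile_classes(grid_of(vals)).values
        # brute-force rank oracle with right-closed intervals
        flat = vals.ravel()
        q = np.quantile(flat, [0.25, 0.5, 0.75])
        expected = np.array([np.sum(q < x) + 1 for x in flat]).reshape(10, 10)
        np.testing.assert_array_equal(classes, expected)
        for k in (1, 2, 3, 4):
            assert 20 <= (classes == k).sum() <= 30

    def test_constant_grid_single_class_with_warning(self):
        with pytest.warns(UserWarning):
            classes = quantile_classes(grid_of(np.full((4, 4), 3.0))).values
        assert np.unique(classes).size == 1

    def test_four_distinct_values_map_to_four_classes(self):
        classes = quantile_classes(grid_of([[1.0, 2.0], [3.0, 4.0]])).values
        np.testing.assert_array_equal(classes, [[1, 2], [3, 4]])

    def test_nodata_preserved(self):
        g = RasterGrid(values=np.array([[1.0, 2.0], [3.0, -9999.0]]), nodata=-9999.0)
        with pytest.warns(UserWarning):
            out = quantile_classes(g)
        assert out.values[1, 1] == -9999.0

    def test_raising_one_cell_never_lowers_its_class(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            vals = rng.uniform(0, 1, size=(6, 6))
            i, j = rng.integers(6), rng.integers(6)
            before = quantile_classes(grid_of(vals)).values[i, j]
            vals2 = vals.copy()
            vals2[i, j] += rng.uniform(0, 1)
            after = quantile_classes(grid_of(vals2)).values[i, j]
            assert after >= before


class TestRules:
    def test_default_con_rule_extremes(self):
        rule = default_con_rule()
        assert rule[3, 0] == 4  # wettest: P class 4, T class 1
        assert rule[0, 3] == 1  # driest: P class 1, T class 4

    def test_default_rules_are_monotone(self):
        validate_rule(default_con_rule(), decreasing_axis=1)
        validate_rule(default_wcon_rule())

    def test_non_monotone_rule_rejected(self):
        bad = default_wcon_rule().copy()
        bad[0, 0], bad[3, 3] = 4, 1
        with pytest.raises(ValueError, match="monotone"):
            validate_rule(bad)

    def test_out_of_range_rule_rejected(self):
        bad = np.full((4, 4), 5)
        with pytest.raises(ValueError):
            validate_rule(bad)


class TestMonthlyCon:
    def make(self, seed=0, shape=(12, 12)):
        rng = np.random.default_rng(seed)
        p = [rng.uniform(20, 120, size=shape) for _ in range(12)]
        t = [rng.uniform(-2, 25, size=shape) for _ in range(12)]
        return make_climate(p, t)

    def test_extreme_cells_forced(self):
        clim = self.make(1)
        con = monthly_con(clim, 1).values
        p_cls = quantile_classes(minmax_rescale(clim.p[0])).values
        t_cls = quantile_classes(minmax_rescale(clim.t[0])).values
        assert (con[(p_cls == 4) & (t_cls == 1)] == 4).all()
        assert (con[(p_cls == 1) & (t_cls == 4)] == 1).all()

    def test_matches_cellwise_lookup_oracle(self):
        clim = self.make(2)
        rule = default_con_rule()
        con = monthly_con(clim, 5).values
        p_cls = quantile_classes(minmax_rescale(clim.p[4])).values.astype(int)
        t_cls = quantile_classes(minmax_rescale(clim.t[4])).values.astype(int)
        expected = np.array(
            [rule[p - 1, t - 1] for p, t in zip(p_cls.ravel(), t_cls.ravel())]
        ).reshape(con.shape)
        np.testing.assert_array_equal(con, expected)

    def test_invalid_month_rejected(self):
        with pytest.raises(ValueError):
            monthly_con(self.make(), 13)


class TestWeightedCon:
    def test_mid_quartile_acc_is_identity_on_qc(self):
        rng = np.random.default_rng(3)
        con = grid_of(rng.permutation(np.repeat([1, 2, 3, 4], 25)).reshape(10, 10))
        acc = grid_of(rng.uniform(0, 1, size=(10, 10)))
        wcon = weighted_con(con, acc)
        qa = quantile_classes(acc).values
        qc = quantile_classes(con).values
        mid = (qa == 2) | (qa == 3)
        np.testing.assert_array_equal(wcon.values[mid], qc[mid])
        # balanced CON classes make QC the identity of CON
        np.testing.assert_array_equal(qc, con.values)

    def test_top_quartile_acc_raises_one_class(self):
        rng = np.random.default_rng(4)
        con = grid_of(rng.permutation(np.repeat([1, 2, 3, 4], 25)).reshape(10, 10))
        acc = grid_of(rng.uniform(0, 1, size=(10, 10)))
        wcon = weighted_con(con, acc).values
        qa = quantile_classes(acc).values
        qc = quantile_classes(con).values
        top = qa == 4
        np.testing.assert_array_equal(wcon[top], np.clip(qc[top] + 1, 1, 4))
        bottom = qa == 1
        np.testing.assert_array_equal(wcon[bottom], np.clip(qc[bottom] - 1, 1, 4))

    def test_matches_lookup_oracle(self):
        rng = np.random.default_rng(5)
        con = grid_of(rng.integers(1, 5, size=(8, 8)))
        acc = grid_of(rng.uniform(0, 1, size=(8, 8)))
        rule = default_wcon_rule()
        wcon = weighted_con(con, acc).values
        qa = quantile_classes(acc).values.astype(int)
        qc = quantile_classes(con).values.astype(int)
        expected = rule[qa - 1, qc - 1]
        np.testing.assert_array_equal(wcon, expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_con(grid_of(np.ones((3, 3))), grid_of(np.ones((4, 4))))


class TestBuildDroughtIndex:
    def setup_flow(self, cfg):
        terrain = generate_terrain(cfg)
        filled = fill_sinks(terrain)
        weights = terrain.with_values(np.ones(terrain.shape))
        return flow_accumulation(filled, weights)

    def test_identical_months_give_identical_wcon(self):
        cfg = SyntheticConfig(
            seed=2, grid_shape=(16, 16), p_seasonal_amplitude=0.0, t_seasonal_amplitude=0.0
        )
        clim = generate_climate(cfg)
        flow = self.setup_flow(cfg)
        index = build_drought_index(clim, flow)
        for m in range(1, 12):
            np.testing.assert_array_equal(index.wcon[m].values, index.wcon[0].values)

    def test_uniform_precip_shift_leaves_classes_unchanged(self):
        cfg = SyntheticConfig(seed=3, grid_shape=(16, 16))
        clim = generate_climate(cfg)
        flow = self.setup_flow(cfg)
        base = build_drought_index(clim, flow)
        shifted = MonthlyClimate(
            p=[g.with_values(g.values + 100.0) for g in clim.p], t=clim.t
        )
        out = build_drought_index(shifted, flow)
        for m in range(12):
            np.testing.assert_array_equal(out.con[m].values, base.con[m].values)

    def test_wet_valley_scores_wetter_than_interfluve(self):
        # V-valley: high flow accumulation concentrates on the valley floor,
        # so the top-ACC-quartile rule must push its wCON above the slopes'.
        rr, cc = np.mgrid[0:15, 0:15]
        dem = RasterGrid(values=(np.abs(cc - 7) * 3.0 + (14 - rr) * 0.1).astype(float))
        filled = fill_sinks(dem)
        flow = flow_accumulation(filled, filled.with_values(np.ones(dem.shape)))
        rng = np.random.default_rng(0)
        p = [rng.uniform(50, 60, size=(15, 15)) for _ in range(12)]
        t = [rng.uniform(8, 12, size=(15, 15)) for _ in range(12)]
        index = build_drought_index(make_climate(p, t), flow)
        valley = np.abs(cc - 7) <= 1
        mean_wcon = np.stack([g.values for g in index.wcon]).mean(axis=0)
        assert mean_wcon[valley].mean() >= mean_wcon[~valley].mean()

    def test_thresholds_recorded_per_month(self):
        cfg = SyntheticConfig(seed=4, grid_shape=(12, 12))
        clim = generate_climate(cfg)
        index = build_drought_index(clim, self.setup_flow(cfg))
        assert len(index.p_thresholds) == 12
        assert all(len(t) == 3 for t in index.qa_thresholds)
        assert index.provenance["qc_quartiles"] == "per month"

    def test_save_writes_grids_and_sidecar(self, tmp_path):
        cfg = SyntheticConfig(seed=5, grid_shape=(10, 10))
        clim = generate_climate(cfg)
        index = build_drought_index(clim, self.setup_flow(cfg))
        out = index.save(tmp_path / "di")
        assert (out / "wcon_12.asc").exists()
        assert (out / "drought_index.json").exists()

    def test_class_frequencies_near_quarter_on_continuous_grid(self):
        rng = np.random.default_rng(8)
        acc = grid_of(rng.uniform(0, 1, size=(50, 50)))
        classes = quantile_classes(acc).values
        freqs = np.array([(classes == k).mean() for k in (1, 2, 3, 4)])
        np.testing.assert_allclose(freqs, 0.25, atol=0.02)
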