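"""Water bookkeeping, WUE and heatmap contracts."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phenovol import synthetic_data as sd, water_budget as wb
from phenovol.traits import db_series


def series(days, pre, post, pot_id="p", is_bare=False, fc=1200.0):
    days = np.asarray(days, float)
    n = days.size
    return sd.WeightSeries(
        pot_id=pot_id, is_bare=is_bare, fc_weight=fc, days=days,
        weight_pre_g=np.asarray(pre, float), weight_post_g=np.asarray(post, float),
        target_fraction=np.ones(n), true_evap_g=np.full(n - 1, np.nan),
        true_transp_g=np.full(n - 1, np.nan),
        truncated=np.zeros(n - 1, dtype=bool))


class TestIntervalLosses:
    def test_simple_difference(self):
        ws = series([0, 2], pre=[1200, 1150], post=[1200, 1180])
        out = wb.interval_losses(ws)
        assert out["loss_g"].tolist() == [50.0]
        assert not out["clipped"].any()

    def test_equal_weights_zero_loss(self):
        ws = series([0, 2], pre=[900, 900], post=[900, 900])
        assert wb.interval_losses(ws)["loss_g"].tolist() == [0.0]

    def test_negative_loss_clipped_and_flagged(self):
        ws = series([0, 2], pre=[1000, 1010], post=[1000, 1010])
        out = wb.interval_losses(ws)
        assert out["loss_g"].tolist() == [0.0]
        assert out["clipped"].all()

    def test_unordered_days_rejected(self):
        with pytest.raises(ValueError):
            series([2, 0], pre=[1, 1], post=[1, 1])

    def test_single_weighing_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            wb.interval_losses(series([0.0], pre=[1.0], post=[1.0]))

    def test_noise_free_simulation_recovers_truth(self, tomato_noise_free):
        for ws in tomato_noise_free.weights.values():
            losses = wb.interval_losses(ws)["loss_g"].to_numpy()
            np.testing.assert_allclose(
                losses, ws.true_evap_g + ws.true_transp_g, rtol=1e-9)


class TestEvaporationBaseline:
    def test_identical_bare_pots(self):
        bares = [series([0, 2, 4], [1200, 1192, 1184], [1200, 1192, 1184],
                        pot_id=f"b{i}", is_bare=True) for i in range(10)]
        np.testing.assert_allclose(
            wb.evaporation_baseline(bares, [0, 2, 4]), 8.0)

    def test_no_bare_pots_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="no bare-soil pots"):
            out = wb.evaporation_baseline([], [0, 2, 4])
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_heterogeneous_mean_matches_brute_force(self, rng):
        days = np.arange(0.0, 11.0, 2.0)
        bares, per_pot = [], []
        for i in range(4):
            losses = rng.uniform(2, 15, days.size - 1)
            post = np.empty(days.size)
            pre = np.empty(days.size)
            pre[0] = post[0] = 1200.0
            for k, lo in enumerate(losses):
                pre[k + 1] = post[k] - lo
                post[k + 1] = 1200.0
            bares.append(series(days, pre, post, pot_id=f"b{i}", is_bare=True))
            per_pot.append(losses)
        got = wb.evaporation_baseline(bares, days)
        np.testing.assert_allclose(got, np.mean(per_pot, axis=0), rtol=1e-12)

    def test_misaligned_days_rejected(self):
        bare = series([0, 2], [1, 1], [1, 1], is_bare=True)
        with pytest.raises(ValueError, match="misaligned"):
            wb.evaporation_baseline([bare], [0, 3])


class TestCumulativeTranspiration:
    def test_subtract_mode(self):
        out = wb.cumulative_transpiration([50, 60], [10, 10], "subtract_evap")
        np.testing.assert_array_equal(out, [40.0, 90.0])

    def test_evaporation_dominates_gives_zeros(self):
        out = wb.cumulative_transpiration([5, 8], [10, 10], "subtract_evap")
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_evapotranspiration_mode_cumulates_raw(self):
        out = wb.cumulative_transpiration([50, 60], [10, 10],
                                          "evapotranspiration")
        np.testing.assert_array_equal(out, [50.0, 110.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            wb.cumulative_transpiration([1, 2, 3], [1, 2], "subtract_evap")

    def test_nondecreasing_nonnegative(self, tomato_bundle):
        days = next(iter(tomato_bundle.weights.values())).days
        bares = [w for w in tomato_bundle.weights.values() if w.is_bare]
        ev = wb.evaporation_baseline(bares, days)
        for ws in tomato_bundle.weights.values():
            losses = wb.interval_losses(ws)["loss_g"].to_numpy()
            for mode in wb.MODES:
                cum = wb.cumulative_transpiration(losses, ev, mode)
                assert (cum >= -1e-12).all()
                assert (np.diff(cum) >= -1e-12).all()

    def test_both_modes_recover_generator_truth(self, tomato_noise_free):
        bund = tomato_noise_free
        days = next(iter(bund.weights.values())).days
        bares = [w for w in bund.weights.values() if w.is_bare]
        ev = wb.evaporation_baseline(bares, days)
        for ws in bund.weights.values():
            if ws.is_bare:
                continue
            losses = wb.interval_losses(ws)["loss_g"].to_numpy()
            np.testing.assert_allclose(
                wb.cumulative_transpiration(losses, ev, "subtract_evap"),
                np.cumsum(ws.true_transp_g), rtol=1e-9)
            np.testing.assert_allclose(
                wb.cumulative_transpiration(losses, ev, "evapotranspiration"),
                np.cumsum(ws.true_evap_g + ws.true_transp_g), rtol=1e-9)


class TestWUE:
    def test_simple_value(self):
        assert wb.compute_wue(100.0, 1100.0, 500.0) == pytest.approx(2.0)

    def test_no_growth_zero_wue(self):
        assert wb.compute_wue(500.0, 500.0, 123.0) == 0.0

    def test_zero_denominator_names_pot(self):
        with pytest.raises(ValueError, match="pot42"):
            wb.compute_wue(1.0, 2.0, 0.0, pot_id="pot42")

    def test_full_simulation_matches_closed_form(self):
        """Noise-free single plant: WUE equals delta-DB over summed true
        transpiration computed directly from generator parameters."""
        design, growth, wp = sd.wheat_ssd_preset(n_genotypes=1, replicates=1,
                                                 cv_noise=0.0,
                                                 factor_range=(1.0, 1.0))
        b = sd.generate_experiment(design, growth, wp, seed=0)
        traits_tbl, _ = db_series(b.counts, b.plants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wue = wb.wue_table(traits_tbl, b.weights, b.plants, t0=104,
                               mode="evapotranspiration")
        pid = b.plants["plant_id"].iloc[0]
        ws = b.weights[pid]
        t_tbl = traits_tbl[traits_tbl["plant_id"] == pid].set_index("day")["db"]
        last = wue[wue["plant_id"] == pid].iloc[-1]
        sel = ws.days[1:] > 105.0
        expect = (t_tbl[last["day"]] - t_tbl[105.0]) / \
            np.sum((ws.true_evap_g + ws.true_transp_g)[sel])
        assert last["wue"] == pytest.approx(expect, rel=1e-9)


class TestWUERatio:
    def test_identical_series_green(self):
        r, c = wb.wue_ratio(2.5, 2.5)
        assert r == 1.0 and c == "green"

    @pytest.mark.parametrize("ratio,expected", [
        (1.32, "green"), (1.0, "green"), (0.52, "red"), (-0.3, "red")])
    def test_heatmap_legend_boundaries(self, ratio, expected):
        assert wb.heat_class(ratio) == expected

    def test_zero_control_flagged_missing(self):
        r, c = wb.wue_ratio(1.0, 0.0)
        assert np.isnan(r) and c == ""

    def test_stressed_genotype_ranks_below_tolerant(self):
        """Factors 1.0 vs 0.6, noise-free: the 0.6 genotype's end-of-run WUE
        ratio is strictly smaller."""
        design, growth, wp = sd.wheat_ssd_preset(n_genotypes=2, cv_noise=0.0,
                                                 factor_range=(0.6, 1.0))
        b = sd.generate_experiment(design, growth, wp, seed=1)
        traits_tbl, _ = db_series(b.counts, b.plants)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            wue = wb.wue_table(traits_tbl, b.weights, b.plants, t0=104)
        ratio, _ = wb.wue_ratio_table(wb.wue_summary(wue),
                                      control_treatment="control")
        end = ratio[ratio.columns.max()]
        g_lo, g_hi = design.genotypes  # factors 0.6 and 1.0 in order
        assert end[g_lo] < end[g_hi]


class TestHeatmapExport:
    @staticmethod
    def ratio_table():
        idx = pd.Index(["g1", "g2", "g3"], name="genotype")
        return pd.DataFrame([[1.1, 1.0, 0.9, 0.8],
                             [1.2, np.nan, 0.7, 0.6],
                             [0.9, 0.8, 0.7, 0.52]],
                            index=idx, columns=[1.0, 2.0, 3.0, 4.0])

    def test_matrix_shape_and_missing_cells(self, tmp_path):
        ratio = self.ratio_table()
        out = tmp_path / "ratio.csv"
        wb.export_heatmap(ratio, out)
        back = pd.read_csv(out, index_col=0)
        assert back.shape == (3, 4)
        assert np.isnan(back.iloc[1, 1])  # empty field, not zero

    def test_cells_match_scalar_ratio_outputs(self, tomato_bundle):
        traits_tbl, _ = db_series(tomato_bundle.counts, tomato_bundle.plants)
        wue = wb.wue_table(traits_tbl, tomato_bundle.weights,
                           tomato_bundle.plants, t0=0)
        summ = wb.wue_summary(wue)
        ratio, classes = wb.wue_ratio_table(summ, control_genotype="UTC_70")
        ctl = summ[summ["genotype"] == "UTC_70"].set_index("day")["mean"]
        for g in ("P2148", "P2390"):
            sub = summ[summ["genotype"] == g].set_index("day")["mean"]
            for day in sub.index:
                r, c = wb.wue_ratio(sub[day], ctl[day])
                assert ratio.loc[g, day] == pytest.approx(r, rel=1e-12)
                assert classes.loc[g, day] == c

    def test_self_ratio_identity(self, tomato_bundle):
        traits_tbl, _ = db_series(tomato_bundle.counts, tomato_bundle.plants)
        wue = wb.wue_table(traits_tbl, tomato_bundle.weights,
                           tomato_bundle.plants, t0=0)
        ratio, classes = wb.wue_ratio_table(wb.wue_summary(wue),
                                            control_genotype="UTC_70")
        row = ratio.loc["UTC_70"].dropna()
        assert (row == 1.0).all()
        assert (classes.loc["UTC_70"][row.index] == "green").all()

    def test_empty_table_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            wb.export_heatmap(pd.DataFrame(), tmp_path / "x.csv")

    def test_plot_written(self, tmp_path):
        out = tmp_path / "hm.png"
        wb.export_heatmap(self.ratio_table(), tmp_path / "r.csv",
                          plot_path=out)
        assert out.stat().st_size > 0


def test_read_weights_roundtrip(tmp_path, tomato_bundle):
    path = tmp_path / "weights.csv"
    tomato_bundle.weights_frame().to_csv(path, index=False)
    back = wb.read_weights(path)
    assert set(back) == set(tomato_bundle.weights)
    ws0 = tomato_bundle.weights["UTC_70_rwm70_r1"]
    np.testing.assert_allclose(back["UTC_70_rwm70_r1"].weight_pre_g,
                               ws0.weight_pre_g)
    assert back["bare_01"].is_bare
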