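"""Evaluation metrics: grouped MAE, sectoral statistics, binned errors."""

import numpy as np
import pandas as pd
import pytest

from retinerve.evaluation import (
    evaluate,
    md_metrics,
    pointwise_mae,
    sectoral_metrics,
    td_binned_error,
    tradeoff_report,
)


class TestPointwiseMAE:
    def test_perfect_prediction_is_zero_everywhere(self, rng):
        y = rng.normal(size=(6, 52))
        md = np.array([-1, -2, -8, -9, -20, -25], dtype=float)
        rep = pointwise_mae(y, y, md)
        assert (rep["mae"] == 0).all()

    def test_constant_bias_gives_unit_mae_in_every_group(self, rng):
        y = rng.normal(size=(6, 52))
        md = np.array([-1, -2, -8, -9, -20, -25], dtype=float)
        rep = pointwise_mae(y, y + 1.0, md)
        assert np.allclose(rep["mae"], 1.0)

    def test_hand_computed_mean_and_se(self):
        # two tests with per-test MAEs 2 and 4 -> mean 3, SE = sd/sqrt(2) = 1
        y = np.zeros((2, 52))
        yh = np.vstack([np.full(52, 2.0), np.full(52, 4.0)])
        rep = pointwise_mae(y, yh, np.array([-1.0, -2.0]))
        assert rep.loc["overall", "mae"] == pytest.approx(3.0)
        assert rep.loc["overall", "se"] == pytest.approx(1.0)

    def test_empty_group_reports_nan_not_zero(self):
        y = np.zeros((2, 52))
        rep = pointwise_mae(y, y + 2.0, np.array([-1.0, -2.0]))
        assert np.isnan(rep.loc["advanced", "mae"])
        assert rep.loc["advanced", "n"] == 0

    def test_overall_is_count_weighted_mean_of_stages(self, rng):
        y = rng.normal(size=(10, 52))
        yh = y + rng.normal(size=(10, 52))
        md = rng.uniform(-30, 0, 10)
        rep = pointwise_mae(y, yh, md)
        stages = rep.drop(index="overall").dropna()
        weighted = (stages["mae"] * stages["n"]).sum() / stages["n"].sum()
        assert rep.loc["overall", "mae"] == pytest.approx(weighted)

    def test_permutation_invariance(self, rng):
        y = rng.normal(size=(8, 52))
        yh = y + rng.normal(size=(8, 52))
        md = rng.uniform(-30, 0, 8)
        perm = rng.permutation(8)
        a = pointwise_mae(y, yh, md)
        b = pointwise_mae(y[perm], yh[perm], md[perm])
        assert np.allclose(a["mae"], b["mae"])


class TestSectoralMetrics:
    def test_perfect_prediction_r2_one(self, grid, rng):
        y = rng.normal(size=(20, 52))
        rep = sectoral_metrics(y, y, grid)
        assert np.allclose(rep["r2"], 1.0)
        assert np.allclose(rep["mae"], 0.0)

    def test_mean_predictor_r2_zero(self, grid, rng):
        y = rng.normal(size=(30, 52))
        idx = grid.sector_indices()
        yh = np.empty_like(y)
        for sector, js in idx.items():
            yh[:, js] = y[:, js].mean()  # per-sector test-set mean
        rep = sectoral_metrics(y, yh, grid)
        assert np.allclose(rep["r2"], 0.0, atol=1e-9)

    def test_within_sector_permutation_leaves_means_invariant(self, grid, rng):
        y = rng.normal(size=(10, 52))
        yh = y + rng.normal(size=(10, 52))
        yh2 = yh.copy()
        js = grid.sector_indices()["superior"]
        yh2[:, js] = yh[:, np.random.default_rng(0).permutation(js)]
        a = sectoral_metrics(y, yh, grid)
        b = sectoral_metrics(y, yh2, grid)
        assert np.allclose(a["mae"], b["mae"])


class TestMDMetrics:
    def test_values_and_symmetry(self):
        out = md_metrics(np.array([0.0, 0.0]), np.array([1.0, 3.0]))
        assert out["mae"] == pytest.approx(2.0)
        flipped = md_metrics(np.array([0.0, 0.0]), np.array([-1.0, -3.0]))
        assert flipped["mae"] == pytest.approx(out["mae"])

    def test_perfect_is_zero(self, rng):
        z = rng.normal(size=5)
        assert md_metrics(z, z)["mae"] == 0.0


class TestBinnedErrors:
    def test_counts_conserve_all_pairs(self, rng):
        y = rng.uniform(-35, 5, size=(9, 52))
        yh = y + rng.normal(size=(9, 52))
        table = td_binned_error(y, yh, bin_width=1.0)
        assert table["count"].sum() == 9 * 52

    def test_perfect_prediction_all_bins_zero(self, rng):
        y = rng.uniform(-35, 5, size=(4, 52))
        table = td_binned_error(y, y)
        occupied = table[table["count"] > 0]
        assert (occupied["mae"] == 0).all()

    def test_homoscedastic_noise_gives_flat_curve(self, rng):
        y = rng.uniform(-30, 0, size=(400, 52))
        yh = y + rng.normal(0, 1.0, size=y.shape)
        table = td_binned_error(y, yh, bin_width=2.0)
        busy = table[table["count"] > 500]
        expected = np.sqrt(2 / np.pi)
        assert np.allclose(busy["mae"], expected, atol=0.12)

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError):
            td_binned_error(np.zeros((1, 52)), np.zeros((1, 52)), bin_width=0)


class TestTradeoffReport:
    def _table(self):
        return pd.DataFrame([
            {"alpha": 0.01, "beta": 0.25, "gamma": 5.0, "mae_interval_4": 12.0,
             "val_mae": 5.0},
            {"alpha": 0.99, "beta": 0.25, "gamma": 5.0, "mae_interval_4": 8.0,
             "val_mae": 6.0},
            {"alpha": 0.0, "beta": 0.0, "gamma": 5.0, "mae_interval_4": 14.0,
             "val_mae": 4.8},
        ])

    def test_rows_preserve_cells_and_flag_basic(self):
        out = tradeoff_report(self._table())
        assert len(out) == 3
        assert out.loc[out["alpha"] == 0.0, "basic"].iloc[0]
        assert not out.loc[out["alpha"] == 0.99, "basic"].iloc[0]

    def test_ordering_is_stable_and_deterministic(self):
        a = tradeoff_report(self._table())
        b = tradeoff_report(self._table())
        assert a.equals(b)
        assert list(a["mae_interval_4"]) == sorted(a["mae_interval_4"])

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError):
            tradeoff_report(pd.DataFrame({"alpha": [0.1]}))


class TestPlotHelpers:
    def test_binned_error_and_tradeoff_plots_render(self, rng, tmp_path):
        import matplotlib

        matplotlib.use("Agg")
        y = rng.uniform(-30, 0, size=(20, 52))
        table = td_binned_error(y, y + rng.normal(size=y.shape))
        from retinerve.evaluation import plot_td_binned_error, plot_tradeoff

        ax = plot_td_binned_error(table)
        assert ax.get_xlabel() == "true TD (dB)"
        rep = tradeoff_report(pd.DataFrame([
            {"alpha": 0.0, "beta": 0.0, "gamma": 5.0,
             "mae_interval_1": 3.0, "mae_interval_4": 14.0, "val_mae": 5.0},
            {"alpha": 0.99, "beta": 0.25, "gamma": 5.0,
             "mae_interval_1": 5.0, "mae_interval_4": 8.0, "val_mae": 6.0},
        ]))
        ax2 = plot_tradeoff(rep)
        assert ax2.get_ylabel() == "mae_interval_4"


class TestFullReport:
    def test_evaluate_bundles_all_metrics(self, small_dataset):
        from retinerve.architectures import build_model

        ds, _ = small_dataset
        model = build_model("linear", seed=0)
        rep = evaluate(model, ds)
        assert set(rep.pointwise.index) == {"overall", "early_or_none", "moderate", "advanced"}
        assert len(rep.sectoral) == 6
        assert {"mae", "se", "n"} <= set(rep.md)
        d = rep.to_dict()
        assert {"pointwise", "sectoral", "md", "td_bins"} <= set(d)
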