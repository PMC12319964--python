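"""Coarse-to-fine parameter estimation: r2, grid search, refinement, batches."""
import dataclasses

import numpy as np
import pytest

from ncsf import (CrfParams, CsfParams, FitGrid, NcsfParams, fit_dataset,
                  grid_fit, iterative_fit, predict_timeseries,
                  variance_explained)
from ncsf.fitting import _ols_gain_offset, _unit_predictions, default_grid
from ncsf.hrf import HrfSpec, hrf_kernel


def node_params(sf_p, cs_p, width_r, slope, amplitude=1.0, baseline=0.0):
    return NcsfParams(csf=CsfParams(cs_p=cs_p, sf_p=sf_p, width_r=width_r),
                      crf=CrfParams(slope_crf=slope, amplitude=amplitude),
                      baseline=baseline)


class TestVarianceExplained:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 0.5, 3.0])
        assert variance_explained(y, y) == pytest.approx(100.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 0.5, 3.0])
        assert variance_explained(np.full(4, y.mean()), y) == pytest.approx(0.0)

    def test_orthogonal_noise_of_equal_variance(self):
        # prediction = data + noise, noise orthogonal to the demeaned data
        # and of equal variance: RSS = TSS, hence r2 = 0
        data = np.array([1.0, -1.0, 1.0, -1.0])
        noise = np.array([1.0, 1.0, -1.0, -1.0])
        pred = data + noise
        assert variance_explained(pred, data) == pytest.approx(0.0)

    def test_zero_variance_data_flagged_nan(self):
        assert np.isnan(variance_explained(np.zeros(5), np.ones(5)))

    def test_worse_than_mean_is_negative(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        assert variance_explained(10 * y, y) < 0


class TestGridFit:
    def test_on_grid_truth_recovered_exactly(self, design, small_grid):
        truth = node_params(2.0, 100.0, 1.0, 3.0, amplitude=1.4,
                            baseline=0.2)
        data = predict_timeseries(truth, design).values
        fit = grid_fit(data, design, grid=small_grid)
        assert fit.params.csf.sf_p == 2.0
        assert fit.params.csf.cs_p == 100.0
        assert fit.params.csf.width_r == 1.0
        assert fit.params.crf.slope_crf == 3.0
        assert fit.params.crf.amplitude == pytest.approx(1.4)
        assert fit.params.baseline == pytest.approx(0.2)
        assert fit.r2 == pytest.approx(100.0)

    def test_matches_exhaustive_rss_scan(self, design, small_grid):
        # independent brute-force oracle: per-node lstsq over the full grid
        rng = np.random.default_rng(11)
        truth = node_params(1.3, 80.0, 1.1, 2.0)
        data = (predict_timeseries(truth, design).values
                + 0.3 * rng.standard_normal(design.n_volumes))
        kernel = hrf_kernel(HrfSpec(), design.tr)
        nodes = small_grid.nodes()
        P = _unit_predictions(nodes, design, kernel, 0.68)
        rss_scan = []
        for p in P:
            X = np.column_stack([p, np.ones_like(p)])
            beta, *_ = np.linalg.lstsq(X, data, rcond=None)
            rss_scan.append(np.sum((data - X @ beta) ** 2))
        best = int(np.argmin(rss_scan))
        fit = grid_fit(data, design, grid=small_grid)
        assert fit.node_index == best
        assert fit.rss == pytest.approx(rss_scan[best], rel=1e-10)

    def test_tie_break_returns_lowest_index(self, design):
        # duplicate slope axis values create exactly tied nodes
        grid = FitGrid(sf_p=np.array([2.0]), cs_p=np.array([100.0]),
                       width_r=np.array([1.0]),
                       slope_crf=np.array([3.0, 3.0]))
        data = predict_timeseries(node_params(2, 100, 1, 3), design).values
        fit = grid_fit(data, design, grid=grid)
        assert fit.node_index == 0

    def test_pure_noise_r2_stays_low(self, design):
        rng = np.random.default_rng(5)
        data = rng.standard_normal(design.n_volumes)
        fit = grid_fit(data, design)
        assert fit.r2 < 20.0

    def test_nonfinite_data_rejected(self, design, small_grid):
        data = np.full(design.n_volumes, np.nan)
        with pytest.raises(ValueError):
            grid_fit(data, design, grid=small_grid)


class TestIterativeFit:
    def test_on_grid_noiseless_truth_unchanged(self, design, small_grid):
        truth = node_params(2.0, 100.0, 1.0, 3.0)
        data = predict_timeseries(truth, design).values
        init = grid_fit(data, design, grid=small_grid)
        fit = iterative_fit(data, design, init=init, grid=small_grid)
        assert fit.rss <= init.rss
        assert fit.params.csf.sf_p == pytest.approx(2.0, rel=1e-4)
        assert fit.r2 == pytest.approx(100.0, abs=1e-6)

    def test_off_grid_noiseless_truth_recovered(self, design):
        truth = node_params(1.7, 120.0, 1.15, 2.5)
        data = predict_timeseries(truth, design).values
        fit = iterative_fit(data, design)
        assert fit.params.csf.sf_p == pytest.approx(1.7, rel=0.01)
        assert fit.params.csf.cs_p == pytest.approx(120.0, rel=0.01)
        assert fit.params.csf.width_r == pytest.approx(1.15, rel=0.01)
        assert fit.params.crf.slope_crf == pytest.approx(2.5, rel=0.01)
        assert fit.r2 > 99.99

    def test_never_worse_than_grid_stage(self, design):
        rng = np.random.default_rng(3)
        truth = node_params(1.0, 150.0, 1.3, 3.0)
        clean = predict_timeseries(truth, design).values
        for _ in range(5):
            data = clean + 0.8 * rng.standard_normal(design.n_volumes)
            init = grid_fit(data, design)
            fit = iterative_fit(data, design, init=init)
            assert fit.rss <= init.rss + 1e-12
            assert fit.r2 >= init.r2 - 1e-9


class TestInvariances:
    def test_scale_invariance(self, design):
        rng = np.random.default_rng(9)
        truth = node_params(2.0, 100.0, 1.0, 3.0)
        data = (predict_timeseries(truth, design).values
                + 0.4 * rng.standard_normal(design.n_volumes))
        f1 = grid_fit(data, design)
        f2 = grid_fit(3.0 * data, design)
        assert f2.node_index == f1.node_index
        assert f2.params.crf.amplitude == pytest.approx(
            3.0 * f1.params.crf.amplitude)
        assert f2.r2 == pytest.approx(f1.r2, abs=1e-9)

    def test_baseline_invariance(self, design):
        rng = np.random.default_rng(13)
        truth = node_params(2.0, 100.0, 1.0, 3.0)
        data = (predict_timeseries(truth, design).values
                + 0.4 * rng.standard_normal(design.n_volumes))
        f1 = grid_fit(data, design)
        f2 = grid_fit(data + 5.0, design)
        assert f2.node_index == f1.node_index
        assert f2.params.baseline == pytest.approx(
            f1.params.baseline + 5.0)
        assert f2.params.crf.amplitude == pytest.approx(
            f1.params.crf.amplitude)

    def test_rss_and_r2_select_same_node(self, design, small_grid):
        rng = np.random.default_rng(21)
        data = rng.standard_normal(design.n_volumes)
        kernel = hrf_kernel(HrfSpec(), design.tr)
        nodes = small_grid.nodes()
        P = _unit_predictions(nodes, design, kernel, 0.68)
        a, b, rss = _ols_gain_offset(P, data[None, :])
        r2 = [variance_explained(a[i, 0] * P[i] + b[i, 0], data)
              for i in range(len(nodes))]
        assert int(np.argmin(rss[:, 0])) == int(np.argmax(r2))


class TestFitDataset:
    def test_noiseless_batch_all_included(self, design, small_grid):
        truths = [node_params(2.0, 100.0, 1.0, 3.0),
                  node_params(0.5, 20.0, 0.5, 1.0),
                  node_params(8.0, 300.0, 2.0, 6.0)]
        data = np.stack([predict_timeseries(t, design).values
                         for t in truths])
        df = fit_dataset(data, design, grid=small_grid, stage="grid")
        assert df["included"].all()
        np.testing.assert_allclose(df["r2"], 100.0, atol=1e-8)
        np.testing.assert_allclose(df["sf_p"], [2.0, 0.5, 8.0])

    def test_chunked_execution_is_bitwise_identical(self, design, small_grid):
        rng = np.random.default_rng(17)
        data = rng.standard_normal((6, design.n_volumes))
        a = fit_dataset(data, design, grid=small_grid, stage="grid")
        b = fit_dataset(data, design, grid=small_grid, stage="grid",
                        chunk_size=2)
        for col in ("sf_p", "cs_p", "rss", "r2", "amplitude", "baseline"):
            np.testing.assert_array_equal(a[col], b[col])

    def test_bad_rows_isolated_not_fatal(self, design, small_grid):
        truth = node_params(2.0, 100.0, 1.0, 3.0)
        good = predict_timeseries(truth, design).values
        bad = np.full(design.n_volumes, np.nan)
        df = fit_dataset(np.stack([good, bad, good]), design,
                         grid=small_grid, stage="grid")
        assert df.loc[0, "ok"] and df.loc[2, "ok"]
        assert not df.loc[1, "ok"]
        assert df.loc[1, "flags"] == "non_finite_data"
        assert not df.loc[1, "included"]

    def test_sub_threshold_rows_flagged_excluded(self, design):
        # signal-free rows land at the null r2 of the grid search (~15%)
        # and must be flagged out by the default 30% inclusion threshold
        rng = np.random.default_rng(2)
        truth = node_params(1.0, 150.0, 1.3, 3.0)
        clean = predict_timeseries(truth, design).values
        clean = clean / clean.std()
        noisy = clean + 0.4 * rng.standard_normal((3, design.n_volumes))
        pure_noise = rng.standard_normal((3, design.n_volumes))
        df = fit_dataset(np.vstack([noisy, pure_noise]), design,
                         stage="grid", r2_threshold=30.0)
        assert df["included"][:3].all()
        assert not df["included"][3:].any()
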