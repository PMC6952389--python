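import numpy as np
import pytest

from adhescan.kinetics import (
    compute_spectrogram,
    fit_lognormal,
    fit_sigmoid,
    population_timecourse,
)
from adhescan.synthetic import PopulationConfig, generate_sigmoid_track, generate_ws_stack


def logistic(t, sat, rate, t0):
    return sat / (1.0 + np.exp(-rate * (t - t0)))


class TestFitSigmoid:
    @pytest.mark.parametrize("params", [(15.0, 0.005, 1200.0), (8.0, 0.01, 600.0)])
    def test_noiseless_exact_recovery(self, params):
        t = np.arange(0.0, 5401.0, 3.0)
        fit = fit_sigmoid(t, logistic(t, *params))
        assert fit.saturation == pytest.approx(params[0], rel=1e-6)
        assert fit.rate == pytest.approx(params[1], rel=1e-6)
        assert fit.midpoint == pytest.approx(params[2], rel=1e-6)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_degenerate(self):
        t = np.arange(0.0, 100.0, 3.0)
        fit = fit_sigmoid(t, np.full_like(t, 4.2))
        assert fit.degenerate

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(5.0), np.arange(5.0))

    def test_recovery_error_scales_with_noise(self):
        """Saturation recovery error grows with the additive noise SD."""
        t = np.arange(0.0, 5401.0, 3.0)
        errors = []
        for noise in (0.0, 0.5, 1.0):
            errs = []
            for seed in range(5):
                _, e = generate_sigmoid_track(noise_sd=noise, seed=seed)
                errs.append(abs(fit_sigmoid(t, e).saturation - 15.0))
            errors.append(np.mean(errs))
        assert errors[0] < errors[1] < errors[2]
        assert errors[2] / 15.0 < 0.05


class TestFitLognormal:
    def test_standard_lognormal_mode(self):
        rng = np.random.default_rng(8)
        fit = fit_lognormal(rng.lognormal(0.0, 1.0, 10_000))
        assert fit.mode == pytest.approx(np.exp(-1.0), rel=0.1)

    def test_recovery_within_3se(self):
        mu, sigma, n = 2.0, 0.5, 300
        rng = np.random.default_rng(12)
        fit = fit_lognormal(rng.lognormal(mu, sigma, n))
        se_mu = sigma / np.sqrt(n)
        se_sigma = sigma / np.sqrt(2 * n)
        assert abs(fit.mu_log - mu) < 3 * se_mu
        assert abs(fit.sigma_log - sigma) < 3 * se_sigma

    def test_constant_sample_degenerate(self):
        fit = fit_lognormal(np.full(5, 7.0))
        assert fit.mu_log == pytest.approx(np.log(7.0))
        assert fit.sigma_log == 0.0
        assert fit.degenerate

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_lognormal(np.array([1.0, 0.0, 2.0]))

    def test_closed_form_moment_ordering(self):
        """mode ≤ median ≤ mean for any σ > 0, by the closed forms."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            fit = fit_lognormal(rng.lognormal(rng.normal(), rng.uniform(0.1, 1.5), 50))
            assert fit.mode <= fit.median <= fit.mean
            s2 = fit.sigma_log**2
            assert fit.variance == pytest.approx(
                (np.exp(s2) - 1) * np.exp(2 * fit.mu_log + s2)
            )


class TestPopulationTimecourse:
    def test_identical_cells_zero_variance(self):
        t = np.arange(0.0, 3000.0, 60.0)
        shared = logistic(t, 10.0, 0.005, 1000.0)
        values = np.tile(shared[:, None], (1, 20))
        tc = population_timecourse(t, values, detection_floor=0.01)
        ok = tc.dropna()
        np.testing.assert_allclose(ok["mean"], shared[tc.dropna().index], rtol=1e-6)
        assert np.all(ok["variance"] < 1e-9)

    def test_sparse_frames_emitted_as_missing(self):
        t = np.array([0.0, 60.0])
        values = np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        tc = population_timecourse(t, values, detection_floor=0.5)
        assert np.isnan(tc["mean"].iloc[0])
        assert not np.isnan(tc["mean"].iloc[1])

    def test_final_force_sample_close_to_lognormal(self):
        """With a fixed footprint, the final-force sample across 300 cells is
        not distinguishable from log-normal at α = 0.01 and the fitted
        moments obey the log-normal ordering."""
        from scipy import stats

        cfg = PopulationConfig(
            n_cells=300,
            duration=60.0,
            frame_interval=60.0,
            footprint_sd_um=0.0,
            footprint_range_um=(45.0, 45.0),
            seed=31,
        )
        _, truth, _ = generate_ws_stack(cfg)
        forces = truth.force[-1]
        assert stats.shapiro(np.log(forces)).pvalue > 0.01
        fit = fit_lognormal(forces)
        assert fit.mode <= fit.median <= fit.mean

    def test_variance_rises_then_falls_with_dispersed_midpoints(self):
        cfg = PopulationConfig(
            n_cells=150, duration=5400.0, frame_interval=180.0, midpoint_sd_s=600.0, seed=17
        )
        _, truth, _ = generate_ws_stack(cfg)
        # detection floor: calibrated force of a one-pixel segment at the
        # 100 pm segmentation noise floor (≈30 nN at the reference slope)
        tc = population_timecourse(truth.times, truth.force, detection_floor=30.0)
        var = tc["variance"].to_numpy()
        t = tc.t_s.to_numpy()
        v_early = var[np.searchsorted(t, 400.0)]
        v_mid = var[np.searchsorted(t, 1400.0)]
        v_late = var[-1]
        assert v_mid > v_early
        assert v_mid > v_late


class TestSpectrogram:
    def test_single_cell_single_entry_per_column(self):
        t = np.arange(0.0, 100.0, 10.0)
        values = np.linspace(1.0, 9.0, t.size)[:, None]
        spec = compute_spectrogram(t, values, np.arange(0.0, 101.0, 10.0), np.arange(0.0, 11.0))
        assert np.all(spec.frequencies.sum(axis=0) == 1.0)
        assert np.all((spec.frequencies > 0).sum(axis=0) == 1)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 300.0, 10.0)
        values = rng.lognormal(3.0, 1.0, (t.size, 40))
        v_edges = np.quantile(values, np.linspace(0, 1, 15))
        v_edges[-1] += 1.0
        spec = compute_spectrogram(t, values, np.linspace(0, 300, 7), v_edges)
        np.testing.assert_allclose(spec.frequencies.sum(axis=0), 1.0)

    def test_matches_brute_force_binning(self):
        """Column histograms equal an independent per-bin counting loop."""
        rng = np.random.default_rng(9)
        t = np.arange(0.0, 120.0, 10.0)
        values = rng.uniform(0.0, 10.0, (t.size, 25))
        t_edges = np.array([0.0, 40.0, 80.0, 120.1])
        v_edges = np.linspace(0.0, 10.0, 6)
        spec = compute_spectrogram(t, values, t_edges, v_edges)
        for b in range(3):
            rows = values[(t >= t_edges[b]) & (t < t_edges[b + 1])].ravel()
            counts = np.array(
                [
                    np.sum(
                        (rows >= v_edges[i])
                        & ((rows < v_edges[i + 1]) | ((i == 4) & (rows == v_edges[5])))
                    )
                    for i in range(5)
                ]
            )
            np.testing.assert_allclose(spec.frequencies[:, b], counts / counts.sum())

    def test_empty_bin_flagged(self):
        t = np.array([0.0, 10.0])
        values = np.ones((2, 3))
        with pytest.warns(UserWarning, match="empty"):
            spec = compute_spectrogram(t, values, np.array([0.0, 20.0, 40.0]), np.array([0.0, 2.0]))
        assert spec.empty_columns[1]
        assert np.all(spec.frequencies[:, 1] == 0.0)

    def test_bad_bins_rejected(self):
        with pytest.raises(ValueError):
            compute_spectrogram(
                np.array([0.0]), np.ones((1, 2)), np.array([1.0, 0.0]), np.array([0.0, 1.0])
            )
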