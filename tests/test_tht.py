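"""Sigmoid fitting: parameter recovery, model selection, ordering."""

import numpy as np
import pytest

from synagg.synthetic import generate_tht_curve
from synagg.tht import (
    ThTSeries,
    compare_conditions,
    fit_sigmoid,
    fit_sigmoid_decay,
    sigmoid_decay_model,
    sigmoid_model,
)

TRUTH = dict(f0=0.1, amplitude=1.0, rate=0.8, t_half=8.0)


class TestFitSigmoid:
    def test_noiseless_round_trip(self):
        series = generate_tht_curve(TRUTH, n_points=50, t_max=20.0, noise_sd=0.0)
        fit = fit_sigmoid(series)
        assert fit.f0 == pytest.approx(TRUTH["f0"], rel=1e-4, abs=1e-6)
        assert fit.amplitude == pytest.approx(TRUTH["amplitude"], rel=1e-4)
        assert fit.rate == pytest.approx(TRUTH["rate"], rel=1e-4)
        assert fit.t_half == pytest.approx(TRUTH["t_half"], rel=1e-4)
        assert not fit.no_transition

    def test_lag_time_convention(self):
        series = generate_tht_curve(TRUTH, n_points=50, t_max=20.0, noise_sd=0.0)
        fit = fit_sigmoid(series)
        assert fit.lag_time == pytest.approx(8.0 - 2 / 0.8, rel=1e-3)  # 5.5 days

    def test_constant_series_flags_no_transition(self):
        t = np.linspace(0, 20, 20)
        fit = fit_sigmoid(ThTSeries(t, np.full_like(t, 0.4)))
        assert fit.no_transition

    def test_negative_lag_not_reported(self):
        truth = dict(f0=0.0, amplitude=1.0, rate=0.5, t_half=1.0)  # t_half < 2/k
        series = generate_tht_curve(truth, n_points=40, t_max=20.0, noise_sd=0.0)
        fit = fit_sigmoid(series)
        assert fit.lag_time is None

    def test_deterministic_given_seed(self):
        series = generate_tht_curve(TRUTH, n_points=50, noise_sd=0.05, seed=3)
        f1 = fit_sigmoid(series, seed=9)
        f2 = fit_sigmoid(series, seed=9)
        assert f1.t_half == f2.t_half and f1.rate == f2.rate

    def test_noisy_t_half_recovery(self):
        # 2% of amplitude noise: median absolute error below half a day
        errs = []
        for rep in range(60):
            series = generate_tht_curve(TRUTH, 50, 20.0, noise_sd=0.02, seed=rep)
            errs.append(abs(fit_sigmoid(series).t_half - TRUTH["t_half"]))
        assert np.median(errs) < 0.5


class TestFitSigmoidDecay:
    def test_decay_round_trip(self):
        truth = dict(TRUTH, decay_fraction=0.4, decay_tau=5.0)
        series = generate_tht_curve(truth, n_points=50, t_max=20.0, noise_sd=0.0)
        fit = fit_sigmoid_decay(series)
        assert fit.model == "sigmoid_decay"
        assert fit.decay_fraction == pytest.approx(0.4, abs=0.02)
        assert fit.rate == pytest.approx(truth["rate"], rel=1e-3)

    def test_pure_sigmoid_not_overfit(self):
        series = generate_tht_curve(TRUTH, n_points=50, t_max=20.0, noise_sd=0.0)
        fit = fit_sigmoid_decay(series)
        assert fit.model == "sigmoid"
        assert fit.decay_fraction == 0.0

    def test_plateau_algebra(self):
        truth = dict(TRUTH, decay_fraction=0.4, decay_tau=5.0)
        series = generate_tht_curve(truth, n_points=60, t_max=40.0, noise_sd=0.0)
        fit = fit_sigmoid_decay(series)
        assert fit.plateau == pytest.approx(
            truth["f0"] + truth["amplitude"] * (1 - truth["decay_fraction"]), rel=0.02
        )
        # model value far past the transition approaches the plateau
        tail = sigmoid_decay_model(
            np.array([500.0]), fit.f0, fit.amplitude, fit.rate, fit.t_half,
            fit.decay_fraction, fit.decay_tau,
        )
        assert tail[0] == pytest.approx(fit.plateau, rel=1e-6)

    def test_affine_intensity_rescaling_maps_f0_and_amplitude(self):
        series = generate_tht_curve(TRUTH, n_points=50, t_max=20.0, noise_sd=0.0)
        scaled = ThTSeries(series.times, 3.0 * series.intensities + 2.0)
        f_orig = fit_sigmoid(series)
        f_scaled = fit_sigmoid(scaled)
        assert f_scaled.rate == pytest.approx(f_orig.rate, rel=1e-6)
        assert f_scaled.t_half == pytest.approx(f_orig.t_half, rel=1e-6)
        assert f_scaled.amplitude == pytest.approx(3.0 * f_orig.amplitude, rel=1e-6)
        assert f_scaled.f0 == pytest.approx(3.0 * f_orig.f0 + 2.0, rel=1e-5)


class TestCompareConditions:
    def _fit(self, t_half, label):
        truth = dict(TRUTH, t_half=t_half)
        series = generate_tht_curve(truth, 50, 30.0, noise_sd=0.0, label=label)
        return fit_sigmoid(series)

    def test_faster_condition_ranks_first(self):
        table = compare_conditions([self._fit(18.0, "slow"), self._fit(10.0, "fast")])
        assert table.iloc[0]["label"] == "fast"
        assert table.iloc[0]["rank_t_half"] == 1

    def test_identical_fits_tie(self):
        table = compare_conditions([self._fit(10.0, "a"), self._fit(10.0, "b")])
        assert set(table["rank_t_half"]) == {1}

    def test_input_order_invariance(self):
        fits = [self._fit(t, f"c{t}") for t in (12.0, 6.0, 9.0)]
        t1 = compare_conditions(fits)
        t2 = compare_conditions(fits[::-1])
        assert list(t1["label"]) == list(t2["label"])

    def test_bootstrap_intervals_with_errors(self):
        truth = dict(TRUTH)
        s1 = generate_tht_curve(truth, 40, 20.0, noise_sd=0.02, seed=1)
        s1.errors = np.full_like(s1.times, 0.02)
        s2 = generate_tht_curve(dict(truth, t_half=12.0), 40, 20.0, noise_sd=0.02, seed=2)
        s2.errors = np.full_like(s2.times, 0.02)
        fits = [fit_sigmoid(s1), fit_sigmoid(s2)]
        table = compare_conditions(fits, [s1, s2], n_boot=30, seed=0)
        assert "t_half_lo" in table.columns
        row = table.iloc[0]
        assert row["t_half_lo"] <= row["t_half"] <= row["t_half_hi"]
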