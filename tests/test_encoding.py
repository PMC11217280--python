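import numpy as np
import pytest

from lumifrontal.encoding import (
    IntensityResponseModel,
    classify_intensity_encoding,
    classify_intensity_encoding_batch,
    dynamic_range,
    fit_naka_rushton,
    naka_rushton,
    pooled_intensity_response,
    pre_post_transition_compare,
    ramp_phase_fit,
    rmse,
    threshold_intensity,
    transition_lag,
)
from lumifrontal.protocols import make_ramp_protocol
from lumifrontal.simulate import (
    DEFAULT_ARCHETYPES,
    simulate_null_responses,
    simulate_unit,
)

E7 = np.array([9.4, 10.4, 11.4, 12.4, 13.4, 14.4, 15.4])


class TestNakaRushton:
    def test_half_saturation_identity(self):
        assert naka_rushton(13.0, 8.0, 1.5, 13.0) == pytest.approx(4.0)

    def test_asymptotes(self):
        assert naka_rushton(1e3, 8.0, 1.5, 13.0) == pytest.approx(8.0)
        assert naka_rushton(-1e3, 8.0, 1.5, 13.0) == pytest.approx(0.0)

    def test_direct_evaluation(self):
        # 8 / (1 + 10^(1.5*(13-14))) evaluated by hand
        expected = 8.0 / (1.0 + 10.0 ** (-1.5))
        assert naka_rushton(14.0, 8.0, 1.5, 13.0) == pytest.approx(expected, rel=1e-12)

    def test_strictly_increasing(self):
        e = np.linspace(8, 18, 101)
        assert np.all(np.diff(naka_rushton(e, 5.0, 2.0, 13.0)) > 0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            naka_rushton(13.0, 8.0, 0.0, 13.0)


class TestFit:
    def test_noiseless_parameter_recovery(self):
        y = naka_rushton(E7, 8.0, 1.5, 13.0)
        fit = fit_naka_rushton(E7, y)
        assert fit.converged
        assert fit.Rmax == pytest.approx(8.0, rel=1e-4)
        assert fit.n == pytest.approx(1.5, rel=1e-4)
        assert fit.K == pytest.approx(13.0, rel=1e-4)
        assert fit.rmse < 1e-8

    def test_suppressed_mirror_symmetry(self):
        y = naka_rushton(E7, 8.0, 1.5, 13.0)
        up = fit_naka_rushton(E7, y)
        down = fit_naka_rushton(E7, -y)
        assert down.direction == -1
        assert down.Rmax == pytest.approx(up.Rmax, rel=1e-6)
        assert down.K == pytest.approx(up.K, rel=1e-6)

    def test_refit_of_fitted_curve_is_stable(self):
        rng = np.random.default_rng(0)
        y = naka_rushton(E7, 5.0, 1.2, 13.5) + rng.normal(0, 0.3, 7)
        fit1 = fit_naka_rushton(E7, y)
        fit2 = fit_naka_rushton(E7, fit1.predict(E7))
        assert fit2.K == pytest.approx(fit1.K, abs=1e-3)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_naka_rushton(E7[:3], np.ones(3))


class TestRmse:
    def test_perfect_fit_zero(self):
        y = naka_rushton(E7, 8.0, 1.5, 13.0)
        fit = fit_naka_rushton(E7, y)
        assert rmse(fit, E7, y) == pytest.approx(0.0, abs=1e-8)

    def test_hand_arithmetic(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 8.0, 1.5, 13.0))
        e2 = np.array([20.0, 21.0])  # deep saturation: prediction = 8
        y2 = np.array([8.0 - 3.0, 8.0 + 4.0])
        assert rmse(fit, e2, y2) == pytest.approx(np.sqrt(12.5))

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        y = naka_rushton(E7, 8.0, 1.5, 13.0) + rng.normal(0, 0.2, 7)
        fit = fit_naka_rushton(E7, y)
        perm = rng.permutation(7)
        assert rmse(fit, E7, y) == pytest.approx(rmse(fit, E7[perm], y[perm]))


class TestEncodingTest:
    def test_noiseless_sigmoid_flagged(self):
        y = naka_rushton(E7, 8.0, 1.5, 13.0)
        _, test = classify_intensity_encoding(E7, y, seed=0)
        assert test.encoding_flag
        assert test.rmse_real < test.percentile5

    def test_flat_responses_not_flagged(self):
        _, test = classify_intensity_encoding(E7, np.full(7, 3.0), seed=0)
        assert not test.encoding_flag

    def test_determinism(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(4, 0.75, 7)
        _, t1 = classify_intensity_encoding(E7, y, seed=5)
        _, t2 = classify_intensity_encoding(E7, y, seed=5)
        assert np.array_equal(t1.rmse_null, t2.rmse_null)

    def test_null_calibration_500_units(self):
        """Intensity-independent units are flagged at <= 5% plus 3 binomial SE."""
        resp = simulate_null_responses(500, seed=21)
        flags = classify_intensity_encoding_batch(E7, resp, seed=22)
        rate = flags.mean()
        se = np.sqrt(0.05 * 0.95 / 500)
        assert rate <= 0.05 + 3 * se

    def test_batch_agrees_with_single_unit_rule(self):
        """The batched classifier applies the identical strict 5th-percentile
        rule as the per-unit path."""
        y = naka_rushton(E7, 6.0, 1.5, 13.0)
        flags = classify_intensity_encoding_batch(E7, y[None, :], seed=0)
        _, single = classify_intensity_encoding(E7, y, seed=0)
        assert bool(flags[0]) == single.encoding_flag is True


class TestThresholdAndDynamicRange:
    def test_half_max_inverse(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 0.2, 1.0, 12.5))
        assert threshold_intensity(fit, 0.1) == pytest.approx(fit.K, abs=1e-6)

    def test_arithmetic_oracle(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 8.0, 1.5, 13.0))
        expected = 13.0 + np.log10(0.1 / 7.9) / 1.5
        assert threshold_intensity(fit, 0.1) == pytest.approx(expected, abs=1e-4)

    def test_inverse_consistency(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 8.0, 1.5, 13.0))
        e_star = threshold_intensity(fit, 0.1)
        assert naka_rushton(e_star, fit.Rmax, fit.n, fit.K) == pytest.approx(0.1, abs=1e-10)

    def test_criterion_above_rmax_flagged(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 0.05, 1.0, 13.0))
        with pytest.raises(ValueError):
            threshold_intensity(fit, 0.1)

    def test_dynamic_range_closed_form(self):
        fit = fit_naka_rushton(E7, naka_rushton(E7, 8.0, 2.0, 13.0))
        lo, hi = dynamic_range(fit)
        assert hi - lo == pytest.approx(np.log10(9.0), abs=1e-4)  # (2/n)log10(9), n=2
        assert naka_rushton(lo, fit.Rmax, fit.n, fit.K) == pytest.approx(0.1 * fit.Rmax, rel=1e-3)
        assert naka_rushton(hi, fit.Rmax, fit.n, fit.K) == pytest.approx(0.9 * fit.Rmax, rel=1e-3)

    def test_width_shrinks_with_slope(self):
        widths = []
        for n in (0.5, 1.0, 2.0, 4.0):
            fit = fit_naka_rushton(E7, naka_rushton(E7, 8.0, n, 13.0))
            lo, hi = dynamic_range(fit)
            widths.append(hi - lo)
        assert all(np.diff(widths) < 0)


class TestModelResults:
    def test_summary_and_bse(self):
        rng = np.random.default_rng(3)
        y = naka_rushton(E7, 6.0, 1.5, 13.2) + rng.normal(0, 0.2, 7)
        res = IntensityResponseModel(E7, y).fit()
        text = res.summary()
        assert "Rmax" in text and "RMSE" in text
        assert all(v >= 0 or np.isnan(v) for v in res.bse().values())

    def test_from_window_rates(self, e_on_unit):
        res = IntensityResponseModel.from_window_rates(e_on_unit["wrates"]).fit()
        arch = e_on_unit["arch"]
        assert res.converged
        assert res.params["K"] == pytest.approx(arch.sustained_K, abs=0.4)
        assert res.encoding_test(seed=0).encoding_flag

    def test_plot_returns_axis(self):
        import matplotlib

        matplotlib.use("Agg")
        y = naka_rushton(E7, 6.0, 1.5, 13.2)
        ax = IntensityResponseModel(E7, y).fit().plot()
        assert ax is not None


class TestPooledResponse:
    def test_mirror_populations(self):
        x = naka_rushton(E7, 5.0, 1.5, 13.0)
        resp = np.vstack([x, -x])
        mean_no, _ = pooled_intensity_response(resp, directions=[1, 1])
        assert np.allclose(mean_no, 0.0)
        mean_yes, _ = pooled_intensity_response(resp)
        assert np.allclose(mean_yes, x)

    def test_single_unit_identity(self):
        x = naka_rushton(E7, 5.0, 1.5, 13.0)
        mean, sem = pooled_intensity_response(x[None, :])
        assert np.allclose(mean, x) and np.allclose(sem, 0.0)


@pytest.fixture(scope="module")
def ramp_protocol():
    return make_ramp_protocol(start_log=12.4, span_log=2.0, phase_s=30.0, n_reps=1)


class TestRampAnalysis:
    def _noiseless_trace(self, proto, Rmax=6.0, n=1.5, K=13.2, baseline=2.0):
        """Instantaneous (zero-lag) tracker: FR = baseline + NR(E(t))."""
        centers = np.arange(60) + 0.5
        e = proto.ramp_intensity(centers)
        return baseline + naka_rushton(e, Rmax, n, K)

    def test_instantaneous_tracker_phases_agree(self, ramp_protocol):
        trace = self._noiseless_trace(ramp_protocol)
        fit_a, test_a = ramp_phase_fit(trace[None, :], ramp_protocol, "ascending", seed=0)
        fit_d, test_d = ramp_phase_fit(trace[None, :], ramp_protocol, "descending", seed=0)
        assert test_a.encoding_flag and test_d.encoding_flag
        assert fit_a.K == pytest.approx(fit_d.K, abs=1e-6)
        assert fit_a.Rmax == pytest.approx(fit_d.Rmax, rel=1e-6)

    def test_flat_unit_not_significant(self, ramp_protocol):
        rng = np.random.default_rng(0)
        trace = 3.0 + rng.normal(0, 0.2, 60)
        _, test = ramp_phase_fit(trace[None, :], ramp_protocol, "ascending", seed=1)
        assert not test.encoding_flag

    def test_hysteresis_from_slow_time_constant(self, ramp_protocol):
        """With a slow tau the ascending-phase FR at a matched intensity sits
        below the descending-phase FR (light-history effect)."""
        from dataclasses import replace

        from lumifrontal.simulate import rate_function

        arch = replace(DEFAULT_ARCHETYPES["E_on"], sustained_tau=5.0)
        onset = ramp_protocol.epochs[0].onset_s
        centers = onset + np.arange(60) + 0.5
        trace = rate_function(arch, ramp_protocol, centers)
        e_asc = ramp_protocol.ramp_intensity(np.arange(30) + 0.5)
        e_des = ramp_protocol.ramp_intensity(30.0 + np.arange(30) + 0.5)
        # compare at matched mid-range intensity
        target = 13.6
        fr_asc = np.interp(target, e_asc, trace[:30])
        fr_des = np.interp(target, e_des[::-1], trace[30:][::-1])
        assert fr_asc < fr_des

    def test_transition_lag_zero_for_peak_at_transition(self):
        trace = np.concatenate([np.arange(31.0), np.arange(29.0, 0.0, -1.0)])
        lag, censored = transition_lag(trace, direction=1)
        assert lag == 0.0 and not censored

    def test_transition_lag_matches_first_order_filter_lag(self, ramp_protocol):
        """Oracle: a first-order filter tracking a triangular input peaks
        tau*ln(2) after the transition."""
        from dataclasses import replace

        from lumifrontal.simulate import rate_function

        tau = 3.0
        arch = replace(DEFAULT_ARCHETYPES["E_on"], sustained_tau=tau)
        onset = ramp_protocol.epochs[0].onset_s
        centers = onset + np.arange(60) + 0.5
        trace = rate_function(arch, ramp_protocol, centers)
        lag, censored = transition_lag(trace, direction=1)
        assert not censored
        assert abs(lag - tau * np.log(2.0)) <= 1.0  # within one 1 s bin

    def test_suppressed_unit_uses_minimum(self, ramp_protocol):
        from lumifrontal.simulate import rate_function

        arch = DEFAULT_ARCHETYPES["S_on"]
        onset = ramp_protocol.epochs[0].onset_s
        centers = onset + np.arange(60) + 0.5
        trace = rate_function(arch, ramp_protocol, centers)
        lag, _ = transition_lag(trace, direction=-1)
        assert trace[int((lag + 30))] == trace.min()

    def test_edge_extremum_censored(self):
        lag, censored = transition_lag(np.arange(60.0), direction=1)
        assert censored

    def test_pre_post_symmetric_traces_null(self):
        tri = np.concatenate([np.arange(30.0), np.arange(29.0, -1.0, -1.0)])
        traces = np.tile(tri, (5, 1))
        res = pre_post_transition_compare(traces, seed=0)
        assert res.p == 1.0  # windows [23,30) and [30,37) mirror exactly

    def test_pre_post_hysteresis_population(self, ramp_protocol):
        from dataclasses import replace

        from lumifrontal.simulate import rate_function

        rng = np.random.default_rng(4)
        onset = ramp_protocol.epochs[0].onset_s
        centers = onset + np.arange(60) + 0.5
        traces = []
        for _ in range(12):
            arch = replace(DEFAULT_ARCHETYPES["E_on"], sustained_tau=5.0)
            traces.append(rate_function(arch, ramp_protocol, centers) + rng.normal(0, 0.1, 60))
        res = pre_post_transition_compare(np.array(traces), seed=1)
        assert res.p <= 0.05
        assert res.statistic > 0  # post-transition FR higher
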