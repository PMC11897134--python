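"""FRAP, coalescence, rate, oxidation, turbidity-cycle and phase-map fits."""

import math

import numpy as np
import pytest
from scipy import ndimage

from phasekit.errors import ArgumentError, DataError
from phasekit.kinetics import (
    CoalescenceEvent,
    KineticTrace,
    PhaseDiagram,
    TurbidityCurve,
    build_phase_map,
    fit_coalescence,
    fit_first_order_fraction,
    fit_frap,
    fit_linear_rate,
    rate_enhancement,
    turbidity_cycle_metrics,
)
from phasekit.synthetic import (
    gen_coalescence_events,
    gen_frap_trace,
    gen_kinetic_trace,
    gen_turbidity_series,
)

from oracles import grid_search_frap, ols_slope, slope_scan


class TestFrap:
    def test_noiseless_full_recovery_closure(self):
        trace = gen_frap_trace(tau=15.0, mobile_fraction=1.0, bleach_depth=0.45)
        fit = fit_frap(trace)
        assert fit.tau == pytest.approx(15.0, rel=1e-6)
        assert fit.mobile_fraction == pytest.approx(1.0, abs=1e-6)
        assert fit.i0 == pytest.approx(0.55, abs=1e-6)

    def test_partial_mobility_matches_grid_search_oracle(self):
        trace = gen_frap_trace(tau=12.0, mobile_fraction=0.6, bleach_depth=0.45)
        fit = fit_frap(trace)
        assert fit.mobile_fraction == pytest.approx(0.6, abs=1e-6)
        oracle = grid_search_frap(trace.times, trace.intensity, trace.bleach_index)
        assert fit.tau == pytest.approx(oracle["tau"], rel=0.05)
        assert fit.plateau == pytest.approx(oracle["plateau"], abs=0.02)
        assert fit.rss <= oracle["rss"] + 1e-12

    def test_half_time_identity(self):
        fit = fit_frap(gen_frap_trace(tau=8.0, mobile_fraction=0.9))
        assert fit.t_half == pytest.approx(fit.tau * math.log(2))

    def test_noisy_recovery_within_tolerance(self):
        hits = 0
        for seed in range(20):
            trace = gen_frap_trace(tau=15.0, mobile_fraction=0.85, noise_sd=0.01, seed=seed)
            fit = fit_frap(trace)
            if abs(fit.tau - 15.0) / 15.0 < 0.05:
                hits += 1
        assert hits >= 19

    def test_too_few_post_bleach_samples(self):
        trace = gen_frap_trace(tau=5.0, mobile_fraction=1.0, n_points=10)
        trace.bleach_index = len(trace.times) - 3
        with pytest.raises(ArgumentError):
            fit_frap(trace)


class TestCoalescence:
    def test_single_event_slope(self):
        fit = fit_coalescence([CoalescenceEvent(tau=0.44, l=10.0)])
        assert fit.eta_over_gamma == pytest.approx(0.044)
        assert fit.stderr is None

    def test_zero_noise_exact_recovery(self):
        events = gen_coalescence_events(0.0213, np.linspace(2, 18, 15), 0.0)
        assert fit_coalescence(events).eta_over_gamma == pytest.approx(0.0213, rel=1e-12)

    def test_noisy_recovery_matches_scan_oracle(self):
        events = gen_coalescence_events(0.044, np.linspace(1, 20, 20), 0.05, seed=3)
        fit = fit_coalescence(events)
        assert fit.eta_over_gamma == pytest.approx(0.044, rel=0.05)
        tau = np.array([e.tau for e in events])
        l = np.array([e.l for e in events])
        assert fit.eta_over_gamma == pytest.approx(slope_scan(l, tau, 0.03, 0.06), abs=1e-5)

    def test_nonpositive_event_is_a_data_error(self):
        with pytest.raises(DataError):
            fit_coalescence([CoalescenceEvent(tau=-0.1, l=5.0)])

    def test_no_events_rejected(self):
        with pytest.raises(ArgumentError):
            fit_coalescence([])


class TestLinearRate:
    def test_exact_line(self):
        trace = gen_kinetic_trace("linear", 0.789, noise_sd=0.0)
        fit = fit_linear_rate(trace)
        assert fit.k == pytest.approx(0.789, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_signal_gives_zero_rate(self):
        trace = KineticTrace(times=np.arange(10.0), signal=np.full(10, 3.3))
        assert fit_linear_rate(trace).k == 0.0

    def test_noisy_slope_within_three_stderr_and_matches_ols_oracle(self):
        trace = gen_kinetic_trace("linear", 0.5, n_points=100, noise_sd=0.01, seed=5)
        fit = fit_linear_rate(trace)
        slope, se = ols_slope(trace.times, trace.signal)
        assert fit.k == pytest.approx(slope, rel=1e-12)
        assert fit.stderr == pytest.approx(se, rel=1e-9)
        assert abs(fit.k - 0.5) <= 3 * fit.stderr

    def test_window_selection_and_validation(self):
        trace = gen_kinetic_trace("linear", 1.0, n_points=50, t_max=10.0)
        fit = fit_linear_rate(trace, window=(0.0, 5.0))
        assert fit.window == (0.0, 5.0)
        with pytest.raises(ArgumentError):
            fit_linear_rate(trace, window=(5.0, 5.0))
        with pytest.raises(ArgumentError):
            fit_linear_rate(trace, window=(0.0, 99.0))

    def test_normalization_reports_raw_slope(self):
        trace = gen_kinetic_trace("linear", 2.0, noise_sd=0.0)
        fit = fit_linear_rate(trace, normalize_to=4.0)
        assert fit.k == pytest.approx(0.5, abs=1e-12)
        assert fit.raw_slope == pytest.approx(2.0, abs=1e-12)


class TestRateEnhancement:
    def test_printed_pair_rounds_to_sixteen(self):
        fold = rate_enhancement(0.789, 0.0479)
        assert fold.fold == pytest.approx(16.47, abs=0.01)
        assert fold.fold_rounded == 16

    @pytest.mark.parametrize("kw,ko,expected", [(3.0, 3.0, 1.0), (0.0, 1.0, 0.0)])
    def test_trivial_ratios(self, kw, ko, expected):
        assert rate_enhancement(kw, ko).fold == pytest.approx(expected)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ArgumentError):
            rate_enhancement(1.0, 0.0)


class TestFirstOrder:
    def test_single_point_closed_form(self):
        fit = fit_first_order_fraction([(15.0, 0.40)])
        assert fit.k == pytest.approx(-math.log(0.6) / 15.0, rel=1e-12)
        assert fit.k == pytest.approx(0.03405, abs=1e-5)

    def test_prediction_at_late_time_exceeds_ninety_percent(self):
        fit = fit_first_order_fraction([(15.0, 0.40)])
        assert fit.predict(80.0) == pytest.approx(0.934, abs=5e-4)
        assert fit.predict(80.0) > 0.90

    def test_zero_fraction_gives_zero_rate(self):
        assert fit_first_order_fraction([(30.0, 0.0)]).k == 0.0

    def test_exact_model_points_recover_k(self):
        k = 0.07
        pts = [(t, 1 - math.exp(-k * t)) for t in (5.0, 10.0, 20.0, 40.0)]
        assert fit_first_order_fraction(pts).k == pytest.approx(k, rel=1e-12)

    def test_saturated_fraction_rejected(self):
        with pytest.raises(ArgumentError):
            fit_first_order_fraction([(10.0, 1.0)])


class TestTurbidityCycles:
    def test_square_wave_is_fully_reversible(self):
        curve = gen_turbidity_series(n_cycles=4, amplitude_decay=1.0, noise_sd=0.0)
        m = turbidity_cycle_metrics(curve)
        assert m.reversibility == pytest.approx([1.0] * 4)

    def test_decaying_cycles_are_geometric(self):
        curve = gen_turbidity_series(n_cycles=3, amplitude_decay=0.9, noise_sd=0.0)
        m = turbidity_cycle_metrics(curve)
        assert m.reversibility == pytest.approx([1.0, 0.9, 0.81], abs=1e-9)

    def test_single_cycle_ratio_is_one(self):
        curve = gen_turbidity_series(n_cycles=1, noise_sd=0.0)
        assert turbidity_cycle_metrics(curve).reversibility == [1.0]

    def test_out_of_range_boundary_rejected(self):
        curve = gen_turbidity_series(n_cycles=1)
        with pytest.raises(ArgumentError):
            turbidity_cycle_metrics(curve, [(0, 10_000)])


class TestPhaseMap:
    def grid(self, turb):
        turb = np.asarray(turb, dtype=float)
        return PhaseDiagram(
            ph_values=np.arange(turb.shape[0], dtype=float),
            nacl_values=np.arange(turb.shape[1], dtype=float),
            turbidity=turb,
        )

    def test_all_below_threshold(self):
        result = build_phase_map(self.grid(np.full((4, 3), 0.02)), 0.04, 0.01)
        assert not result.phase_separated.any()

    def test_unimodal_bump_is_single_connected_region(self):
        from phasekit.synthetic import gen_turbidity_grid

        grid = gen_turbidity_grid(peak=1.0, blank_mean=0.04)
        result = build_phase_map(grid, blank_mean=0.04, blank_sd=0.01)
        assert result.phase_separated.any()
        _, n_regions = ndimage.label(result.phase_separated)  # 4-connected flood fill
        assert n_regions == 1

    def test_cell_exactly_at_threshold_is_negative(self):
        turb = np.full((2, 2), 0.04 + 3 * 0.01)
        result = build_phase_map(self.grid(turb), 0.04, 0.01, k_sd=3)
        assert not result.phase_separated.any()

    def test_missing_cells_reported_with_coordinates(self):
        turb = np.full((2, 2), 0.5)
        turb[1, 0] = np.nan
        with pytest.raises(DataError, match="1.0"):
            build_phase_map(self.grid(turb), 0.04, 0.01)


def test_turbidity_curve_rejects_negative_absorbance():
    with pytest.raises(DataError):
        TurbidityCurve(times=np.arange(3.0), absorbance=np.array([0.1, -0.2, 0.3]))
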