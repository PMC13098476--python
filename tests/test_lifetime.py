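import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import dissipycle as dc
from dissipycle import (
    InsufficientDataError,
    NoActivationError,
    NoBreakpointError,
)

from conftest import piecewise_linear_signal


class TestBreakpoint:
    def test_exact_two_segment_trace_gives_exact_lifetime(self):
        # rise slope 1 from t=15, hard plateau at t=40: tau = 25 exactly
        sig = piecewise_linear_signal(t_d=15.0, slope=1.0, t_break=40.0)
        res = dc.transient_lifetime(sig, 15.0)
        assert res.lifetime == pytest.approx(25.0, abs=1e-9)
        assert res.deactivation_time == pytest.approx(40.0, abs=1e-9)

    def test_sloped_plateau_breakpoint_within_one_sample(self):
        sig = piecewise_linear_signal(t_d=15.0, slope=1.0, t_break=40.0,
                                      plateau_slope=0.02)
        res = dc.transient_lifetime(sig, 15.0)
        assert abs(res.deactivation_time - 40.0) <= 0.5

    @pytest.mark.parametrize("slope,plateau_slope", [
        (1.0, 0.0), (0.5, 0.1), (2.0, -0.05), (5.0, 1.0),
    ])
    def test_breakpoint_consistency_for_slope_ratios_above_five(self, slope,
                                                                plateau_slope):
        sig = piecewise_linear_signal(t_d=10.0, slope=slope, t_break=35.0,
                                      t_end=80.0, plateau_slope=plateau_slope)
        res = dc.transient_lifetime(sig, 10.0)
        assert abs(res.deactivation_time - 35.0) <= 0.5

    def test_flat_trace_raises_no_activation(self):
        t = np.arange(0, 60, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=np.ones_like(t))
        with pytest.raises(NoActivationError):
            dc.transient_lifetime(sig, 10.0)

    def test_noisy_flat_trace_raises_no_activation(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t,
                             values=1.0 + rng.normal(0, 0.05, t.size))
        with pytest.raises(NoActivationError):
            dc.transient_lifetime(sig, 10.0)

    def test_pure_ramp_has_no_breakpoint(self):
        # signal keeps rising: rise and plateau fits are parallel
        t = np.arange(0, 60, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=0.1 * t)
        with pytest.raises(NoBreakpointError):
            dc.transient_lifetime(sig, 0.0)

    def test_too_few_samples_rejected(self):
        t = np.arange(0, 3, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=t.copy())
        with pytest.raises(InsufficientDataError):
            dc.transient_lifetime(sig, 0.0)

    @given(st.floats(min_value=0.05, max_value=50.0))
    def test_scale_equivariance(self, c):
        sig = piecewise_linear_signal(t_d=15.0, slope=1.0, t_break=40.0,
                                      plateau_slope=0.01)
        tau = dc.transient_lifetime(sig, 15.0).lifetime
        scaled = sig.replace(values=c * sig.values)
        tau_c = dc.transient_lifetime(scaled, 15.0).lifetime
        assert tau_c == pytest.approx(tau, rel=1e-9)

    @given(st.floats(min_value=-10.0, max_value=100.0))
    def test_time_shift_equivariance(self, shift):
        sig = piecewise_linear_signal(t_d=15.0, slope=1.0, t_break=40.0,
                                      plateau_slope=0.01)
        tau = dc.transient_lifetime(sig, 15.0).lifetime
        shifted = sig.replace(time=sig.time + shift)
        tau_s = dc.transient_lifetime(shifted, 15.0 + shift).lifetime
        assert tau_s == pytest.approx(tau, rel=1e-9)

    def test_low_noise_bias_on_canonical_cycle(self, dz_clean_cycle):
        clean, _ = dz_clean_cycle
        tau0 = dc.transient_lifetime(clean, 15.0).lifetime
        dyn = float(clean.values.max() - clean.values.min())
        taus = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noisy = clean.replace(
                values=clean.values + rng.normal(0, 0.02 * dyn, clean.values.shape))
            taus.append(dc.transient_lifetime(noisy, 15.0).lifetime)
        assert abs(np.mean(taus) - tau0) / tau0 < 0.05


class TestSegmentation:
    def test_published_dose_times_give_seven_windows(self):
        from dissipycle.synthetic import RECYCLABILITY_DOSES_DNAZYME as doses
        t = np.arange(0, 300.5, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=np.sqrt(t))
        wins = dc.segment_cycles(sig, doses)
        assert len(wins) == 7
        assert wins[0].t_start == 15.0 and wins[0].t_end == 45.5
        assert wins[-1].t_end == t[-1]
        assert wins[0].baseline == pytest.approx(np.sqrt(15.0))

    def test_single_dose_spans_to_trace_end(self):
        t = np.arange(0, 100.5, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=t.copy())
        (win,) = dc.segment_cycles(sig, [20.0])
        assert (win.t_start, win.t_end) == (20.0, 100.0)

    @pytest.mark.parametrize("times", [[30.0, 10.0], [10.0, 10.0], [10.0, 200.0]])
    def test_bad_dose_times_rejected(self, times):
        t = np.arange(0, 100.5, 0.5)
        sig = dc.SignalTrace(channel="fluor520", time=t, values=t.copy())
        with pytest.raises(ValueError):
            dc.segment_cycles(sig, times)


class TestFatigue:
    def test_ideal_data_self_comparison_is_flat(self):
        design = dc.suite_design("recyclability")
        cond, sched = design.conditions[0], design.schedules[0]
        _, clean, _ = dc.generate_trace(cond, design.truth, sched,
                                        dc.NoiseModel(sigma=0.0), seed=0,
                                        t_end=design.t_end)
        net = dc.build_network(design.truth, cond)
        rep = dc.fatigue_report(clean, design.truth, net, cond, sched)
        f = np.array(rep.fatigue_index)
        assert np.all(np.abs(f[~np.isnan(f)]) <= 0.02)
        assert not rep.fatigue_detected

    def test_waste_inhibition_gives_growing_positive_indices(self):
        design = dc.suite_design("recyclability")
        cond, sched = design.conditions[0], design.schedules[0]
        truth_fatigued = design.truth.replace(K_W=5.0)
        _, clean, _ = dc.generate_trace(cond, truth_fatigued, sched,
                                        dc.NoiseModel(sigma=0.0), seed=0,
                                        t_end=design.t_end)
        net = dc.build_network(truth_fatigued, cond)
        rep = dc.fatigue_report(clean, design.truth, net, cond, sched)
        f = np.array(rep.fatigue_index)
        defined = f[~np.isnan(f)]
        assert defined.size >= 5
        assert np.all(defined > 0)
        assert np.all(np.diff(defined) >= 0)
        assert rep.fatigue_detected

    def test_reporter_depletion_shrinks_cycle_amplitudes(self):
        design = dc.suite_design("recyclability")
        cond, sched = design.conditions[0], design.schedules[0]
        _, clean, _ = dc.generate_trace(cond, design.truth, sched,
                                        dc.NoiseModel(sigma=0.0), seed=0,
                                        t_end=design.t_end)
        net = dc.build_network(design.truth, cond)
        rep = dc.fatigue_report(clean, design.truth, net, cond, sched)
        amps = np.array(rep.delta_signal)
        assert np.all(np.diff(amps) < 0)
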