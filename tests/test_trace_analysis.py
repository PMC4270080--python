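"""Operational trace measurements on constructed waveforms with known answers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrospike.trace_analysis import (
    MeasurementError,
    Trace,
    ap_threshold,
    detect_spikelet,
    dvdt,
    epsp_amplitude,
    latency_difference,
    phase_plane,
    ppr,
    rise_time_20_80,
    sag_ratio,
)

DT40 = 0.025  # 40 kHz
DT20 = 0.05  # 20 kHz


def biexp(t, onset, amp, tau_rise, tau_decay):
    """Peak-normalized double-exponential transient."""
    s = np.maximum(t - onset, 0.0)
    kern = np.exp(-s / tau_decay) - np.exp(-s / tau_rise)
    kern[t < onset] = 0.0
    tp = tau_rise * tau_decay / (tau_decay - tau_rise) * math.log(tau_decay / tau_rise)
    return amp * kern / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def make_epsp(amp=10.0, onset=10.0, dt=DT40, duration=120.0, baseline=-70.0,
              tau_rise=2.0, tau_decay=20.0):
    t = np.arange(0.0, duration, dt)
    return Trace(t, baseline + biexp(t, onset, amp, tau_rise, tau_decay))


class TestDvdt:
    def test_linear_ramp(self):
        t = np.arange(0.0, 1.0, DT40)
        tr = Trace(t, -70.0 + 10.0 * t)  # 10 mV over 1 ms
        d = dvdt(tr).samples
        assert np.allclose(d, 10.0)

    def test_constant_trace_zero(self):
        t = np.arange(0.0, 5.0, DT40)
        d = dvdt(Trace(t, np.full_like(t, -70.0))).samples
        assert np.allclose(d, 0.0)

    def test_sine_peak_derivative(self):
        a, freq = 5.0, 0.2  # mV, kHz
        omega = 2 * math.pi * freq
        t = np.arange(0.0, 20.0, DT40)
        d = dvdt(Trace(t, a * np.sin(omega * t))).samples
        assert np.max(np.abs(d)) == pytest.approx(a * omega, rel=0.01)

    def test_too_short(self):
        with pytest.raises(MeasurementError):
            dvdt(Trace(np.array([0.0, 0.1]), np.array([-70.0, -69.0])))


class TestPhasePlane:
    def test_ramp_is_horizontal_line(self):
        t = np.arange(0.0, 2.0, DT40)
        pp = phase_plane(Trace(t, -70.0 + 4.0 * t))
        assert np.allclose(pp[:, 1], 4.0)

    def test_exponential_relaxation_slope(self):
        # dV/dt = (V_inf - V)/tau: a straight line of slope -1/tau
        tau, v_inf, v0 = 10.0, -60.0, -80.0
        t = np.arange(0.0, 80.0, DT40)
        tr = Trace(t, v_inf + (v0 - v_inf) * np.exp(-t / tau))
        pp = phase_plane(tr)
        slope = np.polyfit(pp[5:-5, 0], pp[5:-5, 1], 1)[0]
        assert slope == pytest.approx(-1.0 / tau, rel=0.01)

    def test_spike_encloses_area(self):
        t = np.arange(0.0, 30.0, DT40)
        v = -70 + biexp(t, 10.0, 90.0, 0.2, 1.0)
        pp = phase_plane(Trace(t, v))
        area = np.trapezoid(pp[:, 1], pp[:, 0])
        assert abs(area) > 0


class TestAPThreshold:
    def make_piecewise(self, dt=DT40):
        """Slope 5 V/s from -70 to -50, then 60 V/s up to +20, then decay."""
        t1 = np.arange(0.0, 4.0, dt)  # 5 V/s * 4 ms = 20 mV
        seg1 = -70.0 + 5.0 * t1
        t2 = np.arange(0.0, 70.0 / 60.0, dt)
        seg2 = seg1[-1] + 60.0 * (t2 + dt)
        t3 = np.arange(0.0, 5.0, dt)
        seg3 = seg2[-1] - 40.0 * (t3 + dt)
        v = np.concatenate([seg1, seg2, seg3])
        return Trace(np.arange(v.size) * dt, v)

    @pytest.mark.parametrize("criterion", [10.0, 50.0])
    def test_constructed_crossing_recovered(self, criterion):
        tr = self.make_piecewise()
        ev = ap_threshold(tr, criterion)
        assert ev is not None
        # analytic crossing at -50 mV, recovered at sample resolution
        assert ev.threshold_voltage == pytest.approx(-50.0, abs=60.0 * DT40 + 1e-9)
        assert ev.peak_voltage > 0
        assert ev.criterion == criterion

    def test_subthreshold_epsp_gives_none(self):
        tr = make_epsp(amp=8.0)  # max dV/dt well under 10 V/s
        assert np.max(dvdt(tr).samples) < 10.0
        assert ap_threshold(tr, 10.0) is None

    def test_criterion_ordering_on_gradual_spike(self):
        # exponential acceleration: threshold(10) <= threshold(50)
        t = np.arange(0.0, 12.0, DT40)
        v = -70.0 + 0.05 * np.exp(t / 1.2)
        v = np.minimum(v, 30.0)
        tr = Trace(t, v)
        e10, e50 = ap_threshold(tr, 10.0), ap_threshold(tr, 50.0)
        assert e10 is not None and e50 is not None
        assert e10.threshold_voltage <= e50.threshold_voltage


class TestSpikeletDetection:
    def test_pure_epsp_empty(self):
        assert detect_spikelet(make_epsp(amp=15.0)) == []

    def test_epsp_with_fast_kernel_detected(self):
        tr = make_epsp(amp=10.0)
        fast = biexp(tr.time, 13.0, 18.0, 0.3, 3.0)
        tr2 = Trace(tr.time, tr.samples + fast)
        assert tr2.samples.max() < 0.0
        evs = detect_spikelet(tr2)
        assert len(evs) == 1
        assert evs[0].peak_dvdt >= 10.0

    def test_roc_on_seeded_fixture_suite(self):
        """Sensitivity and specificity >= 0.95 on 200 noisy synthetic traces."""
        rng = np.random.default_rng(2024)
        tp = fp = 0
        n_each = 100
        for i in range(2 * n_each):
            has_spikelet = i < n_each
            amp = rng.uniform(5.0, 20.0)
            t = np.arange(0.0, 120.0, DT20)
            # distal-input somatic EPSP kinetics: ~6 ms 20-80% rise
            v = -70.0 + biexp(t, 10.0, amp, 4.0, 40.0)
            if has_spikelet:
                v = v + biexp(t, rng.uniform(12.0, 16.0), rng.uniform(8.0, 20.0),
                              0.3, 3.0)
            v = v + rng.normal(0.0, 0.2, v.size)
            detected = len(detect_spikelet(Trace(t, v))) > 0
            if has_spikelet and detected:
                tp += 1
            elif not has_spikelet and detected:
                fp += 1
        sensitivity = tp / n_each
        specificity = 1 - fp / n_each
        assert sensitivity >= 0.95
        assert specificity >= 0.95


class TestEPSPAmplitude:
    def test_clean_epsp_both_modes(self):
        tr = make_epsp(amp=10.0)
        assert epsp_amplitude(tr, 10.0) == pytest.approx(10.0, abs=0.05)
        assert epsp_amplitude(tr, 10.0, dspike_aware=True) == pytest.approx(10.0, abs=0.05)

    def test_early_spikelet_excluded_when_aware(self):
        tr = make_epsp(amp=10.0, tau_rise=2.0, tau_decay=30.0)
        spike = biexp(tr.time, 12.0, 9.0, 0.2, 0.8)  # brief, peaks ~2.4 ms post-stim
        tr2 = Trace(tr.time, tr.samples + spike)
        assert epsp_amplitude(tr2, 10.0) > 13.0  # without flag: transient peak
        assert epsp_amplitude(tr2, 10.0, dspike_aware=True) == pytest.approx(10.0, abs=0.6)

    def test_flat_trace_zero(self):
        t = np.arange(0.0, 50.0, DT40)
        tr = Trace(t, np.full_like(t, -70.0))
        assert epsp_amplitude(tr, 10.0) == 0.0

    def test_stimulus_outside_trace(self):
        with pytest.raises(MeasurementError):
            epsp_amplitude(make_epsp(), 500.0)


class TestRiseTime:
    def test_linear_ramp(self):
        t = np.arange(0.0, 40.0, DT40)
        v = -70.0 + np.clip((t - 10.0), 0.0, 10.0)  # 0 -> 10 mV over 10 ms
        assert rise_time_20_80(Trace(t, v), 10.0) == pytest.approx(6.0, abs=2 * DT40)

    def test_single_exponential_closed_form(self):
        tau = 5.0
        t = np.arange(0.0, 120.0, DT40)
        v = -70.0 + 10.0 * (1 - np.exp(-np.maximum(t - 10.0, 0.0) / tau))
        expected = tau * math.log(0.8 / 0.2)  # 6.93 ms
        assert rise_time_20_80(Trace(t, v), 10.0) == pytest.approx(expected, rel=0.01)

    def test_step_within_one_sample(self):
        t = np.arange(0.0, 20.0, DT40)
        v = np.where(t >= 10.0, -60.0, -70.0)
        assert rise_time_20_80(Trace(t, v), 10.0) <= DT40


class TestPPR:
    def test_identical_epsps(self):
        t = np.arange(0.0, 150.0, DT40)
        v = -70.0 + biexp(t, 10.0, 8.0, 2.0, 15.0) + biexp(t, 60.0, 8.0, 2.0, 15.0)
        assert ppr(Trace(t, v), 10.0, 60.0) == pytest.approx(1.0, abs=0.05)

    def test_facilitated_second_pulse(self):
        t = np.arange(0.0, 150.0, DT40)
        v = -70.0 + biexp(t, 10.0, 8.0, 2.0, 15.0) + biexp(t, 60.0, 12.0, 2.0, 15.0)
        assert ppr(Trace(t, v), 10.0, 60.0) == pytest.approx(1.5, abs=0.08)

    def test_flat_first_response_is_error(self):
        t = np.arange(0.0, 150.0, DT40)
        with pytest.raises(MeasurementError):
            ppr(Trace(t, np.full_like(t, -70.0)), 10.0, 60.0)


class TestSagAndPassive:
    def test_sag_requires_hyperpolarizing_step(self):
        t = np.arange(0.0, 300.0, DT20)
        v = -70.0 + 5.0 * (t > 10.0)
        with pytest.raises(MeasurementError):
            sag_ratio(Trace(t, v), 10.0, 290.0)

    def test_pure_exponential_step_has_no_sag(self):
        t = np.arange(0.0, 400.0, DT20)
        v = -70.0 - 10.0 * (1 - np.exp(-np.maximum(t - 10.0, 0.0) / 30.0))
        assert sag_ratio(Trace(t, v), 10.0, 390.0) < 1e-3


class TestLatency:
    def test_identical_traces_zero(self):
        tr = make_epsp(amp=20.0, tau_rise=0.3, tau_decay=3.0)  # fast: crosses 10 V/s
        assert latency_difference({"a": tr, "b": tr}, "a", "b") == 0.0

    def test_shifted_copy(self):
        t = np.arange(0.0, 60.0, DT40)
        va = -70.0 + biexp(t, 10.0, 20.0, 0.3, 3.0)
        vb = -70.0 + biexp(t, 10.5, 20.0, 0.3, 3.0)
        d = latency_difference({"a": Trace(t, va), "b": Trace(t, vb)}, "a", "b")
        assert d == pytest.approx(0.5, abs=2 * DT40)

    def test_missing_event_is_error(self):
        slow = make_epsp(amp=5.0)
        fast = make_epsp(amp=20.0, tau_rise=0.3, tau_decay=3.0)
        with pytest.raises(MeasurementError):
            latency_difference({"a": fast, "b": slow}, "a", "b")


class TestInvariances:
    @settings(derandomize=True, max_examples=20)
    @given(shift=st.floats(-20.0, 20.0), offset=st.floats(-10.0, 10.0))
    def test_translation_invariance(self, shift, offset):
        """Time shift leaves durations unchanged; voltage offset shifts
        absolute-voltage outputs by the offset and leaves amplitudes alone."""
        t = np.arange(0.0, 120.0, DT20)
        v = -70.0 + biexp(t, 30.0, 12.0, 2.0, 20.0)
        a = Trace(t, v)
        b = Trace(t + shift, v + offset)
        ra = rise_time_20_80(a, 30.0)
        rb = rise_time_20_80(b, 30.0 + shift)
        assert rb == pytest.approx(ra, abs=1e-9)
        assert epsp_amplitude(b, 30.0 + shift) == pytest.approx(
            epsp_amplitude(a, 30.0), abs=1e-9)

    def test_sampling_rate_robustness(self):
        """Metrics change by < 2% when sampling doubles from 20 to 40 kHz."""
        for dt in (DT20, DT40):
            pass
        metrics = {}
        for dt in (DT20, DT40):
            t = np.arange(0.0, 150.0, dt)
            v = (-70.0 + biexp(t, 10.0, 12.0, 2.0, 20.0)
                 + biexp(t, 70.0, 12.0, 2.0, 20.0))
            tr = Trace(t, v)
            metrics[dt] = (
                epsp_amplitude(tr, 10.0),
                rise_time_20_80(tr, 10.0),
                ppr(tr, 10.0, 70.0),
                np.max(dvdt(tr).samples),
            )
        for a, b in zip(metrics[DT20], metrics[DT40]):
            assert b == pytest.approx(a, rel=0.02)


class TestPassiveConstants:
    def test_isopotential_constants_from_simulated_step(self):
        from dendrospike.simulator import (CurrentStimulus, SimulationConfig,
                                           discretize, initialize, run)
        from dendrospike.trace_analysis import passive_constants
        from conftest import make_passive_biophysics, make_soma_only

        model = discretize(make_soma_only(), make_passive_biophysics(), 10.0)
        model = initialize(model, SimulationConfig(settle=0.0))
        stim = CurrentStimulus(0, "step", -0.01, onset=10.0, duration=500.0)
        ts = run(model, (), (stim,),
                 SimulationConfig(dt=0.05, duration=450.0, settle=0.0))
        r_in, tau = passive_constants(Trace(ts.time, ts.voltages["soma[0.5]"]),
                                      10.0, 410.0, -0.01)
        assert tau == pytest.approx(30.0, rel=0.01)
        expected_r = 40_000.0 / model.areas[0] / 1e6
        assert r_in == pytest.approx(expected_r, rel=0.01)

    def test_spine_factor_halves_r_input_keeps_tau(self):
        from dendrospike.simulator import (CurrentStimulus, SimulationConfig,
                                           discretize, initialize, run)
        from dendrospike.trace_analysis import passive_constants
        from conftest import make_passive_biophysics, make_stick

        results = {}
        for f in (1.0, 2.0):
            model = discretize(make_stick(length=200.0, diameter=2.0),
                               make_passive_biophysics(spine_factor=f), 10.0)
            model = initialize(model, SimulationConfig(settle=0.0))
            stim = CurrentStimulus(0, "step", -0.01, onset=10.0, duration=600.0)
            ts = run(model, (), (stim,),
                     SimulationConfig(dt=0.05, duration=550.0, settle=0.0))
            results[f] = passive_constants(
                Trace(ts.time, ts.voltages["soma[0.5]"]), 10.0, 510.0, -0.01)
        # doubling the spine factor roughly halves R_input (soma uncorrected,
        # so not exactly half) and leaves tau_m unchanged
        assert results[2.0][0] < 0.62 * results[1.0][0]
        assert results[2.0][1] == pytest.approx(results[1.0][1], rel=0.05)
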