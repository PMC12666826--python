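import dataclasses
import math

import numpy as np
import pytest

from aclrqc import (
    JointModel,
    MetricError,
    SegmentationError,
    Trace,
    analyze_spring_check,
    compute_creep,
    detect_catch,
    detect_rupture,
    extract_metrics,
    fit_stiffness,
    precond_amplitude_error,
    segment_phases,
    simulate_trace,
    spring_model,
)
from aclrqc.metrics import DetectionParams


def strip_phase(trace):
    return Trace(trace.time, trace.displacement, trace.load, trace.sample_rate)


def creep_superposition_oracle(dj, tau):
    T = 40.0
    return dj * (
        (1 - math.exp(-T / tau))
        + (1 - math.exp(-(T - 10) / tau))
        - (1 - math.exp(-(T - 30) / tau))
    )


class TestSegmentation:
    def test_command_channel_passthrough(self, noiseless_aclr):
        trace = noiseless_aclr.trace
        seg = segment_phases(trace)
        assert seg.method == "command_channel"
        ch = trace.command_phase
        for k in range(1, 6):
            s, e = seg.phase(k)
            assert np.all(ch[s:e] == k)

    def test_signal_detection_within_50ms_of_truth(self, noiseless_aclr):
        trace = noiseless_aclr.trace
        truth = segment_phases(trace)
        detected = segment_phases(strip_phase(trace))
        assert detected.method == "signal_detected"
        tol = int(0.05 * trace.sample_rate)
        for k in range(1, 6):
            (s1, e1), (s2, e2) = truth.phase(k), detected.phase(k)
            assert abs(s1 - s2) <= tol
        # ramp onset in particular
        assert abs(truth.phase(4)[0] - detected.phase(4)[0]) <= tol

    def test_flat_trace_raises(self):
        n = 45000
        trace = Trace(np.arange(n) / 1000.0, np.zeros(n), np.zeros(n), 1000.0)
        with pytest.raises(SegmentationError, match="onset"):
            segment_phases(trace)


class TestCreep:
    def test_elastic_joint_shows_no_creep(self):
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.0,
                       creep_compliance_extra=0.0)
        res = simulate_trace(m, seed=0, tracking_tau=1e-9)
        c = compute_creep(res.trace, segment_phases(res.trace))
        assert abs(c) <= 1e-6

    @pytest.mark.parametrize("dj,tau", [(0.02, 5.0), (0.01, 3.0), (0.03, 8.0),
                                        (0.015, 2.0)])
    def test_matches_closed_form_within_5pct(self, dj, tau):
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.0,
                       creep_compliance_extra=dj, retardation_time=tau)
        res = simulate_trace(m, seed=0, tracking_tau=1e-9)
        c = compute_creep(res.trace, segment_phases(res.trace))
        assert c == pytest.approx(creep_superposition_oracle(dj, tau), rel=0.05)

    def test_strictly_increasing_in_compliance(self):
        creeps = []
        for dj in (0.01, 0.02, 0.04):
            m = JointModel(failure_displacement=1.1, load_noise_sd=0.0,
                           creep_compliance_extra=dj)
            res = simulate_trace(m, seed=0)
            creeps.append(compute_creep(res.trace, segment_phases(res.trace)))
        assert creeps[0] < creeps[1] < creeps[2]

    def test_preload_never_reached_raises(self, noiseless_aclr):
        trace = noiseless_aclr.trace
        low = Trace(trace.time, trace.displacement, trace.load * 0.1,
                    trace.sample_rate, trace.command_phase)
        with pytest.raises(MetricError, match="preload"):
            compute_creep(low, segment_phases(low))


class TestPrecondAmplitudeError:
    def test_ideal_tracking_is_nearly_error_free(self):
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.0)
        res = simulate_trace(m, seed=0, tracking_tau=1e-9)
        err = precond_amplitude_error(res.trace, segment_phases(res.trace))
        # only the value-averaging window's tiny attenuation remains
        assert err == pytest.approx(0.0, abs=0.1)

    def test_hand_computed_example(self):
        # all peaks 2.9 N, all valleys 1.05 N -> 100*((0.1/3 + 0.05/1)/2)
        fs = 1000.0
        n = 45000
        t = np.arange(n) / fs
        phase = np.full(n, 5)
        phase[:10000] = 1
        phase[10000:30000] = 2
        phase[30000:40000] = 3
        phase[40000:40166] = 4
        load = np.full(n, 1.0)
        t2 = t[10000:30000] - 10.0
        load[10000:30000] = 1.975 - 0.925 * np.cos(2 * np.pi * 0.5 * t2)
        trace = Trace(t, np.zeros(n), load, fs, command_phase=phase)
        err = precond_amplitude_error(trace, segment_phases(trace))
        assert err == pytest.approx(100 * ((0.1 / 3 + 0.05 / 1) / 2), abs=0.1)
        assert err == pytest.approx(4.17, abs=0.1)

    def test_first_order_lag_matches_frequency_response(self):
        # differential oracle: the lag's contribution over the ideal-tracking
        # baseline must equal the first-order frequency-response prediction
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.0)
        lag = simulate_trace(m, seed=0, tracking_tau=0.05)
        ideal = simulate_trace(m, seed=0, tracking_tau=1e-9)
        err_lag = precond_amplitude_error(lag.trace, segment_phases(lag.trace))
        err_ideal = precond_amplitude_error(ideal.trace, segment_phases(ideal.trace))
        g = 1.0 / math.sqrt(1.0 + (2 * math.pi * 0.5 * 0.05) ** 2)
        predicted = 100.0 * 0.5 * ((1 - g) / 3.0 + (1 - g) / 1.0)
        assert err_lag - err_ideal == pytest.approx(predicted, rel=0.05)

    def test_noise_does_not_inflate_amplitude_error(self):
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.05)
        res = simulate_trace(m, seed=4)
        err = precond_amplitude_error(res.trace, segment_phases(res.trace))
        assert err < 3.0  # realistic 1-5 % QC band, not noise-driven blowup

    def test_missing_extrema_raises(self, noiseless_aclr):
        trace = noiseless_aclr.trace
        flat = Trace(trace.time, trace.displacement,
                     np.full(trace.n_samples, 2.0), trace.sample_rate,
                     trace.command_phase)
        with pytest.raises(MetricError, match="extrema"):
            precond_amplitude_error(flat, segment_phases(flat))


class TestDetectRupture:
    def test_no_rupture_returns_none(self):
        m = JointModel(failure_displacement=2.0, failure_mode="no_rupture",
                       load_noise_sd=0.05)
        res = simulate_trace(m, seed=0)
        assert detect_rupture(res.trace, segment_phases(res.trace)) is None

    def test_noiseless_recovery_is_exact(self, noiseless_aclr):
        ev = detect_rupture(noiseless_aclr.trace, segment_phases(noiseless_aclr.trace))
        assert ev is not None
        assert ev.displacement_at_rupture == pytest.approx(1.10, abs=0.02)
        assert ev.load_at_rupture == pytest.approx(
            noiseless_aclr.truth.rupture_load, abs=0.1
        )
        assert ev.drop_count == 1

    def test_two_stage_collapse_counts_two_drops(self):
        m = JointModel(failure_displacement=1.0, drop_fraction=0.5,
                       catch_stiffness=8.0, load_noise_sd=0.0)
        res = simulate_trace(m, seed=0)
        trace = res.trace
        seg = segment_phases(trace)
        rs, re = seg.phase(4)
        disp = trace.displacement - trace.displacement[rs]
        load = trace.load.copy()
        sel = slice(rs, re)
        second = (disp[sel] > 1.3)
        load[sel] = np.where(second, np.maximum(load[sel] - 3.0, 0.0), load[sel])
        modified = Trace(trace.time, trace.displacement, load,
                         trace.sample_rate, trace.command_phase)
        ev = detect_rupture(modified, segment_phases(modified))
        assert ev is not None
        assert ev.displacement_at_rupture == pytest.approx(1.0, abs=0.02)
        assert ev.drop_count == 2


class TestDetectCatch:
    def test_aclr_catch_is_detected(self, noiseless_aclr):
        trace = noiseless_aclr.trace
        seg = segment_phases(trace)
        ev = detect_rupture(trace, seg)
        caught, floor = detect_catch(trace, seg, ev)
        assert caught
        assert floor > 0.5

    def test_fracture_has_no_catch(self):
        m = JointModel(failure_displacement=1.0, failure_mode="fracture",
                       load_noise_sd=0.0)
        res = simulate_trace(m, seed=0)
        seg = segment_phases(res.trace)
        ev = detect_rupture(res.trace, seg)
        caught, floor = detect_catch(res.trace, seg, ev)
        assert not caught
        assert floor < 0.5

    def test_late_rupture_catch_via_floor_criterion(self):
        # failure near ramp end: no room to re-load, but the joint stays loaded
        m = JointModel(failure_displacement=1.44, drop_fraction=0.6,
                       catch_gap=0.15, load_noise_sd=0.0)
        res = simulate_trace(m, seed=0)
        seg = segment_phases(res.trace)
        ev = detect_rupture(res.trace, seg)
        assert ev is not None
        caught, floor = detect_catch(res.trace, seg, ev)
        assert caught
        assert floor >= 0.5


class TestFitStiffness:
    def test_noiseless_recovery(self):
        m = JointModel(failure_displacement=1.1, linear_stiffness=12.0,
                       load_noise_sd=0.0)
        res = simulate_trace(m, seed=0)
        seg = segment_phases(res.trace)
        ev = detect_rupture(res.trace, seg)
        fit = fit_stiffness(res.trace, seg, ev)
        assert fit.reliable
        assert fit.stiffness == pytest.approx(12.0, abs=0.1)

    def test_physis_stiffness_ratio(self):
        common = dict(failure_displacement=1.1, load_noise_sd=0.0)
        base = simulate_trace(JointModel(linear_stiffness=12.6, **common), seed=0)
        physis = simulate_trace(
            JointModel(linear_stiffness=12.6 * 1.5, failure_mode="physis", **common),
            seed=0,
        )
        ratio = (
            fit_stiffness(physis.trace, segment_phases(physis.trace),
                          detect_rupture(physis.trace, segment_phases(physis.trace))).stiffness
            / fit_stiffness(base.trace, segment_phases(base.trace),
                            detect_rupture(base.trace, segment_phases(base.trace))).stiffness
        )
        assert ratio == pytest.approx(1.5, rel=0.02)

    def test_strictly_increasing_in_true_stiffness(self):
        vals = []
        for k in (10.0, 12.0, 14.0):
            m = JointModel(failure_displacement=1.2, linear_stiffness=k,
                           load_noise_sd=0.05)
            res = simulate_trace(m, seed=9)
            seg = segment_phases(res.trace)
            ev = detect_rupture(res.trace, seg)
            vals.append(fit_stiffness(res.trace, seg, ev).stiffness)
        assert vals[0] < vals[1] < vals[2]

    def test_short_prerupture_span_raises(self):
        m = JointModel(failure_displacement=0.28, drop_fraction=0.9,
                       load_noise_sd=0.0)
        res = simulate_trace(m, seed=0)
        seg = segment_phases(res.trace)
        ev = detect_rupture(res.trace, seg)
        assert ev is not None
        with pytest.raises(MetricError, match="window"):
            fit_stiffness(res.trace, seg, ev)


class TestExtractMetrics:
    def test_noiseless_end_to_end_recovery(self, noiseless_aclr, noiseless_metrics):
        truth = noiseless_aclr.truth
        m = noiseless_metrics
        assert m.rupture_displacement == pytest.approx(truth.rupture_displacement,
                                                       abs=0.02)
        assert m.rupture_load == pytest.approx(truth.rupture_load, abs=0.1)
        assert m.linear_stiffness == pytest.approx(truth.linear_stiffness, rel=0.03)
        assert m.total_creep == pytest.approx(truth.total_creep, rel=0.05)
        assert m.catch_detected is True
        assert m.drop_count == 1
        assert m.ultimate_load >= m.rupture_load

    def test_ultimate_displacement_never_exceeds_command(self, noiseless_metrics):
        assert noiseless_metrics.ultimate_displacement <= 1.5
        assert noiseless_metrics.displacement_error_pct <= 0.2

    def test_no_rupture_schema(self):
        m = JointModel(failure_displacement=2.0, failure_mode="no_rupture",
                       load_noise_sd=0.05)
        res = simulate_trace(m, seed=0)
        met = extract_metrics(res.trace, segment_phases(res.trace))
        assert met.rupture_displacement is None
        assert met.rupture_load is None
        assert met.catch_detected is None
        assert met.drop_count == 0
        assert met.ultimate_displacement > 0
        assert met.ultimate_load > 0

    def test_invariant_to_time_offset(self):
        m = JointModel(failure_displacement=1.1, load_noise_sd=0.05)
        res = simulate_trace(m, seed=3)
        tr = res.trace
        shifted = Trace(tr.time + 123.456, tr.displacement, tr.load,
                        tr.sample_rate, tr.command_phase)
        a = extract_metrics(tr, segment_phases(tr))
        b = extract_metrics(shifted, segment_phases(shifted))
        for f in ("rupture_displacement", "rupture_load", "linear_stiffness",
                  "total_creep", "ultimate_displacement", "ultimate_load"):
            assert getattr(a, f) == pytest.approx(getattr(b, f), rel=1e-9)


class TestSpringCheck:
    def test_ideal_spring_passes(self):
        res = simulate_trace(spring_model(10.0), seed=0)
        check = analyze_spring_check(res.trace, 10.0, tolerance_pct=5.0)
        assert check.passed
        assert check.deviation_pct == pytest.approx(0.0, abs=0.1)
        assert not check.instrument_fault

    def test_drifted_spring_fails(self):
        res = simulate_trace(spring_model(10.8), seed=0)
        check = analyze_spring_check(res.trace, 10.0, tolerance_pct=5.0)
        assert not check.passed
        assert check.deviation_pct == pytest.approx(8.0, abs=0.5)
        assert not check.instrument_fault

    def test_drop_artifact_flags_instrument_fault(self):
        res = simulate_trace(spring_model(10.0), seed=0)
        tr = res.trace
        seg = segment_phases(tr)
        rs, re = seg.phase(4)
        disp = tr.displacement - tr.displacement[rs]
        load = tr.load.copy()
        sel = slice(rs, re)
        load[sel] = np.where(disp[sel] > 1.0, np.maximum(load[sel] - 6.0, 0.2),
                             load[sel])
        broken = Trace(tr.time, tr.displacement, load, tr.sample_rate,
                       tr.command_phase)
        check = analyze_spring_check(broken, 10.0, tolerance_pct=5.0)
        assert check.instrument_fault
        assert not check.passed
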