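"""Quantification stage: ratiometry, baseline, 2-SD detection, response
window localisation, amplitude, AUC and the no-return exclusion rule."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tastecalc.presets import get_preset
from tastecalc.quantify import (
    DataError,
    QuantConfig,
    compute_ratio,
    detect_response,
    estimate_baseline,
    integrate_response,
    locate_response_window,
    quantify_amplitude,
    quantify_cell,
    quantify_epoch,
)
from tastecalc.simulate import (
    TraceGenParams,
    calibrate_decay,
    simulate_preset_traces,
    simulate_trace,
    time_to_peak,
)
from tastecalc.trace import StimulusEpoch, Trace, TraceValidationError

from conftest import make_trace


class TestComputeRatio:
    def test_equal_channels_give_unity(self):
        tr = Trace("c", np.arange(10.0), f340=np.full(10, 7.0),
                   f380=np.full(10, 7.0))
        assert np.allclose(compute_ratio(tr).ratio, 1.0)

    def test_doubled_numerator(self):
        tr = Trace("c", np.arange(10.0), f340=np.full(10, 4.0),
                   f380=np.full(10, 2.0))
        assert np.allclose(compute_ratio(tr).ratio, 2.0)

    def test_zero_denominator_reports_sample_index(self):
        f380 = np.full(10, 2.0)
        f380[3] = 0.0
        tr = Trace("c", np.arange(10.0), f340=np.ones(10), f380=f380)
        with pytest.raises(DataError, match="index 3"):
            compute_ratio(tr)

    def test_existing_ratio_passthrough(self):
        tr = make_trace(np.ones(10))
        assert compute_ratio(tr) is tr


class TestEstimateBaseline:
    def test_constant_trace(self, epoch):
        tr = make_trace(np.full(100, 1.3), epochs=[epoch])
        stats = estimate_baseline(tr, epoch)
        assert stats.mean == pytest.approx(1.3)
        assert stats.sd < 1e-6  # epsilon floor, not literal zero

    def test_two_sample_hand_case(self):
        # window [0, 2) holds exactly {1.0, 1.2}: mean 1.1, sample SD 0.1414
        ep = StimulusEpoch("SAC", 2.0, 2.0, 5.0)
        tr = make_trace([1.0, 1.2, 2.0, 2.0, 2.0, 2.0])
        stats = estimate_baseline(tr, ep, window_s=2.0, min_samples=2)
        assert stats.mean == pytest.approx(1.1)
        assert stats.sd == pytest.approx(math.sqrt(0.02), rel=1e-9)
        assert stats.sd == pytest.approx(0.1414, abs=5e-5)

    def test_window_before_trace_start_rejected(self, epoch):
        tr = make_trace(np.ones(100), epochs=[epoch])
        with pytest.raises(DataError, match="before the trace"):
            estimate_baseline(tr, epoch, window_s=45.0)

    def test_too_few_samples_rejected(self):
        ep = StimulusEpoch("SAC", 2.0, 3.0, 6.0)
        tr = make_trace(np.ones(10))
        with pytest.raises(DataError, match="pre-stimulus samples"):
            estimate_baseline(tr, ep, window_s=3.0)


def _baseline_for(tr, epoch):
    return estimate_baseline(tr, epoch)


class TestDetectResponse:
    def test_flat_trace_not_responsive(self, epoch):
        tr = make_trace(np.ones(150), epochs=[epoch])
        responsive, idx = detect_response(tr, epoch, _baseline_for(tr, epoch))
        assert not responsive and idx is None

    def test_sustained_step_above_threshold(self, epoch):
        rng = np.random.default_rng(0)
        vals = 1.0 + rng.normal(0, 0.002, 150)
        vals[65:75] += 3 * 0.002
        tr = make_trace(vals, epochs=[epoch])
        responsive, idx = detect_response(tr, epoch, _baseline_for(tr, epoch),
                                          min_run=3)
        assert responsive
        assert 60 <= idx <= 70

    def test_single_sample_spike_rejected_by_run_rule(self, epoch):
        rng = np.random.default_rng(1)
        vals = 1.0 + rng.normal(0, 0.002, 150)
        vals[70] += 5 * 0.002
        tr = make_trace(vals, epochs=[epoch])
        baseline = _baseline_for(tr, epoch)
        responsive, _ = detect_response(tr, epoch, baseline, min_run=3)
        # brute-force oracle: scan every window of 3 consecutive samples
        thr = baseline.mean + 2 * baseline.sd
        in_win = (tr.time >= epoch.start_s) & (tr.time <= epoch.end_s + 60.0)
        above = (vals > thr) & in_win
        oracle = any(above[i:i + 3].all() for i in range(len(above) - 2))
        assert responsive == oracle

    @given(st.lists(st.booleans(), min_size=1, max_size=60),
           st.integers(1, 5))
    @settings(max_examples=200, deadline=None)
    def test_run_detection_matches_brute_force(self, mask, run):
        from tastecalc.quantify import _first_run
        mask = np.asarray(mask)
        brute = next(
            (i for i in range(len(mask) - run + 1) if mask[i:i + run].all()),
            None,
        )
        assert _first_run(mask, run) == brute

    def test_specificity_on_noise_only_cohort(self, epoch):
        # false-positive rate of the 2-SD + run-of-3 rule on pure noise
        p = TraceGenParams(epoch=epoch, responder=False, duration_total=150.0)
        n_traces, hits = 10_000, 0
        for i in range(n_traces):
            tr = simulate_trace(p, seed=np.random.SeedSequence(900, spawn_key=(i,)))
            responsive, _ = detect_response(tr, epoch, _baseline_for(tr, epoch))
            hits += responsive
        assert hits / n_traces <= 0.01

    def test_sensitivity_at_five_sigma_amplitude(self, epoch):
        # responders at amplitude 5 * (noise_sd / baseline) * 100 %
        amp = 5 * 0.002 * 100
        p = TraceGenParams(epoch=epoch, responder=True, amplitude_pct=amp,
                           duration_total=150.0)
        n_traces, hits = 1000, 0
        for i in range(n_traces):
            tr = simulate_trace(p, seed=np.random.SeedSequence(901, spawn_key=(i,)))
            responsive, _ = detect_response(tr, epoch, _baseline_for(tr, epoch))
            hits += responsive
        assert hits / n_traces >= 0.99


class TestLocateWindow:
    def test_square_pulse_onset_and_offset(self, square_pulse_trace, epoch):
        tr = square_pulse_trace
        baseline = estimate_baseline(tr, epoch)
        responsive, idx = detect_response(tr, epoch, baseline)
        assert responsive
        onset, offset, no_return = locate_response_window(tr, baseline, idx)
        assert not no_return
        assert onset == 61.0  # last at-baseline sample before the pulse
        assert offset == 72.0  # first sample back at baseline after the pulse

    def test_monotone_rise_never_returns(self, epoch):
        vals = np.ones(150)
        vals[61:] = 1.0 + 0.01 * np.arange(89)
        tr = make_trace(vals, epochs=[epoch])
        baseline = estimate_baseline(tr, epoch)
        _, idx = detect_response(tr, epoch, baseline)
        onset, offset, no_return = locate_response_window(tr, baseline, idx)
        assert no_return and offset is None

    def test_duration_round_trip_with_calibrated_decay(self, epoch):
        # noise-free trace scored against the nominal noise band the decay
        # was calibrated for
        from tastecalc.quantify import BaselineStats

        target = time_to_peak(2.0) + 46.0
        tau = calibrate_decay(50.0, target, noise_sd=0.002)
        p = TraceGenParams(epoch=epoch, amplitude_pct=50.0, noise_sd=0.0,
                           decay_tau=tau, duration_total=200.0)
        tr = simulate_trace(p, seed=0)
        baseline = BaselineStats(1.0, 0.002, (0.0, 30.0))
        responsive, idx = detect_response(tr, epoch, baseline)
        assert responsive
        onset, offset, no_return = locate_response_window(tr, baseline, idx)
        assert not no_return
        assert offset - onset == pytest.approx(target, abs=1.0)


class TestAmplitude:
    def test_peak_at_baseline_is_zero(self, epoch):
        tr = make_trace(np.ones(150), epochs=[epoch])
        baseline = estimate_baseline(tr, epoch)
        _, amp = quantify_amplitude(tr, baseline, 60.0, 80.0)
        assert amp == pytest.approx(0.0)

    @pytest.mark.parametrize("base,peak,expected", [
        (1.0, 1.742, 74.2),
        (2.0, 3.0, 50.0),
    ])
    def test_percent_formula(self, epoch, base, peak, expected):
        vals = np.full(150, base)
        vals[65] = peak
        tr = make_trace(vals, epochs=[epoch])
        baseline = estimate_baseline(tr, epoch)
        _, amp = quantify_amplitude(tr, baseline, 60.0, 80.0)
        assert amp == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_baseline_rejected(self, epoch):
        from tastecalc.quantify import BaselineStats
        tr = make_trace(np.ones(150), epochs=[epoch])
        with pytest.raises(DataError, match="baseline mean"):
            quantify_amplitude(tr, BaselineStats(0.0, 0.1, (0, 30)), 60.0, 80.0)


class TestIntegrateResponse:
    def test_flat_window_is_zero(self, epoch):
        tr = make_trace(np.ones(150), epochs=[epoch])
        baseline = estimate_baseline(tr, epoch)
        assert integrate_response(tr, baseline, 60.0, 80.0) == 0.0

    def test_square_pulse_area(self, square_pulse_trace, epoch):
        tr = square_pulse_trace
        baseline = estimate_baseline(tr, epoch)
        # 0.5 ratio units over 10 s; trapezoid ramps at both edges sum to one
        # full sample, giving exactly height * width
        auc = integrate_response(tr, baseline, 61.0, 72.0)
        assert auc == pytest.approx(5.0, rel=1e-9)

    def test_negative_excursions_clamped(self, epoch):
        vals = np.ones(150)
        vals[62:72] = 0.4  # dip below baseline
        tr = make_trace(vals, epochs=[epoch])
        baseline = estimate_baseline(tr, epoch)
        assert integrate_response(tr, baseline, 61.0, 72.0) == 0.0

    def test_inverted_window_rejected(self, square_pulse_trace, epoch):
        baseline = estimate_baseline(square_pulse_trace, epoch)
        with pytest.raises(DataError, match="offset"):
            integrate_response(square_pulse_trace, baseline, 72.0, 61.0)

    def test_auc_scales_linearly_with_amplitude(self, epoch):
        aucs = []
        for amp in (20.0, 40.0):
            p = TraceGenParams(epoch=epoch, amplitude_pct=amp, noise_sd=0.0,
                               decay_tau=10.0, duration_total=200.0)
            tr = simulate_trace(p, seed=0)
            baseline = estimate_baseline(tr, epoch)
            aucs.append(integrate_response(tr, baseline, 32.0, 199.0))
        assert aucs[1] / aucs[0] == pytest.approx(2.0, rel=1e-6)


class TestQuantifyCell:
    def test_nonresponsive_epoch_has_absent_measures(self, epoch):
        p = TraceGenParams(epoch=epoch, responder=False, duration_total=150.0)
        tr = simulate_trace(p, seed=4)
        (call,) = quantify_cell(tr)
        assert not call.responsive
        assert call.auc is None and call.duration_s is None
        assert call.amplitude_pct is None

    def test_preset_amplitude_recovered(self):
        preset = get_preset("ctl_SAC")
        tr = simulate_trace(preset.params, seed=9)
        (call,) = quantify_cell(tr)
        assert call.responsive
        assert call.amplitude_pct == pytest.approx(74.2, abs=3.0)

    def test_noise_free_amplitude_exact(self, epoch):
        p = TraceGenParams(epoch=epoch, amplitude_pct=37.8, noise_sd=0.0,
                           duration_total=240.0)
        (call,) = quantify_cell(simulate_trace(p, seed=0))
        assert call.amplitude_pct == pytest.approx(37.8, abs=1e-6)

    def test_noisy_cohort_mean_amplitude_within_three_se(self, epoch):
        p = TraceGenParams(epoch=epoch, amplitude_pct=37.8, duration_total=240.0)
        traces, _ = simulate_preset_traces(p, 100, seed=21, amplitude_cv=0.25)
        amps = [quantify_cell(tr)[0].amplitude_pct for tr in traces]
        amps = np.array([a for a in amps if a is not None])
        se = amps.std(ddof=1) / math.sqrt(amps.size)
        assert abs(amps.mean() - 37.8) < 3 * se

    def test_two_epochs_response_only_in_second(self):
        ep1 = StimulusEpoch("SAC", 2.0, 30.0, 60.0)
        ep2 = StimulusEpoch("DEN", 5.0, 180.0, 210.0)
        rng = np.random.default_rng(3)
        vals = 1.0 + rng.normal(0, 0.002, 300)
        vals[185:200] += 0.2
        tr = make_trace(vals, epochs=[ep2, ep1])  # order independent
        calls = quantify_cell(tr)
        assert [c.stimulus for c in calls] == ["SAC", "DEN"]
        assert [c.responsive for c in calls] == [False, True]

    def test_overlapping_epochs_rejected(self):
        ep1 = StimulusEpoch("SAC", 2.0, 30.0, 60.0)
        ep2 = StimulusEpoch("DEN", 5.0, 50.0, 90.0)
        tr = make_trace(np.ones(150), epochs=[ep1, ep2])
        with pytest.raises(TraceValidationError, match="overlap"):
            quantify_cell(tr)

    def test_no_return_call_keeps_amplitude_only(self, epoch):
        vals = np.ones(150)
        vals[61:] = 1.5  # steps up and never comes back
        tr = make_trace(vals, epochs=[epoch])
        (call,) = quantify_cell(tr)
        assert call.responsive and call.excluded_no_return
        assert call.amplitude_pct is not None
        assert call.auc is None and call.duration_s is None

    def test_duration_recovery_in_noisy_cohort_mean(self):
        preset = get_preset("ob_DEN")
        traces, _ = simulate_preset_traces(preset.params, 200, seed=31,
                                           amplitude_cv=preset.amplitude_cv)
        durs = [c.duration_s for tr in traces for c in quantify_cell(tr)
                if c.duration_s is not None]
        assert abs(np.mean(durs) - 65.5) / 65.5 < 0.10
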