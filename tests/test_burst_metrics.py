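"""Drive-potential quantification: spike detection, envelope
extraction, burst segmentation, classification, and summary statistics
— validated against exact generator ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prebotc.burst_metrics import (
    BurstEvent,
    MetricsConfig,
    UndefinedStatisticsError,
    burst_statistics,
    classify_discharge,
    classify_trace,
    detect_spikes,
    dp_envelope,
    measure_drive_current,
    segment_bursts,
)
from prebotc.simulator import Trace
from prebotc.synthetic import (default_templates, generate_drive_current,
                               generate_trace)


def flat_trace(v=-50.0, duration=20.0, dt=0.0005):
    t = np.arange(0.0, duration, dt)
    return Trace(t=t, V=np.full_like(t, v))


def square_trace(amps, dur=2.9, period=8.0, base=-52.7, dt=0.0005,
                 edge=0.08):
    """Noise-free smoothed-square DPs via the generator with zeroed
    randomness."""
    from dataclasses import replace
    tpl = replace(default_templates()["plateau"],
                  dp_amplitude=(np.mean(amps), 0.0),
                  dp_duration=(dur, 0.0), cycle_period=(period, 0.0),
                  noise_sd=0.0, spike_height=0.0, baseline_vm=base)
    tr, gt = generate_trace(tpl, len(amps), seed=0)
    return tr, gt


class TestDetectSpikes:
    def test_constant_trace_no_spikes(self):
        assert len(detect_spikes(flat_trace())) == 0

    def test_counts_generated_transients(self):
        tr = flat_trace(duration=10.0)
        t = tr.t
        V = tr.V.copy()
        times = np.arange(1.0, 9.5, 0.5)
        for s in times:
            V += 40.0 * np.exp(-0.5 * ((t - s) / 0.0015) ** 2)
        sp = detect_spikes(Trace(t=t, V=V))
        assert len(sp) == len(times)
        assert np.allclose(sp, times, atol=0.01)

    def test_spike_count_invariant_to_oversampling(self):
        dt = 0.00025
        t = np.arange(0.0, 10.0, dt)
        V = np.full_like(t, -50.0)
        for s in (2.0, 5.0, 8.0):
            V += 40.0 * np.exp(-0.5 * ((t - s) / 0.0015) ** 2)
        fine = detect_spikes(Trace(t=t, V=V))
        coarse = detect_spikes(Trace(t=t[::2], V=V[::2]))
        assert len(fine) == len(coarse) == 3


class TestEnvelope:
    def test_identity_on_spike_free_square_wave(self):
        tr, _ = square_trace([30.0] * 3)
        env = dp_envelope(tr)
        assert np.max(np.abs(env.V - tr.V)) < 1.0

    def test_strips_spikes_to_within_two_mv(self):
        from dataclasses import replace
        tpl = replace(default_templates()["plateau"], noise_sd=0.0)
        tr, _ = generate_trace(tpl, 3, seed=5)
        bare, _ = generate_trace(replace(tpl, spike_height=0.0), 3, seed=5)
        sp = detect_spikes(tr)
        env = dp_envelope(tr, spike_times=sp)
        assert np.max(np.abs(env.V - bare.V)) < 2.0

    def test_monotone_in_monotone_out(self):
        t = np.arange(0.0, 5.0, 0.001)
        tr = Trace(t=t, V=np.linspace(-60.0, -20.0, len(t)))
        env = dp_envelope(tr)
        assert np.all(np.diff(env.V) >= 0)

    def test_window_too_small_rejected(self):
        t = np.arange(0.0, 5.0, 0.05)  # 50 ms sampling
        with pytest.raises(ValueError):
            dp_envelope(Trace(t=t, V=np.zeros_like(t)), window_ms=50.0)


class TestSegmentation:
    def test_flat_trace_yields_no_events(self):
        assert segment_bursts(flat_trace()) == []

    def test_three_square_dps_measured_exactly(self):
        tr, gt = square_trace([30.0, 30.0, 30.0], dur=2.9)
        events = segment_bursts(dp_envelope(tr))
        assert len(events) == 3
        for e in events:
            assert e.dp_duration == pytest.approx(2.9, rel=0.05)
            assert e.dp_amplitude == pytest.approx(30.0, abs=0.5)

    def test_amplitude_invariant_to_dc_offset(self):
        tr, _ = square_trace([25.0] * 4)
        shifted = Trace(t=tr.t, V=tr.V + 17.0)
        a = [e.dp_amplitude for e in segment_bursts(dp_envelope(tr))]
        b = [e.dp_amplitude for e in segment_bursts(dp_envelope(shifted))]
        assert np.allclose(a, b, atol=0.2)

    def test_bimodal_amplitudes_both_detected(self):
        """Small-mode events must not be lost next to large ones."""
        from dataclasses import replace
        tpl = replace(default_templates()["mixed"], noise_sd=0.5)
        tr, gt = generate_trace(tpl, 20, seed=11)
        events = segment_bursts(dp_envelope(tr), spike_times=detect_spikes(tr))
        assert len(events) == len(gt)

    def test_edge_truncated_events_dropped(self):
        t = np.arange(0.0, 10.0, 0.0005)
        V = np.full_like(t, -50.0)
        V[t < 1.0] = -20.0            # event truncated at the left edge
        m = (t > 4.0) & (t < 6.0)
        V[m] = -20.0                  # complete interior event
        events = segment_bursts(Trace(t=t, V=V))
        assert len(events) == 1
        assert events[0].onset == pytest.approx(4.0, abs=0.1)


class TestClassification:
    def test_no_events_no_spikes_is_silent(self):
        tr = flat_trace()
        c = classify_discharge([], tr)
        assert c.label == "silent"
        assert c.events == []

    def test_plateau_label_from_long_blocked_events(self):
        tr = flat_trace()
        events = [BurstEvent(onset=o, offset=o + 2.9, dp_amplitude=30.0,
                             dp_duration=2.9, spike_times=[o + 0.2],
                             depol_block=True)
                  for o in (2.0, 10.0, 18.0)]
        c = classify_discharge(events, tr)
        assert c.label == "plateau"

    def test_even_mixture_is_mixed(self):
        tr = flat_trace()
        events = []
        for i, o in enumerate(np.arange(2.0, 50.0, 6.0)):
            dur = 2.9 if i % 2 == 0 else 0.79
            events.append(BurstEvent(onset=o, offset=o + dur,
                                     dp_amplitude=20.0, dp_duration=dur))
        c = classify_discharge(events, tr)
        assert c.label == "mixed"

    def test_rare_minority_does_not_make_mixed(self):
        tr = flat_trace(duration=80.0)
        events = [BurstEvent(onset=o, offset=o + 0.79, dp_amplitude=15.0,
                             dp_duration=0.79)
                  for o in np.arange(2.0, 70.0, 4.0)]
        events[0].dp_duration = 2.9
        events[0].offset = events[0].onset + 2.9
        c = classify_discharge(events, tr)
        assert c.label == "oscillatory"  # 1/18 long is below minority

    def test_few_events_flagged_indeterminate(self):
        tr = flat_trace()
        events = [BurstEvent(onset=2.0, offset=4.9, dp_amplitude=30.0,
                             dp_duration=2.9)]
        c = classify_discharge(events, tr)
        assert c.indeterminate
        assert c.label == "plateau"

    def test_tonic_spiking_without_quiescence(self):
        t = np.arange(0.0, 20.0, 0.0005)
        V = np.full_like(t, -45.0)
        for s in np.arange(0.05, 19.95, 0.1):  # 10 Hz continuous firing
            V += 40.0 * np.exp(-0.5 * ((t - s) / 0.0015) ** 2)
        c = classify_trace(Trace(t=t, V=V))
        assert c.label == "tonic"

    def test_classification_invariant_to_offset_shift_resample(self):
        tpl = default_templates()["mixed"]
        tr, _ = generate_trace(tpl, 14, seed=3)
        c0 = classify_trace(tr)
        shifted = Trace(t=tr.t + 100.0, V=tr.V + 12.0)
        c1 = classify_trace(shifted)
        half = Trace(t=tr.t[::2], V=tr.V[::2])
        c2 = classify_trace(half)
        assert c0.label == c1.label == c2.label == "mixed"


class TestStatistics:
    def test_empty_event_list_rejected(self):
        with pytest.raises(UndefinedStatisticsError):
            burst_statistics([])

    def test_single_event_flags_undefined_sd(self):
        ev = BurstEvent(onset=1.0, offset=3.9, dp_amplitude=30.0,
                        dp_duration=2.9)
        st_ = burst_statistics([ev])
        assert not st_["sd_defined"]
        assert st_["amplitude_mean"] == 30.0
        assert np.isnan(st_["amplitude_sd"])

    def test_periodic_train_frequency(self):
        period = 4.0
        events = [BurstEvent(onset=o, offset=o + 0.8, dp_amplitude=15.0,
                             dp_duration=0.8)
                  for o in np.arange(2.0, 42.0, period)]
        st_ = burst_statistics(events)
        assert st_["frequency_hz"] == pytest.approx(1.0 / period, rel=1e-9)

    def test_sampling_recovery_of_generator_means(self):
        """A large plateau-template sample recovers the template mean
        amplitude within two standard errors."""
        tpl = default_templates()["plateau"]
        tr, gt = generate_trace(tpl, 120, seed=99)
        events = segment_bursts(dp_envelope(tr, spike_times=detect_spikes(tr)),
                                spike_times=detect_spikes(tr))
        st_ = burst_statistics(events)
        gt_amp = np.mean([e.dp_amplitude for e in gt])
        sem = np.std([e.dp_amplitude for e in gt]) / np.sqrt(len(gt))
        assert len(events) == len(gt)
        assert abs(st_["amplitude_mean"] - gt_amp) < 2 * sem + 0.2


class TestDriveCurrent:
    def test_flat_trace_errors(self):
        with pytest.raises(ValueError):
            measure_drive_current(flat_trace(v=0.0), n_cycles=15)

    def test_identical_deflections_recovered_exactly(self):
        tr, amps = generate_drive_current(15, 55.0, 0.0, seed=1)
        got = measure_drive_current(tr, n_cycles=15)
        assert got == pytest.approx(55.0, rel=0.01)

    def test_sampled_amplitudes_recovered_within_two_sem(self):
        tr, amps = generate_drive_current(15, 55.0, 0.9, seed=7)
        got = measure_drive_current(tr, n_cycles=15)
        sem = 0.9 / np.sqrt(15)
        assert abs(got - amps.mean()) < 2 * sem

    def test_too_few_cycles_reports_count(self):
        tr, _ = generate_drive_current(5, 15.0, 0.0, seed=2)
        with pytest.raises(ValueError, match="5"):
            measure_drive_current(tr, n_cycles=15)


@given(st.floats(-40.0, 40.0))
@settings(max_examples=20, deadline=None)
def test_offset_invariance_property(offset):
    tr, _ = square_trace([20.0] * 3)
    base_events = segment_bursts(dp_envelope(tr))
    moved = Trace(t=tr.t, V=tr.V + offset)
    events = segment_bursts(dp_envelope(moved))
    assert len(events) == len(base_events) == 3
    for a, b in zip(base_events, events):
        assert a.dp_amplitude == pytest.approx(b.dp_amplitude, abs=0.3)
        assert a.dp_duration == pytest.approx(b.dp_duration, abs=0.01)
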