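"""dF/F normalizations against brute-force oracles, QC boundary behavior,
and event-locked extraction rules (baseline shift, inclusion, amplitudes)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialcircuit import photometry as pho
from socialcircuit import synth

import oracles


def make_recording(signal, fs=100.0, control=None):
    t = np.arange(len(signal)) / fs
    return pho.PhotometryRecording(t, np.asarray(signal, float),
                                   None if control is None
                                   else np.asarray(control, float), fs_hz=fs)


class TestLowpass:
    def test_constant_unchanged(self):
        rec = make_recording(np.full(2000, 3.7), control=np.full(2000, 1.1))
        out = pho.lowpass(rec)
        assert np.allclose(out.signal, 3.7, atol=1e-9)
        assert np.allclose(out.control, 1.1, atol=1e-9)

    def test_stopband_and_passband(self):
        fs = 100.0
        t = np.arange(3000) / fs
        hi = make_recording(np.sin(2 * np.pi * 40 * t), fs)
        lo = make_recording(np.sin(2 * np.pi * 1 * t), fs)
        out_hi = pho.lowpass(hi).signal[500:-500]
        out_lo = pho.lowpass(lo).signal[500:-500]
        assert np.abs(out_hi).max() < 0.1  # > 10x attenuation at 40 Hz
        assert np.abs(out_lo).max() == pytest.approx(1.0, rel=0.05)

    def test_nyquist_violation_raises(self):
        rec = make_recording(np.zeros(100), fs=25.0)
        with pytest.raises(ValueError):
            pho.lowpass(rec, corner_hz=15.0)


class TestIsosbestic:
    def test_identity_control(self):
        rng = np.random.default_rng(0)
        c = 10 + rng.random(500)
        out = pho.isosbestic_normalize(make_recording(c, control=c))
        assert np.allclose(out.dff, 0.0, atol=1e-12)

    def test_affine_relation_absorbed(self):
        rng = np.random.default_rng(1)
        c = 10 + rng.random(500)
        s = 2.0 * c + 5.0
        out = pho.isosbestic_normalize(make_recording(s, control=c))
        assert np.allclose(out.dff, 0.0, atol=1e-10)

    def test_constant_control_raises(self):
        with pytest.raises(ValueError):
            pho.isosbestic_normalize(
                make_recording(np.arange(100.0) + 10, control=np.full(100, 2.0)))

    def test_missing_control_raises(self):
        with pytest.raises(ValueError):
            pho.isosbestic_normalize(make_recording(np.arange(100.0) + 1))

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(0.1, 10.0), shift=st.floats(0.0, 5.0))
    def test_affine_invariance_of_control_channel(self, scale, shift):
        """Rescaling the control channel leaves dF/F unchanged (the affine
        fit absorbs it)."""
        rng = np.random.default_rng(7)
        c = 10 + rng.random(400)
        s = 12 + 0.5 * rng.random(400)
        d1 = pho.isosbestic_normalize(make_recording(s, control=c)).dff
        d2 = pho.isosbestic_normalize(
            make_recording(s, control=scale * c + shift)).dff
        assert np.allclose(d1, d2, atol=1e-8)

    def test_artifact_rejection_with_transient(self):
        params = synth.PhotoSimParams(bleach_tau_s=np.inf, artifact_amp=0.02,
                                      noise_sd=0.0, seed=3)
        rec, truth = synth.simulate_photometry([30.0], params, 120.0,
                                               event_amps=[0.05])
        out = pho.isosbestic_normalize(rec)
        assert out.dff.max() == pytest.approx(0.05, rel=0.10)
        r = np.corrcoef(out.dff, truth["artifact"])[0, 1]
        assert abs(r) < 0.1


class TestSlidingMedian:
    def test_constant_signal(self):
        out = pho.sliding_median_normalize(make_recording(np.full(3000, 4.2)))
        assert np.allclose(out.dff, 0.0, atol=1e-15)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        for n, fs in ((500, 10.0), (1500, 100.0), (2000, 100.0)):
            sig = 10 + rng.random(n)
            rec = make_recording(sig, fs=fs)
            out = pho.sliding_median_normalize(rec)
            med = oracles.brute_sliding_median(sig, fs)
            assert np.max(np.abs(out.dff - (sig - med) / med)) < 1e-12

    def test_isolated_transient_peak(self):
        # 0.5 s square transient on constant baseline: median robust
        fs, b, a = 100.0, 10.0, 2.0
        sig = np.full(6000, b)
        sig[3000:3050] += a
        out = pho.sliding_median_normalize(make_recording(sig, fs))
        assert out.dff.max() == pytest.approx(a / b, rel=0.02)

    def test_nonpositive_median_raises(self):
        sig = np.concatenate([np.full(1500, -1.0), np.full(1500, 2.0)])
        with pytest.raises(ValueError, match="non-positive"):
            pho.sliding_median_normalize(make_recording(sig))

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            pho.sliding_median_normalize(make_recording(np.ones(100)))


class TestQcSpread:
    @pytest.mark.parametrize("spread,expected", [
        (0.008, False), (0.015, True), (0.0100, True)])
    def test_threshold_boundaries(self, spread, expected):
        # uniform ramp: P95 - P5 is 90% of the full range
        full = spread / 0.9
        dff = np.linspace(-full / 2, full / 2, 10001)
        trace = pho.NormalizedTrace(np.arange(dff.size) / 100.0, dff,
                                    "sliding_median", 100.0)
        got_spread, ok = pho.qc_spread(trace)
        assert got_spread == pytest.approx(spread, rel=1e-6)
        assert ok is expected

    def test_constant_trace_excluded(self):
        trace = pho.NormalizedTrace(np.arange(100) / 100.0, np.zeros(100),
                                    "sliding_median", 100.0)
        spread, ok = pho.qc_spread(trace)
        assert spread == 0.0 and not ok

    def test_percentiles_match_bruteforce(self):
        rng = np.random.default_rng(9)
        dff = rng.normal(0, 0.01, 1500)
        trace = pho.NormalizedTrace(np.arange(1500) / 100.0, dff,
                                    "sliding_median", 100.0)
        spread, _ = pho.qc_spread(trace)
        brute = (oracles.brute_percentile(dff, 95)
                 - oracles.brute_percentile(dff, 5))
        assert spread == pytest.approx(brute, abs=1e-12)


def flat_trace(n=20000, fs=100.0, value=0.0):
    return pho.NormalizedTrace(np.arange(n) / fs, np.full(n, value),
                               "sliding_median", fs)


class TestEventLocked:
    def test_short_bout_excluded_tube_mode(self):
        els = pho.extract_event_locked(
            flat_trace(), pd.DataFrame({"onset_s": [10.0],
                                        "bout_duration_s": [12.0]}),
            pho.WindowSpec.tube())
        assert not els.events.included.iloc[0]
        assert els.events.reason.iloc[0] == "short_bout"

    def test_bout_exactly_15s_excluded(self):
        # inclusion demands strictly longer than 15 s
        els = pho.extract_event_locked(
            flat_trace(), pd.DataFrame({"onset_s": [10.0, 20.0],
                                        "bout_duration_s": [15.0, 15.1]}),
            pho.WindowSpec.tube())
        assert list(els.events.reason) == ["short_bout", ""]

    def test_refractory_excluded_ofsi_mode(self):
        els = pho.extract_event_locked(
            flat_trace(), pd.DataFrame({"onset_s": [10.0, 12.0]}),
            pho.WindowSpec.ofsi())
        assert list(els.events.included) == [True, False]
        assert els.events.reason.iloc[1] == "refractory"

    def test_refractory_boundary_3s(self):
        els = pho.extract_event_locked(
            flat_trace(), pd.DataFrame({"onset_s": [10.0, 13.0, 17.0]}),
            pho.WindowSpec.ofsi())
        # 3.0 s gap is not "< 3 s": included
        assert list(els.events.included) == [True, True, True]

    def test_window_out_of_range(self):
        els = pho.extract_event_locked(
            flat_trace(n=3000), pd.DataFrame({"onset_s": [0.5, 29.5, 15.0]}),
            pho.WindowSpec.ofsi())
        df = els.events.set_index("onset_s")
        assert df.loc[0.5, "reason"] == "window_out_of_range"
        assert df.loc[29.5, "reason"] == "window_out_of_range"
        assert df.loc[15.0, "included"]

    def test_constant_trace_shifts_to_zero(self):
        els = pho.extract_event_locked(
            flat_trace(value=0.37), pd.DataFrame({"onset_s": [50.0]}),
            pho.WindowSpec.ofsi())
        assert np.allclose(els.traces, 0.0, atol=1e-12)
        assert els.amplitudes[0] == pytest.approx(0.0, abs=1e-12)

    def test_baseline_idempotence(self):
        rng = np.random.default_rng(12)
        trace = pho.NormalizedTrace(np.arange(20000) / 100.0,
                                    rng.normal(0, 0.01, 20000),
                                    "sliding_median", 100.0)
        ev = pd.DataFrame({"onset_s": [50.0, 120.0]})
        els = pho.extract_event_locked(trace, ev, pho.WindowSpec.ofsi())
        rel = els.rel_time_s
        base = (rel >= -1.5 - 0.005) & (rel < -1.0 - 0.005)
        assert np.all(np.abs(els.traces[:, base].mean(axis=1)) < 1e-9)

    def test_amplitude_matches_kernel_expectation(self):
        params = synth.PhotoSimParams(bleach_tau_s=np.inf, artifact_amp=0.0,
                                      noise_sd=0.0, seed=1)
        rec, _ = synth.simulate_photometry([60.0], params, 150.0,
                                           event_amps=[0.05])
        trace = pho.NormalizedTrace(rec.time_s, (rec.signal - 100.0) / 100.0,
                                    "sliding_median", rec.fs_hz)
        els = pho.extract_event_locked(
            trace, pd.DataFrame({"onset_s": [60.0]}), pho.WindowSpec.ofsi())
        expected = 0.05 * synth.kernel_amplitude_fraction()
        assert els.amplitudes[0] == pytest.approx(expected, rel=0.05)

    def test_no_included_events_warns(self):
        with pytest.warns(UserWarning):
            els = pho.extract_event_locked(
                flat_trace(), pd.DataFrame({"onset_s": [10.0],
                                            "bout_duration_s": [5.0]}),
                pho.WindowSpec.tube())
        assert els.traces.shape[0] == 0


class TestPrePost:
    def test_flat_trace_zero_change(self):
        els = pho.extract_event_locked(
            flat_trace(value=0.2), pd.DataFrame({"onset_s": [30.0, 60.0]}),
            pho.WindowSpec.ofsi())
        pp = pho.pre_post_change(els)
        assert np.allclose(pp.change, 0.0, atol=1e-12)

    def test_step_at_onset(self):
        fs, h = 100.0, 0.04
        dff = np.zeros(20000)
        dff[5000:] = h  # step at t = 50 s
        trace = pho.NormalizedTrace(np.arange(20000) / fs, dff,
                                    "sliding_median", fs)
        els = pho.extract_event_locked(
            trace, pd.DataFrame({"onset_s": [50.0]}), pho.WindowSpec.ofsi())
        pp = pho.pre_post_change(els)
        assert pp.change.iloc[0] == pytest.approx(h, rel=1e-6)

    def test_transients_detected_by_paired_test(self):
        from socialcircuit import stats as sct
        params = synth.PhotoSimParams(bleach_tau_s=np.inf, artifact_amp=0.0,
                                      noise_sd=0.005, seed=6)
        onsets = np.arange(12) * 12.0 + 10.0
        rec, _ = synth.simulate_photometry(onsets, params, 160.0,
                                           event_amps=[0.05] * 12)
        trace = pho.sliding_median_normalize(rec)
        els = pho.extract_event_locked(
            trace, pd.DataFrame({"onset_s": onsets}), pho.WindowSpec.ofsi())
        pp = pho.pre_post_change(els)
        r = sct.paired_t(pp.pre_mean, pp.post_mean)
        assert r.p < 0.05 and r.t > 0
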