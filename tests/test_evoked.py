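"""Epoching, trial rejection, averaging, global field power and component
peak logic against closed-form and brute-force oracles."""

import numpy as np
import pytest

from capcompare.evoked import (
    EmptyResultError,
    EvokedWaveform,
    GfpSeries,
    PeakOrderError,
    SuspiciousShiftError,
    align_latency,
    average,
    blink_overlays,
    epoch,
    find_peaks,
    gfp_t,
    reject_trials,
)
from capcompare.preprocess import InsufficientDataError

FS = 500.0


def _epochs(data, triggers, **kw):
    return epoch(data, FS, triggers, **kw)


class TestEpoch:
    def test_shape_150_trials_250_samples(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((4, int(220 * FS)))
        triggers = [1.0 + 1.3 * k for k in range(150)]
        es = _epochs(data, triggers)
        assert es.epochs.shape == (150, 4, 250)
        assert es.times[0] == pytest.approx(-100.0)
        assert es.times[-1] == pytest.approx(398.0)

    def test_constant_channel_zero_after_baseline(self):
        data = np.full((2, int(10 * FS)), 5.0)
        es = _epochs(data, [2.0, 4.0])
        assert np.abs(es.epochs).max() < 1e-12

    def test_out_of_bounds_trigger_dropped(self):
        data = np.zeros((1, int(10 * FS)))
        es = _epochs(data, [0.05, 5.0])
        assert es.epochs.shape[0] == 1
        assert es.n_dropped_bounds == 1

    def test_no_usable_trigger_rejected(self):
        with pytest.raises(InsufficientDataError):
            _epochs(np.zeros((1, 100)), [0.01])


class TestRejectTrials:
    def _with_blink(self):
        rng = np.random.default_rng(1)
        data = 5 * rng.standard_normal((3, int(30 * FS)))
        data[1, int(9.9 * FS) : int(10.1 * FS)] += 600.0
        return _epochs(data, [2.0, 10.0, 20.0])

    def test_large_amplitude_trial_rejected(self):
        es = reject_trials(self._with_blink(), 150.0)
        assert es.rejected == (1,)

    def test_infinite_threshold_keeps_all(self):
        es = reject_trials(self._with_blink(), np.inf)
        assert es.rejected == ()

    def test_all_rejected_raises(self):
        es = self._with_blink()
        with pytest.raises(EmptyResultError):
            reject_trials(es, 1e-12)


class TestAverage:
    def test_identical_trials(self):
        # 5 Hz tone: 2-s trigger spacing is a whole number of periods, so
        # both epochs carry identical samples
        t = np.arange(0, 10, 1 / FS)
        es = _epochs(np.tile(np.sin(2 * np.pi * 5 * t), (2, 1)), [2.0, 4.0])
        ev = average(es)
        assert np.allclose(ev.mean, es.epochs[0], atol=1e-12)
        assert ev.n_trials_used == 2

    def test_opposite_trials_cancel(self):
        t = np.zeros((1, int(10 * FS)))
        t[0, int(2.05 * FS)] = 1.0
        t[0, int(4.05 * FS)] = -1.0
        ev = average(_epochs(t, [2.0, 4.0], baseline=False))
        assert np.abs(ev.mean).max() < 1e-12

    def test_noise_shrinks_like_sqrt_n(self):
        # n trials of pure noise: residual SD ~ sigma/sqrt(n) (within 20%)
        rng = np.random.default_rng(2)
        sigma, n = 4.0, 150
        data = sigma * rng.standard_normal((1, int((n + 4) * FS)))
        ev = average(_epochs(data, [2.0 + k for k in range(n)], baseline=False))
        assert ev.mean.std() == pytest.approx(sigma / np.sqrt(n), rel=0.2)


class TestGfp:
    def test_equal_channels_zero(self):
        ev = EvokedWaveform(np.ones((5, 20)), np.arange(20.0), 1)
        assert np.all(gfp_t(ev).gfp == 0)

    def test_two_channel_closed_form(self):
        ev = EvokedWaveform(np.array([[1.0], [-1.0]]), np.array([0.0]), 1)
        assert gfp_t(ev).gfp[0] == pytest.approx(1.0)

    def test_brute_force_population_sd(self):
        rng = np.random.default_rng(3)
        m = rng.standard_normal((64, 200))
        ev = EvokedWaveform(m, np.arange(200.0), 1)
        brute = np.array([np.sqrt(np.mean((m[:, j] - m[:, j].mean()) ** 2))
                          for j in range(200)])
        assert np.abs(gfp_t(ev).gfp - brute).max() < 1e-12

    def test_invariant_to_channel_common_offset(self):
        rng = np.random.default_rng(4)
        m = rng.standard_normal((8, 50))
        offs = rng.standard_normal(50)  # one offset per sample, all channels
        a = gfp_t(EvokedWaveform(m, np.arange(50.0), 1)).gfp
        b = gfp_t(EvokedWaveform(m + offs[None, :], np.arange(50.0), 1)).gfp
        assert np.allclose(a, b, atol=1e-12)

    @pytest.mark.parametrize("alpha", [-2.5, 0.0, 3.0])
    def test_scales_linearly(self, alpha):
        rng = np.random.default_rng(5)
        m = rng.standard_normal((8, 30))
        base = gfp_t(EvokedWaveform(m, np.arange(30.0), 1)).gfp
        scaled = gfp_t(EvokedWaveform(alpha * m, np.arange(30.0), 1)).gfp
        assert np.allclose(scaled, abs(alpha) * base, atol=1e-12)


class TestFindPeaks:
    def _gfp(self, values):
        times = np.arange(-100, 400, 2.0)
        return GfpSeries(gfp=values, times=times)

    def test_simulated_latencies_recovered(self, study):
        _, pairs, _ = study
        for gel, dry in pairs:
            for a in (gel, dry):
                assert abs(a.vep_peaks["N75"].latency - 72.0) <= 4.0
                assert abs(a.vep_peaks["P100"].latency - 120.0) <= 4.0

    def test_single_shared_peak_unresolved(self):
        times = np.arange(-100, 400, 2.0)
        g = np.zeros_like(times)
        g[times == 96.0] = 5.0  # inside both search windows
        with pytest.raises(PeakOrderError) as err:
            find_peaks(GfpSeries(g, times))
        assert set(err.value.candidates) == {"N75", "P100"}

    def test_flat_gfp_earliest_sample_low_confidence(self):
        times = np.arange(-100, 400, 2.0)
        peaks = find_peaks(GfpSeries(np.zeros_like(times) + 1.0, times))
        by_name = {p.name.value: p for p in peaks}
        assert by_name["N75"].latency == 50.0
        assert by_name["N75"].low_confidence
        assert by_name["P100"].latency == 90.0

    def test_window_outside_axis_rejected(self):
        times = np.arange(0, 100, 2.0)
        with pytest.raises(ValueError):
            find_peaks(GfpSeries(np.zeros_like(times), times),
                       {"N75": (50.0, 100.0), "P100": (90.0, 170.0)})


class TestAlignLatency:
    def _evoked(self):
        times = np.arange(-100, 400, 2.0)
        m = np.zeros((3, times.size))
        m[:, int(np.nonzero(times == 80.0)[0][0])] = [3.0, -1.0, 2.0]
        return EvokedWaveform(m, times, 10)

    def test_shift_arithmetic(self):
        ev = align_latency(self._evoked(), own_n75=80.0, reference_n75=72.0)
        assert ev.shift_ms == pytest.approx(-8.0)

    def test_null_shift_identity(self):
        base = self._evoked()
        ev = align_latency(base, 72.0, 72.0)
        assert np.array_equal(ev.mean, base.mean)
        assert ev.shift_ms == 0.0

    def test_shift_moves_peak_to_reference(self):
        ev = align_latency(self._evoked(), 80.0, 72.0)
        peak_t = ev.times[np.argmax(ev.mean[0])]
        assert peak_t == pytest.approx(72.0, abs=2.0)

    def test_excessive_shift_rejected(self):
        with pytest.raises(SuspiciousShiftError):
            align_latency(self._evoked(), 80.0, 200.0)

    def test_realign_converges_on_simulated_vep(self, study):
        _, pairs, _ = study
        a = pairs[0][0]
        ev = align_latency(a.vep_evoked, a.vep_peaks["N75"].latency, 80.0)
        peaks = find_peaks(gfp_t(ev))
        n75 = [p for p in peaks if p.name.value == "N75"][0]
        assert abs(n75.latency - 80.0) <= 2.0


class TestBlinkOverlays:
    @pytest.fixture(scope="class")
    def clean_session(self, ten_twenty):
        from capcompare.synthdata import CapType, short_config, simulate_session

        cfg = short_config(n_subjects=1, seed=77,
                           bad_channel_prob={"gel": 0.0, "dry": 0.0})
        rec, _ = simulate_session(cfg, "S77", CapType.GEL, ten_twenty)
        return rec

    def test_overlay_recovers_template_amplitude(self, clean_session):
        from capcompare.synthdata import SegmentKind, blink_weights

        rec = clean_session
        seg = rec.segment(SegmentKind.BLINK)
        rel = [t - seg.start for t in seg.trigger_times]
        overlays = blink_overlays(rec.segment_data(SegmentKind.BLINK), FS, rel)
        fp1 = rec.layout.index_of("Fp1")
        measured = np.abs(overlays["2s"].mean[fp1]).max()
        w = blink_weights(rec.layout)[fp1]
        assert measured == pytest.approx(200.0 * w, rel=0.10)

    def test_ten_second_overlay_present_with_enough_triggers(self, clean_session):
        from capcompare.synthdata import SegmentKind

        rec = clean_session
        seg = rec.segment(SegmentKind.BLINK)
        rel = [t - seg.start for t in seg.trigger_times]
        overlays = blink_overlays(rec.segment_data(SegmentKind.BLINK), FS, rel)
        assert "2s" in overlays
        # 12-s desk-scale blink segment has 6 triggers -> one 5-blink trial
        assert "10s" in overlays
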