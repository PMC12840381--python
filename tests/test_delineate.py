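"""Delineation: R detection against generator truth, averaging, fiducials."""

import dataclasses

import numpy as np
import pytest

from lvscreen.delineate import (average_beat, delineate_record,
                                detect_r_peaks, locate_waves)
from lvscreen.errors import InsufficientBeats, NoBeatsDetected
from lvscreen.synth import (BeatTemplateParams, CohortConfig, ECGRecord,
                            SubjectProfile, synthesize_record)


def make_record(lvef=62.0, hr=60.0, sdnn=0.0, noise=0.0, seed=1,
                duration=60.0):
    cfg = CohortConfig(hr_mean_bpm=hr, sdnn_target_ms=sdnn,
                       noise_rms_uv=noise, duration_s=duration, seed=seed)
    prof = SubjectProfile("T0", "male", 60.0, False, False, False, lvef)
    return synthesize_record(prof, cfg, seed=seed)


class TestDetectRPeaks:
    def test_beat_count_at_60_bpm(self):
        rec = make_record(hr=60.0)
        r_idx, rr = detect_r_peaks(rec)
        assert 59 <= len(r_idx) <= 61
        assert len(rr) == len(r_idx) - 1

    def test_flat_signal_raises(self):
        rec = ECGRecord("Z", 1000.0, np.zeros(60000))
        with pytest.raises(NoBeatsDetected):
            detect_r_peaks(rec)

    def test_short_record_raises(self):
        rec = ECGRecord("Z", 1000.0, np.random.default_rng(0).normal(size=5000))
        with pytest.raises(InsufficientBeats):
            detect_r_peaks(rec)

    @pytest.mark.parametrize("hr", [50.0, 70.0, 100.0])
    def test_r_position_error_below_10ms(self, hr):
        """Detected R positions match generator truth within 10 ms."""
        rec = make_record(hr=hr, sdnn=30.0, noise=10.0, seed=int(hr))
        r_idx, _ = detect_r_peaks(rec)
        true_ms = np.asarray(rec.ground_truth["r_times_ms"])
        det_ms = r_idx * 1000.0 / rec.sampling_rate_hz
        # match each true beat to the nearest detection
        err = [np.min(np.abs(det_ms - t)) for t in true_ms]
        assert len(det_ms) == len(true_ms)
        assert max(err) <= 10.0

    def test_refractory_constraint(self):
        rec = make_record(hr=100.0, sdnn=40.0, noise=15.0, seed=8)
        _, rr = detect_r_peaks(rec)
        assert np.all(rr >= 250.0)


class TestAverageBeat:
    def test_identical_beats_reproduce_template(self):
        rec = make_record(noise=0.0)
        r_idx, _ = detect_r_peaks(rec)
        avg, window = average_beat(rec, r_idx)
        pre = int(window[0] * rec.sampling_rate_hz / 1000.0)
        seg = rec.samples_uv[r_idx[5] - pre:
                             r_idx[5] + int(window[1] * rec.sampling_rate_hz
                                            / 1000.0)]
        np.testing.assert_allclose(avg, seg, atol=1e-6)

    def test_averaging_reduces_noise(self):
        clean = make_record(noise=0.0, seed=3)
        noisy = make_record(noise=20.0, seed=3)
        r_idx, _ = detect_r_peaks(noisy)
        avg, window = average_beat(noisy, r_idx)
        fs = noisy.sampling_rate_hz
        pre = int(window[0] * fs / 1000.0)
        post = int(window[1] * fs / 1000.0)
        r = r_idx[10]
        truth = clean.samples_uv[r - pre:r + post]
        single = noisy.samples_uv[r - pre:r + post]
        rmse = lambda a, b: np.sqrt(np.mean((a - b) ** 2))  # noqa: E731
        assert rmse(avg, truth) < rmse(single, truth)

    def test_five_beats_insufficient(self):
        rec = make_record()
        r_idx, _ = detect_r_peaks(rec)
        with pytest.raises(InsufficientBeats):
            average_beat(rec, r_idx[:5])


class TestLocateWaves:
    def test_symmetric_t_has_balanced_fronts(self):
        """A symmetric Gaussian T puts Tons and Toffs equidistant from Tpeak."""
        fs = 1000.0
        t_ms = np.arange(-300, 500, 1000.0 / fs)
        beat = BeatTemplateParams(
            t=dataclasses.replace(BeatTemplateParams().t, asymmetry=1.0))
        avg = beat.evaluate(t_ms)
        fid = locate_waves(avg, fs, (300.0, 500.0))
        lead = fid.t_peak - fid.t_ons
        trail = fid.t_offs - fid.t_peak
        assert abs(lead - trail) <= 4.0

    def test_t_peak_matches_generator_center(self):
        rec = make_record(noise=0.0, seed=5)
        avg, fid = delineate_record(rec)
        gt = rec.ground_truth
        true_tpeak_rel_qrson = gt["t_center_ms"] - gt["qrs_on_ms"]
        # detected QRS onset sits inside the true 3-sigma kernel support,
        # so compare T positions relative to the R peak instead
        measured = fid.t_peak - fid.r_peak
        assert abs(measured - gt["t_center_ms"]) <= 10.0
        assert abs((fid.t_peak - fid.qrs_on) - true_tpeak_rel_qrson) <= 15.0

    def test_ordering_invariants(self, small_study):
        _, _, records = small_study
        for rec in records[:20]:
            _, fid = delineate_record(rec)
            assert fid.qrs_on < fid.r_peak < fid.qrs_off
            if fid.t_peak is not None:
                assert fid.qrs_off < fid.t_ons < fid.t_peak < fid.t_offs
                assert fid.t_offs <= fid.t_end
            assert fid.ordering_ok()

    def test_time_shift_equivariance(self):
        """Dropping k leading samples shifts beat indices by exactly k."""
        rec = make_record(noise=5.0, seed=11)
        k = 57
        shifted = ECGRecord("T0", rec.sampling_rate_hz, rec.samples_uv[k:])
        r1, _ = detect_r_peaks(rec)
        r2, _ = detect_r_peaks(shifted)
        np.testing.assert_array_equal(r1[1:] - k, r2[1:len(r1)])
        _, f1 = delineate_record(rec)
        _, f2 = delineate_record(shifted)
        assert f1.r_peak == pytest.approx(f2.r_peak, abs=2.0)
        assert f1.t_peak == pytest.approx(f2.t_peak, abs=2.0)

    def test_amplitude_scale_invariance_of_times(self):
        rec = make_record(noise=5.0, seed=13)
        scaled = ECGRecord("T0", rec.sampling_rate_hz, 2.5 * rec.samples_uv)
        _, f1 = delineate_record(rec)
        _, f2 = delineate_record(scaled)
        for attr in ("r_peak", "s_peak", "qrs_off", "t_peak", "t_ons",
                     "t_offs"):
            assert getattr(f1, attr) == pytest.approx(getattr(f2, attr),
                                                      abs=2.0)

    def test_noiseless_cohort_fully_delineated(self, noiseless_cohort):
        """Every noiseless synthetic record delineates without error."""
        _, records, table = noiseless_cohort
        assert table.n_excluded == 0
        assert len(table.df) == len(records)
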