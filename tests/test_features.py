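"""ECG parameters: closed-form oracles, invariances, cohort extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from lvscreen.delineate import FiducialSet, delineate_record
from lvscreen.errors import InsufficientBeats, LVScreenError
from lvscreen.features import (ALL_FEATURES, amplitude_features,
                               band_energy, dwt_band_energies,
                               extract_cohort, interval_features,
                               rhythm_features, shape_features,
                               spectral_centroid, spectral_features)
from lvscreen.synth import CohortConfig, ECGRecord, SubjectProfile, \
    synthesize_record
from tests.conftest import covariate_frame

FS = 1000.0


def make_fid(**kw):
    base = dict(r_indices=np.array([], dtype=int), rr_ms=np.array([]),
                window_ms=(300.0, 500.0), baseline_uv=0.0,
                qrs_on=0.0, r_peak=44.0, s_peak=72.0, qrs_off=92.0,
                j_point=92.0, t_ons=260.0, t_peak=320.0, t_offs=360.0,
                t_end=400.0, p_ons=-180.0, p_offs=-110.0,
                p_peak_pos=-150.0, p_peak_neg=-120.0)
    base.update(kw)
    return FiducialSet(**base)


class TestAmplitudes:
    def test_true_t_amplitude_recovered(self):
        cfg = CohortConfig(noise_rms_uv=0.0, sdnn_target_ms=0.0, seed=2)
        prof = SubjectProfile("A", "female", 55.0, False, False, False, 63.0)
        rec = synthesize_record(prof, cfg, seed=2)
        avg, fid = delineate_record(rec)
        amps = amplitude_features(avg, fid, FS)
        assert amps["TA"] == pytest.approx(rec.ground_truth["t_amp_uv"],
                                           abs=5.0)

    def test_constant_offset_invariance(self):
        cfg = CohortConfig(noise_rms_uv=0.0, sdnn_target_ms=0.0, seed=3)
        prof = SubjectProfile("A", "male", 55.0, False, False, False, 60.0)
        rec = synthesize_record(prof, cfg, seed=3)
        avg, fid = delineate_record(rec)
        a1 = amplitude_features(avg, fid, FS)
        shifted = ECGRecord("A", FS, rec.samples_uv + 200.0)
        avg2, fid2 = delineate_record(shifted)
        a2 = amplitude_features(avg2, fid2, FS)
        for k in a1:
            assert a1[k] == pytest.approx(a2[k], abs=2.0), k

    def test_j80_is_80ms_after_j_point(self):
        # a ramp makes the 80-ms offset arithmetic visible in the value
        avg = np.arange(800, dtype=float)
        fid = make_fid(baseline_uv=0.0)
        amps = amplitude_features(avg, fid, FS)
        assert amps["J80A"] - amps["JA"] == pytest.approx(80.0)


class TestIntervals:
    def test_bazett_identity_at_rr_1s(self):
        out = interval_features(make_fid(), mean_rr_ms=1000.0)
        assert out["QT"] == pytest.approx(400.0)
        assert out["QTc"] == pytest.approx(400.0)

    def test_bazett_at_rr_640(self):
        out = interval_features(make_fid(), mean_rr_ms=640.0)
        assert out["QTc"] == pytest.approx(500.0)

    def test_qt_over_tq(self):
        out = interval_features(make_fid(), mean_rr_ms=1000.0)
        assert out["QT_over_TQ"] == pytest.approx(400.0 / 600.0, abs=1e-9)

    def test_qt_over_tq_undefined_when_rr_below_qt(self):
        out = interval_features(make_fid(), mean_rr_ms=390.0)
        assert np.isnan(out["QT_over_TQ"])

    def test_derived_intervals(self):
        out = interval_features(make_fid(), mean_rr_ms=1000.0)
        assert out["QRSw"] == pytest.approx(92.0)
        assert out["TpTe"] == pytest.approx(80.0)   # Tfi - Tpeak
        assert out["VAT"] == pytest.approx(44.0)    # Rpeak - QRSst


class TestRhythm:
    def test_constant_rr_zero_sdnn(self):
        assert rhythm_features(np.full(20, 800.0))["SDNN"] == 0.0

    def test_alternating_rr_closed_form(self):
        rr = np.tile([800.0, 1200.0], 10)
        assert rhythm_features(rr)["SDNN"] == pytest.approx(200.0)

    def test_homogeneity(self, rng):
        rr = rng.normal(900, 40, 50)
        s1 = rhythm_features(rr)["SDNN"]
        s2 = rhythm_features(2 * rr)["SDNN"]
        assert s2 == pytest.approx(2 * s1)

    def test_too_few_intervals(self):
        with pytest.raises(InsufficientBeats):
            rhythm_features(np.full(5, 800.0))


class TestSpectral:
    def test_centroid_of_pure_tone(self):
        t = np.arange(int(0.2 * FS)) / FS
        c = spectral_centroid(np.sin(2 * np.pi * 25.0 * t), FS)
        assert c == pytest.approx(25.0, abs=1.0)

    def test_zero_window_zero_energies(self):
        d, approx = dwt_band_energies(np.zeros(64), FS)
        assert np.all(d == 0.0) and approx == 0.0
        assert band_energy(np.zeros(64), FS, (150, 250)) == 0.0

    def test_dwt_parseval(self, rng):
        """Detail + approximation energies equal total segment energy."""
        for n in (37, 64, 211):
            x = rng.normal(size=n)
            d, approx = dwt_band_energies(x, FS)
            total = np.sum(x ** 2) / FS
            assert abs(d.sum() + approx - total) <= 1e-6 * total

    def test_energies_nonnegative_on_cohort(self, small_features):
        df = small_features.df
        energy_cols = ["QRSE1", "QRSE2", "QRS12energy", "TE1", "TE2", "TE3",
                       "TE4", "Tpenergy", "HFQRS"]
        assert (df[energy_cols].fillna(0.0) >= 0.0).all().all()
        assert (df["SDNN"] >= 0.0).all()

    def test_qrs12_is_sum_of_levels(self, small_features):
        df = small_features.df
        np.testing.assert_allclose(df["QRS12energy"],
                                   df["QRSE1"] + df["QRSE2"], rtol=1e-9)


class TestShape:
    def _triangle_beat(self, lead_slope, trail_slope):
        """Flat beat with a triangular T: known front slopes exactly."""
        avg = np.zeros(800)
        rise = np.arange(0, 51) * lead_slope
        fall = rise[-1] - np.arange(1, 101) * trail_slope
        avg[400:451] = rise
        avg[451:551] = np.maximum(fall, 0.0)
        fid = make_fid(r_peak=300.0, s_peak=330.0, qrs_off=350.0,
                       j_point=350.0, t_ons=425.0, t_peak=450.0,
                       t_offs=500.0, t_end=550.0)
        return avg, fid

    def test_piecewise_linear_slope_ratio(self):
        avg, fid = self._triangle_beat(2.0, 1.0)
        out = shape_features(avg, fid, FS, smooth_hz=None)
        assert out["SBeta"] == pytest.approx(2.0, rel=1e-6)

    def test_time_reversal_inverts_sbeta(self):
        avg, fid = self._triangle_beat(2.0, 1.0)
        fwd = shape_features(avg, fid, FS, smooth_hz=None)["SBeta"]
        rev_avg, _ = self._triangle_beat(1.0, 0.5)
        # rebuild the same triangle mirrored: leading 1.0, trailing 2.0
        avg2 = np.zeros(800)
        rise = np.arange(0, 101) * 1.0
        fall = rise[-1] - np.arange(1, 51) * 2.0
        avg2[400:501] = rise
        avg2[501:551] = np.maximum(fall, 0.0)
        fid2 = make_fid(r_peak=300.0, s_peak=330.0, qrs_off=350.0,
                        j_point=350.0, t_ons=450.0, t_peak=500.0,
                        t_offs=525.0, t_end=550.0)
        rev = shape_features(avg2, fid2, FS, smooth_hz=None)["SBeta"]
        assert rev == pytest.approx(1.0 / fwd, rel=0.05)

    def test_symmetric_t_gives_unit_sbeta(self):
        import dataclasses
        from lvscreen.delineate import locate_waves
        from lvscreen.synth import BeatTemplateParams
        beat = BeatTemplateParams(
            t=dataclasses.replace(BeatTemplateParams().t, asymmetry=1.0))
        t_ms = np.arange(-300, 500, 1.0)
        avg = beat.evaluate(t_ms)
        fid = locate_waves(avg, FS, (300.0, 500.0))
        out = shape_features(avg, fid, FS)
        assert out["SBeta"] == pytest.approx(1.0, abs=0.05)


class TestExtractCohort:
    def test_clean_records_no_exclusions(self, small_features, small_study):
        _, _, records = small_study
        assert len(small_features.df) == len(records)
        assert small_features.n_excluded == 0

    def test_flat_records_excluded_and_counted(self, small_study):
        cfg, profiles, records = small_study
        flat = [ECGRecord("F0", 1000.0, np.zeros(20000)),
                ECGRecord("F1", 1000.0, np.zeros(20000))]
        extra = covariate_frame(profiles[:2]).assign(subject_id=["F0", "F1"])
        cov = pd.concat([covariate_frame(profiles), extra])
        table = extract_cohort(records + flat, cov)
        assert len(table.df) == len(records)
        assert table.n_excluded == 2

    def test_duplicate_ids_rejected(self, small_study):
        _, profiles, records = small_study
        with pytest.raises(LVScreenError):
            extract_cohort([records[0], records[0]],
                           covariate_frame(profiles))

    def test_schema_covers_named_screening_features(self, small_features):
        below_normal_list = ["QRSw", "TE1", "Beta", "RA", "PpeakN", "TpTe",
                             "Tons", "RonsF", "TE3", "QRS12energy", "QTc",
                             "male_gender", "QRSst", "TA", "QRSE2", "QRSE1",
                             "Rpeak", "J80A", "Tpeak", "Speak", "TE2",
                             "RoffsF"]
        below_40_list = ["Pst", "TE3", "SDNN", "PpeakP", "SA", "QRS12energy",
                         "RonsF", "Pfi", "TE4", "Tpenergy", "J80A", "QRSst",
                         "QRSw", "TA", "HFQRS", "male_gender", "Toffs",
                         "TpTe"]
        covariate_list = ["male_gender", "age", "smoking", "diabetes",
                          "hypertension", "TpTe", "VAT", "QTc", "QT_over_TQ",
                          "HFQRS", "JA", "J80A", "TA"]
        cols = set(small_features.df.columns)
        for name in set(below_normal_list + below_40_list + covariate_list):
            assert name in cols, name
        assert set(ALL_FEATURES) <= cols

    def test_parameter_recovery_on_noiseless_cohort(self, noiseless_cohort):
        """TA, QRSw and Tpeak track generator ground truth at r >= 0.99."""
        _, records, table = noiseless_cohort
        df = table.df.set_index("subject_id")
        gt = {r.subject_id: r.ground_truth for r in records}
        ids = df.index
        ta_true = np.array([gt[i]["t_amp_uv"] for i in ids])
        qrsw_true = np.array([gt[i]["qrs_off_ms"] - gt[i]["qrs_on_ms"]
                              for i in ids])
        tp_true = np.array([gt[i]["t_center_ms"] for i in ids])
        # T-peak position against the true T-kernel centre, both taken
        # relative to the R peak (a landmark both sides define identically)
        tp_meas = df["Tpeak"] - df["Rpeak"]
        assert np.corrcoef(df["TA"], ta_true)[0, 1] >= 0.99
        assert np.corrcoef(df["QRSw"], qrsw_true)[0, 1] >= 0.99
        assert np.corrcoef(tp_meas, tp_true)[0, 1] >= 0.99

    def test_ta_thresholding_screens_low_ef(self, noiseless_cohort):
        """Lower TA discriminates EF<40 with AUC >= 0.8 (monotone link)."""
        _, _, table = noiseless_cohort
        df = table.df
        label = (df["LVEF"] < 40.0).astype(int)
        assert label.sum() >= 5
        assert roc_auc_score(label, -df["TA"]) >= 0.8
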