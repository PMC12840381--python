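"""Digital ECG parameters measured on the delineated averaged beat.

All amplitudes are in uV relative to the isoelectric baseline, positions in
ms relative to QRS onset (the time origin of a delineated beat), intervals
in ms, and band energies in uV^2*s. The parameter set reconstructs the
named screening features:

amplitudes   RA, SA, TA, PpeakP, PpeakN, JA, J80A
positions    Rpeak, Speak, Tpeak, Tons, Toffs, Tfi, Pst, Pfi, QRSst, QRSfi
intervals    QRSw, QT, QTc (Bazett), TpTe, VAT, QT_over_TQ
shape        Beta (R-wave front-slope ratio), SBeta (T-wave front-slope ratio)
spectral     RonsF, RoffsF (spectral centroids at QRS onset/offset),
             QRSE1/QRSE2 + QRS12energy and TE1..TE4 + Tpenergy (Daubechies-4
             discrete-wavelet detail-band energies of the QRS and T windows),
             HFQRS (150-250 Hz energy inside QRS)
rhythm       SDNN (population SD of RR over the whole record)

The exact formulas of the commercial system are proprietary; each parameter
here is a documented approximation consistent with its name and published
description, and the extraction version is recorded in the table metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal as sps

from .delineate import FiducialSet, delineate_record
from .errors import InsufficientBeats, LVScreenError, NoBeatsDetected
from .synth import ECGRecord

EXTRACTION_VERSION = "lvscreen-features-1"

#: ECG parameter columns in canonical order.
ECG_FEATURES = [
    "RA", "SA", "TA", "PpeakP", "PpeakN", "JA", "J80A",
    "Rpeak", "Speak", "Tpeak", "Tons", "Toffs", "Tfi",
    "Pst", "Pfi", "QRSst", "QRSfi",
    "QRSw", "QT", "QTc", "TpTe", "VAT", "QT_over_TQ",
    "Beta", "SBeta",
    "RonsF", "RoffsF",
    "QRSE1", "QRSE2", "QRS12energy",
    "TE1", "TE2", "TE3", "TE4", "Tpenergy", "HFQRS",
    "SDNN",
]
CLINICAL_FEATURES = ["male_gender", "age", "smoking", "diabetes", "hypertension"]
ALL_FEATURES = ECG_FEATURES + CLINICAL_FEATURES


@dataclass
class FeatureTable:
    """Cohort feature matrix: one row per subject, plus provenance."""

    df: pd.DataFrame
    metadata: dict

    @property
    def n_excluded(self) -> int:
        return self.metadata.get("n_excluded", 0)


def _idx(fid: FiducialSet, ms: float, fs: float) -> int:
    """Averaged-beat sample index of a time given in ms relative to QRSon."""
    dt_ms = 1000.0 / fs
    pre = int(round(fid.window_ms[0] / dt_ms))  # R-peak index
    return int(round(pre + (ms - fid.r_peak) / dt_ms))


def amplitude_features(avg: np.ndarray, fid: FiducialSet, fs: float) -> dict:
    """Wave amplitudes relative to the PQ baseline.

    J80A is the amplitude 80 ms after the J point; PpeakP/PpeakN are the
    maximum positive/negative P deflections. Missing landmarks yield NaN.
    """
    b = fid.baseline_uv
    n = len(avg)

    def amp_at(ms: float | None) -> float:
        if ms is None:
            return np.nan
        i = _idx(fid, ms, fs)
        if not 0 <= i < n:
            return np.nan
        return float(avg[i] - b)

    out = {
        "RA": amp_at(fid.r_peak),
        "SA": amp_at(fid.s_peak),
        "TA": amp_at(fid.t_peak),
        "PpeakP": amp_at(fid.p_peak_pos),
        "PpeakN": amp_at(fid.p_peak_neg),
        "JA": amp_at(fid.j_point),
    }
    j_i = _idx(fid, fid.j_point, fs) + int(round(0.080 * fs))
    out["J80A"] = float(avg[j_i] - b) if 0 <= j_i < n else np.nan
    return out


def interval_features(fid: FiducialSet, mean_rr_ms: float) -> dict:
    """Positions and intervals derived from the fiducials.

    QTc uses Bazett's correction (QT / sqrt(RR in s)); QT/TQ relates the
    electrically active interval to the resting interval and is undefined
    when RR <= QT.
    """
    if mean_rr_ms <= 0:
        raise LVScreenError("mean RR must be positive")
    f = fid
    nan = np.nan
    qt = (f.t_end - f.qrs_on) if f.t_end is not None else nan
    out = {
        "Rpeak": f.r_peak, "Speak": f.s_peak,
        "Tpeak": f.t_peak if f.t_peak is not None else nan,
        "Tons": f.t_ons if f.t_ons is not None else nan,
        "Toffs": f.t_offs if f.t_offs is not None else nan,
        "Tfi": f.t_end if f.t_end is not None else nan,
        "Pst": f.p_ons if f.p_ons is not None else nan,
        "Pfi": f.p_offs if f.p_offs is not None else nan,
        "QRSst": f.qrs_on,
        "QRSfi": f.qrs_off,
        "QRSw": f.qrs_off - f.qrs_on,
        "QT": qt,
        "QTc": qt / np.sqrt(mean_rr_ms / 1000.0),
        "TpTe": (f.t_end - f.t_peak)
                if None not in (f.t_end, f.t_peak) else nan,
        "VAT": f.r_peak - f.qrs_on,
    }
    out["QT_over_TQ"] = (qt / (mean_rr_ms - qt)
                         if np.isfinite(qt) and mean_rr_ms > qt else nan)
    return out


def rhythm_features(rr_ms: np.ndarray) -> dict:
    """SDNN: population standard deviation of the RR series (ms)."""
    rr = np.asarray(rr_ms, dtype=float)
    if len(rr) < 8:
        raise InsufficientBeats(f"need >= 8 RR intervals, got {len(rr)}")
    return {"SDNN": float(np.std(rr))}


def spectral_centroid(segment: np.ndarray, fs: float, n_fft: int = 4096) -> float:
    """Power-weighted mean frequency (Hz) of a Hann-windowed segment."""
    seg = np.asarray(segment, dtype=float)
    seg = (seg - np.mean(seg)) * np.hanning(len(seg))
    spec = np.abs(np.fft.rfft(seg, n=n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    total = float(np.sum(spec))
    if total <= 0:
        return np.nan
    return float(np.sum(freqs * spec) / total)


def dwt_band_energies(segment: np.ndarray, fs: float, levels: int = 4,
                      wavelet: str = "db4") -> tuple[np.ndarray, float]:
    """Detail-band energies (uV^2*s) of an orthogonal DWT of the segment.

    The segment is zero-padded to a power-of-two length and decomposed with
    periodized Daubechies-4, which keeps the transform orthonormal so the
    coefficient energies sum exactly to the signal energy (Parseval).
    Returns (energy per detail level 1..levels, approximation energy).
    """
    seg = np.asarray(segment, dtype=float)
    n = max(2 ** levels, 2 ** int(np.ceil(np.log2(max(len(seg), 2)))))
    padded = np.zeros(n)
    padded[:len(seg)] = seg
    with warnings.catch_warnings():
        # short windows exceed pywt's advisory max level; periodization
        # keeps the transform orthogonal regardless
        warnings.simplefilter("ignore", UserWarning)
        coeffs = pywt.wavedec(padded, wavelet, mode="periodization",
                              level=levels)
    dt = 1.0 / fs
    details = np.array([float(np.sum(c ** 2)) * dt
                        for c in coeffs[:0:-1]])  # level 1 first
    approx = float(np.sum(coeffs[0] ** 2)) * dt
    return details, approx


def band_energy(segment: np.ndarray, fs: float,
                band: tuple[float, float]) -> float:
    """Energy (uV^2*s) of the segment within a frequency band, by FFT."""
    seg = np.asarray(segment, dtype=float)
    if len(seg) < 2:
        return np.nan
    spec = np.abs(np.fft.rfft(seg)) ** 2
    freqs = np.fft.rfftfreq(len(seg), d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    # one-sided spectrum: double interior bins (Parseval normalisation)
    weights = np.ones_like(spec)
    weights[1:] = 2.0
    if len(seg) % 2 == 0:
        weights[-1] = 1.0
    return float(np.sum(weights[sel] * spec[sel]) / (len(seg) * fs))


def spectral_features(avg: np.ndarray, fid: FiducialSet, fs: float) -> dict:
    """Spectral centroids and band energies of the QRS and T windows."""
    if fs < 500.0:
        raise LVScreenError("sampling rate must be >= 500 Hz")
    b = fid.baseline_uv
    x = np.asarray(avg, dtype=float) - b
    n = len(x)
    half40 = int(round(0.020 * fs))

    def centroid_at(ms: float) -> float:
        i = _idx(fid, ms, fs)
        lo, hi = i - half40, i + half40
        if lo < 0 or hi > n:
            return np.nan
        return spectral_centroid(x[lo:hi], fs)

    out = {"RonsF": centroid_at(fid.qrs_on), "RoffsF": centroid_at(fid.qrs_off)}

    i_on = _idx(fid, fid.qrs_on, fs)
    i_off = _idx(fid, fid.qrs_off, fs)
    qrs = x[max(0, i_on):min(n, i_off + 1)]
    if len(qrs) >= 4:
        d, _ = dwt_band_energies(qrs, fs)
        out["QRSE1"], out["QRSE2"] = float(d[0]), float(d[1])
        out["QRS12energy"] = float(d[0] + d[1])
        out["HFQRS"] = band_energy(qrs, fs, (150.0, 250.0))
    else:
        out["QRSE1"] = out["QRSE2"] = out["QRS12energy"] = out["HFQRS"] = np.nan

    if fid.t_ons is not None and fid.t_end is not None:
        lo = max(0, _idx(fid, fid.t_ons, fs) - int(0.020 * fs))
        hi = min(n, _idx(fid, fid.t_end, fs) + int(0.020 * fs))
        tseg = x[lo:hi]
    else:
        tseg = np.array([])
    if len(tseg) >= 16:
        d, _ = dwt_band_energies(tseg, fs)
        for k in range(4):
            out[f"TE{k + 1}"] = float(d[k])
        out["Tpenergy"] = float(np.sum(tseg ** 2) / fs)
    else:
        out.update({f"TE{k + 1}": np.nan for k in range(4)})
        out["Tpenergy"] = np.nan
    return out


def shape_features(avg: np.ndarray, fid: FiducialSet, fs: float,
                   smooth_hz: float | None = 15.0) -> dict:
    """Front-slope ratios of the R and T waves.

    SBeta = max|dV/dt| on the leading T front / max|dV/dt| on the trailing
    T front; Beta is the same construction on the R wave (QRSon..Rpeak vs
    Rpeak..Speak). A symmetric wave gives a ratio of 1; values below 1 mean
    a shallower leading limb. Slopes for the T wave are taken after an
    optional low-pass (default 15 Hz) because they are noise-sensitive.
    """
    x = np.asarray(avg, dtype=float)
    dt_ms = 1000.0 / fs
    deriv = np.gradient(x) / dt_ms
    if smooth_hz is not None:
        sos = sps.butter(2, smooth_hz, btype="low", fs=fs, output="sos")
        sderiv = np.gradient(sps.sosfiltfilt(sos, x)) / dt_ms
    else:
        sderiv = deriv
    n = len(x)

    def max_abs(d: np.ndarray, ms_a: float, ms_b: float) -> float:
        ia = int(np.clip(_idx(fid, ms_a, fs), 0, n - 1))
        ib = int(np.clip(_idx(fid, ms_b, fs), 0, n - 1))
        if ib <= ia:
            return np.nan
        return float(np.max(np.abs(d[ia:ib + 1])))

    out: dict = {}
    lead_r = max_abs(deriv, fid.qrs_on, fid.r_peak)
    trail_r = max_abs(deriv, fid.r_peak, fid.s_peak)
    out["Beta"] = (lead_r / trail_r
                   if np.isfinite(trail_r) and trail_r > 1e-9 else np.nan)
    if None not in (fid.t_peak, fid.t_end):
        lead_t = max_abs(sderiv, fid.qrs_off + 40.0, fid.t_peak)
        trail_t = max_abs(sderiv, fid.t_peak, fid.t_end)
        out["SBeta"] = (lead_t / trail_t
                        if np.isfinite(trail_t) and trail_t > 1e-9 else np.nan)
    else:
        out["SBeta"] = np.nan
    return out


def extract_record_features(record: ECGRecord) -> dict:
    """All ECG parameters of one record (delineation included)."""
    avg, fid = delineate_record(record)
    fs = record.sampling_rate_hz
    mean_rr = float(np.mean(fid.rr_ms))
    feats: dict = {}
    feats.update(amplitude_features(avg, fid, fs))
    feats.update(interval_features(fid, mean_rr))
    feats.update(rhythm_features(fid.rr_ms))
    feats.update(spectral_features(avg, fid, fs))
    feats.update(shape_features(avg, fid, fs))
    return feats


def extract_cohort(records: list[ECGRecord], covariates: pd.DataFrame,
                   seed: int | None = None) -> FeatureTable:
    """Stack per-record parameters and clinical covariates into a cohort table.

    ``covariates`` needs columns subject_id, sex, age, smoking, diabetes,
    hypertension and (if available) lvef. Records failing the delineation
    quality gates are excluded and counted in the metadata, mirroring the
    exclusion of unsatisfactory recordings from a real screening cohort.
    """
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise LVScreenError("duplicate subject ids among records")
    cov = covariates.set_index("subject_id")
    rows, excluded = [], []
    for rec in records:
        try:
            feats = extract_record_features(rec)
        except (NoBeatsDetected, InsufficientBeats) as exc:
            excluded.append((rec.subject_id, str(exc)))
            continue
        c = cov.loc[rec.subject_id]
        feats["subject_id"] = rec.subject_id
        feats["male_gender"] = int(c["sex"] == "male")
        feats["age"] = float(c["age"])
        for k in ("smoking", "diabetes", "hypertension"):
            feats[k] = int(bool(c[k]))
        if "lvef" in cov.columns:
            feats["LVEF"] = float(c["lvef"])
        rows.append(feats)
    cols = ["subject_id"] + ALL_FEATURES + (
        ["LVEF"] if "lvef" in cov.columns else [])
    df = pd.DataFrame(rows)
    df = df.reindex(columns=cols)
    meta = {
        "extraction_version": EXTRACTION_VERSION,
        "n_excluded": len(excluded),
        "excluded": excluded,
        "seed": seed,
    }
    return FeatureTable(df=df, metadata=meta)
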