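"""Beat detection, beat averaging and wave delineation for one record.

R peaks are found with a Pan-Tompkins-style chain (band-pass, derivative,
squaring, moving-window integration, adaptive threshold, 250-ms refractory)
and refined on the raw signal. Beats are aligned on R and reduced to a
pointwise-median averaged beat, on which the fiducial points are located:

* QRS onset/offset from sustained derivative-magnitude threshold crossings
  either side of R; the J point is taken at QRS offset;
* the isoelectric baseline as the median of the PQ segment
  (QRSon-80 ms .. QRSon-20 ms);
* T peak as the extremum of the baseline-corrected post-QRS window; T onset
  and T offset as the maximum-|slope| points of the leading and trailing
  T fronts (derivatives from centred differences after a 15 Hz low-pass);
* T end (Tfi) by the tangent method: the tangent at the trailing
  maximum-slope point extended to the baseline;
* P onset/peaks/offset within a pre-QRS search window.

All fiducial times are reported in ms relative to QRS onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import InsufficientBeats, NoBeatsDetected, WaveNotFound
from .synth import ECGRecord

MIN_BEATS = 8
REFRACTORY_MS = 250.0


@dataclass
class FiducialSet:
    """Wave landmarks on the averaged beat, in ms relative to QRS onset."""

    r_indices: np.ndarray                # per-beat R sample indices
    rr_ms: np.ndarray                    # per-beat RR intervals (ms)
    window_ms: tuple[float, float]       # averaged-beat span (before, after R)
    baseline_uv: float
    # landmarks (ms relative to QRSon); None where the wave was unresolvable
    p_ons: float | None = None
    p_peak_pos: float | None = None
    p_peak_neg: float | None = None
    p_offs: float | None = None
    qrs_on: float = 0.0                  # time origin by construction
    r_peak: float = 0.0
    s_peak: float = 0.0
    qrs_off: float = 0.0
    j_point: float = 0.0
    t_ons: float | None = None
    t_peak: float | None = None
    t_offs: float | None = None
    t_end: float | None = None
    notes: list = field(default_factory=list)

    def ordering_ok(self) -> bool:
        seq = [self.qrs_on, self.r_peak, self.qrs_off]
        if None not in (self.t_ons, self.t_peak, self.t_offs, self.t_end):
            seq += [self.t_ons, self.t_peak, self.t_offs]
        if not all(a < b for a, b in zip(seq, seq[1:])):
            return False
        if self.t_offs is not None and self.t_end is not None \
                and self.t_offs > self.t_end:
            return False
        if None not in (self.p_ons, self.p_offs):
            if not (self.p_ons < self.p_offs < self.qrs_on):
                return False
        return True


def detect_r_peaks(record: ECGRecord) -> tuple[np.ndarray, np.ndarray]:
    """Locate R peaks; returns (sample indices, RR series in ms).

    Raises NoBeatsDetected on flat signals and InsufficientBeats when fewer
    than 8 beats survive, mirroring the exclusion of unsatisfactory records.
    """
    x = np.asarray(record.samples_uv, dtype=float)
    fs = record.sampling_rate_hz
    if len(x) < 10 * fs:
        raise InsufficientBeats("record shorter than 10 s")
    if np.ptp(x) < 1e-9 or np.std(x) < 1e-9:
        raise NoBeatsDetected("flat signal")

    sos = sps.butter(2, [5.0, 25.0], btype="band", fs=fs, output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    thr = 0.25 * np.percentile(integ, 99)
    refractory = int(round(REFRACTORY_MS * fs / 1000.0))
    above = integ > thr
    # rising-edge candidates of the integrated signal
    edges = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    peaks = []
    half = int(round(0.080 * fs))
    for e in edges:
        lo = max(0, e - half)
        hi = min(len(x), e + 2 * half)
        cand = lo + int(np.argmax(np.abs(bp[lo:hi])))
        # refine on the raw signal around the band-passed extremum
        lo2 = max(0, cand - half // 2)
        hi2 = min(len(x), cand + half // 2)
        cand = lo2 + int(np.argmax(x[lo2:hi2]))
        if peaks and cand - peaks[-1] < refractory:
            if x[cand] > x[peaks[-1]]:
                peaks[-1] = cand
            continue
        peaks.append(cand)
    peaks_arr = np.asarray(sorted(set(peaks)), dtype=int)
    if len(peaks_arr) == 0:
        raise NoBeatsDetected("no QRS candidates above threshold")
    if len(peaks_arr) < MIN_BEATS:
        raise InsufficientBeats(
            f"only {len(peaks_arr)} beats detected (need {MIN_BEATS})")
    rr_ms = np.diff(peaks_arr) * 1000.0 / fs
    return peaks_arr, rr_ms


def average_beat(record: ECGRecord, r_indices: np.ndarray,
                 window_ms: tuple[float, float] | None = None
                 ) -> tuple[np.ndarray, tuple[float, float]]:
    """Pointwise-median averaged beat from R-aligned segments.

    The default window spans -300..+500 ms around R at 60 bpm, scaled by
    the mean RR of the record; beats whose window falls off the record are
    excluded. Requires >= 8 usable beats.
    """
    x = np.asarray(record.samples_uv, dtype=float)
    fs = record.sampling_rate_hz
    if window_ms is None:
        mean_rr = float(np.mean(np.diff(r_indices))) * 1000.0 / fs
        scale = np.clip(mean_rr / 1000.0, 0.6, 1.2)
        window_ms = (300.0 * scale, 500.0 * scale)
    pre = int(round(window_ms[0] * fs / 1000.0))
    post = int(round(window_ms[1] * fs / 1000.0))
    segs = [x[r - pre:r + post] for r in r_indices
            if r - pre >= 0 and r + post <= len(x)]
    if len(segs) < MIN_BEATS:
        raise InsufficientBeats(
            f"only {len(segs)} usable beats inside the record (need {MIN_BEATS})")
    avg = np.median(np.vstack(segs), axis=0)
    return avg, (pre * 1000.0 / fs, post * 1000.0 / fs)


def _sustained_below(mag: np.ndarray, start: int, thr: float, fs: float,
                     direction: int, hold_ms: float = 8.0) -> int:
    """First index scanning from ``start`` where ``mag`` stays < thr for
    ``hold_ms``; returns the boundary index."""
    hold = max(1, int(round(hold_ms * fs / 1000.0)))
    i = start
    n = len(mag)
    run = 0
    while 0 <= i < n:
        if mag[i] < thr:
            run += 1
            if run >= hold:
                return i - direction * (hold - 1)
        else:
            run = 0
        i += direction
    return int(np.clip(i - direction, 0, n - 1))


def _subsample_crossing(mag: np.ndarray, boundary: int, thr: float,
                        direction: int) -> float:
    """Fractional index where ``mag`` crosses ``thr`` at a QRS boundary.

    ``boundary`` is the first below-threshold sample scanning in
    ``direction``; the adjacent sample toward the QRS is above threshold.
    Linear interpolation between the two refines the crossing below the
    sample grid.
    """
    inner = boundary - direction  # neighbour toward the QRS (above thr)
    if not 0 <= inner < len(mag):
        return float(boundary)
    hi, lo = mag[inner], mag[boundary]
    if hi <= lo or hi < thr:
        return float(boundary)
    frac = (hi - thr) / (hi - lo)  # 0 at inner, 1 at boundary
    return float(inner + direction * frac)


def locate_waves(avg: np.ndarray, fs: float,
                 window_ms: tuple[float, float],
                 r_indices: np.ndarray | None = None,
                 rr_ms: np.ndarray | None = None,
                 strict: bool = False) -> FiducialSet:
    """Locate P/QRS/T landmarks on an averaged beat.

    ``window_ms`` is the (pre, post) span around R used to build the beat;
    the R peak is assumed near sample ``pre``. Returns times in ms relative
    to the detected QRS onset. An unresolvable T wave (amplitude below
    twice the noise floor) leaves the T-dependent fields None; with
    ``strict=True`` it raises WaveNotFound instead.
    """
    dt_ms = 1000.0 / fs
    pre = int(round(window_ms[0] / dt_ms))
    n = len(avg)

    # R peak: extremum near the alignment point
    r_lo = max(0, pre - int(30 / dt_ms))
    r_hi = min(n, pre + int(30 / dt_ms))
    i_r = r_lo + int(np.argmax(avg[r_lo:r_hi]))

    # QRS bounds from the derivative magnitude (5% of max |d| near R).
    # A 40 Hz low-pass first: boundary thresholds must not depend on the
    # record's high-frequency intra-QRS content.
    sos40 = sps.butter(2, 40.0, btype="low", fs=fs, output="sos")
    deriv = np.gradient(sps.sosfiltfilt(sos40, avg)) / dt_ms
    mag = np.abs(deriv)
    qrs_span = int(150 / dt_ms)
    local = mag[max(0, i_r - qrs_span):min(n, i_r + qrs_span)]
    thr = 0.05 * float(np.max(local))
    i_on = _sustained_below(mag, i_r - int(10 / dt_ms), thr, fs, direction=-1)
    f_on = _subsample_crossing(mag, i_on, thr, -1)
    # S peak: minimum shortly after R
    s_hi = min(n, i_r + int(80 / dt_ms))
    i_s = i_r + int(np.argmin(avg[i_r:s_hi]))
    i_off = _sustained_below(mag, i_s + int(5 / dt_ms), thr, fs, direction=+1)
    f_off = _subsample_crossing(mag, i_off, thr, +1)

    # baseline: median of the PQ segment (QRSon-80 .. QRSon-20 ms)
    b_lo = max(0, i_on - int(80 / dt_ms))
    b_hi = max(b_lo + 1, i_on - int(20 / dt_ms))
    baseline = float(np.median(avg[b_lo:b_hi]))

    fid = FiducialSet(
        r_indices=np.asarray(r_indices if r_indices is not None else [],
                             dtype=int),
        rr_ms=np.asarray(rr_ms if rr_ms is not None else [], dtype=float),
        window_ms=window_ms,
        baseline_uv=baseline,
    )
    to_ms = lambda i: (i - f_on) * dt_ms  # noqa: E731 — times relative to QRSon
    fid.qrs_on = 0.0
    fid.r_peak = to_ms(i_r)
    fid.s_peak = to_ms(i_s)
    fid.qrs_off = to_ms(f_off)
    fid.j_point = fid.qrs_off

    # --- T wave on a 15 Hz low-passed copy (slope landmarks are noise-prone)
    sos = sps.butter(2, 15.0, btype="low", fs=fs, output="sos")
    smooth = sps.sosfiltfilt(sos, avg)
    sderiv = np.gradient(smooth) / dt_ms

    t_lo = min(n - 2, i_off + int(60 / dt_ms))
    t_hi = n - int(10 / dt_ms)
    if t_hi <= t_lo + 4:
        fid.notes.append("T search window empty")
        return fid
    seg = smooth[t_lo:t_hi] - baseline
    i_t = t_lo + int(np.argmax(np.abs(seg)))
    t_amp = smooth[i_t] - baseline
    noise_floor = float(np.std(avg[b_lo:b_hi] - np.median(avg[b_lo:b_hi])))
    if abs(t_amp) < max(2.0 * noise_floor, 5.0):
        fid.notes.append("T wave below noise floor")
        if strict:
            raise WaveNotFound("T amplitude below 2x noise floor")
        return fid

    i_tons = t_lo + int(np.argmax(np.abs(sderiv[t_lo:i_t]))) if i_t > t_lo else i_t
    i_toffs = i_t + int(np.argmax(np.abs(sderiv[i_t:t_hi]))) if t_hi > i_t else i_t
    fid.t_peak = to_ms(i_t)
    fid.t_ons = to_ms(i_tons)
    fid.t_offs = to_ms(i_toffs)
    # tangent method: extend the trailing max-slope tangent to the baseline
    slope = sderiv[i_toffs]
    if abs(slope) > 1e-9:
        dt_to_base = (baseline - smooth[i_toffs]) / slope  # ms
        fid.t_end = float(np.clip(fid.t_offs + dt_to_base,
                                  fid.t_offs, to_ms(n - 1)))
    else:
        fid.t_end = fid.t_offs
        fid.notes.append("flat trailing T front; Tfi = Toffs")

    # --- P wave in the pre-QRS window
    p_lo = max(0, i_on - int(250 / dt_ms))
    p_hi = max(p_lo + 2, i_on - int(30 / dt_ms))
    pseg = smooth[p_lo:p_hi] - baseline
    if len(pseg) > 4 and float(np.max(np.abs(pseg))) > max(2.0 * noise_floor, 5.0):
        i_pp = p_lo + int(np.argmax(pseg))
        i_pn = p_lo + int(np.argmin(pseg))
        fid.p_peak_pos = to_ms(i_pp)
        fid.p_peak_neg = to_ms(i_pn)
        p_amp = float(np.max(np.abs(pseg)))
        i_main = p_lo + int(np.argmax(np.abs(pseg)))
        lvl = 0.1 * p_amp
        j = i_main
        while j > p_lo and abs(smooth[j] - baseline) > lvl:
            j -= 1
        fid.p_ons = to_ms(j)
        j = i_main
        while j < p_hi - 1 and abs(smooth[j] - baseline) > lvl:
            j += 1
        fid.p_offs = to_ms(min(j, i_on - 1))
        if not (fid.p_ons < fid.p_offs < fid.qrs_on):
            fid.p_ons = fid.p_offs = None
            fid.p_peak_pos = fid.p_peak_neg = None
            fid.notes.append("P ordering failed; P marked missing")
    else:
        fid.notes.append("P wave below noise floor")
    return fid


def delineate_record(record: ECGRecord) -> tuple[np.ndarray, FiducialSet]:
    """Full per-record chain: R detection -> averaged beat -> fiducials.

    Returns (averaged beat, FiducialSet)."""
    r_idx, rr_ms = detect_r_peaks(record)
    avg, window = average_beat(record, r_idx)
    fid = locate_waves(avg, record.sampling_rate_hz, window,
                       r_indices=r_idx, rr_ms=rr_ms)
    return avg, fid
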