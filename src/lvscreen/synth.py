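"""Synthetic single-lead ECG cohorts with LVEF-linked morphology.

The generator stands in for a clinical screening cohort: each synthetic
subject carries clinical covariates (sex, age, smoking, diabetes,
hypertension) and a latent left-ventricular ejection fraction (LVEF, %),
and each 60-s lead-I record is a train of template beats whose morphology
degrades monotonically as LVEF falls below the normal range:

* T-wave amplitude decreases,
* the QRS complex widens,
* high-frequency (150-250 Hz) intra-QRS content decreases.

Each beat is a sum of Gaussian kernels (one per P/Q/R/S wave, an asymmetric
pair for T), in the spirit of classic synthetic-ECG beat models. A narrow
Gabor burst centred on the R peak supplies the high-frequency QRS band.
Every record carries its generating ground truth (fiducial times, kernel
amplitudes) so downstream delineation error is measurable in ms / uV.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

# Sex-specific lower bounds of normal LVEF (%): the screening endpoint
# "below normal" is <52 for men, <54 for women.
MALE_EF_CUTOFF = 52.0
FEMALE_EF_CUTOFF = 54.0

#: LVEF (%) below which the generator starts degrading beat morphology.
#: Chosen just above the female cutoff so every "below-normal" subject has
#: nonzero severity.
MORPHOLOGY_EF_REF = 55.0
#: severity = clip((MORPHOLOGY_EF_REF - LVEF) / SEVERITY_SCALE, 0, 2):
#: severity 1 at LVEF 40 (the severe endpoint), saturating at LVEF 25.
SEVERITY_SCALE = 15.0


@dataclass(frozen=True)
class WaveKernel:
    """One Gaussian wave kernel of the beat template.

    amplitude_uv : peak deflection relative to baseline (uV, signed)
    width_ms     : Gaussian sigma (ms)
    center_ms    : kernel centre relative to the R peak (ms)
    asymmetry    : trailing-sigma / leading-sigma ratio (>0); 1 = symmetric
    """

    amplitude_uv: float
    width_ms: float
    center_ms: float
    asymmetry: float = 1.0

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ConfigurationError("kernel width must be > 0")
        if self.asymmetry <= 0:
            raise ConfigurationError("kernel asymmetry must be > 0")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Kernel value at times ``t_ms`` relative to the R peak."""
        x = t_ms - self.center_ms
        sigma = np.where(x < 0, self.width_ms, self.width_ms * self.asymmetry)
        return self.amplitude_uv * np.exp(-0.5 * (x / sigma) ** 2)


@dataclass(frozen=True)
class BeatTemplateParams:
    """Per-wave kernels of one beat plus the high-frequency QRS burst."""

    p: WaveKernel = WaveKernel(120.0, 22.0, -170.0)
    q: WaveKernel = WaveKernel(-100.0, 7.0, -28.0)
    r: WaveKernel = WaveKernel(1000.0, 10.0, 0.0)
    s: WaveKernel = WaveKernel(-200.0, 8.0, 28.0)
    # Normal T: the leading (ascending) limb is shallower than the trailing
    # limb, so the leading/trailing slope ratio sits slightly below 1.
    t: WaveKernel = WaveKernel(300.0, 45.0, 280.0, asymmetry=0.82)
    hf_amplitude_uv: float = 25.0   # Gabor burst peak (uV)
    hf_freq_hz: float = 180.0       # burst carrier, inside the 150-250 Hz band
    hf_width_ms: float = 4.0        # burst Gaussian sigma

    def __post_init__(self) -> None:
        centers = [self.p.center_ms, self.q.center_ms, self.r.center_ms,
                   self.s.center_ms, self.t.center_ms]
        if not all(a < b for a, b in zip(centers, centers[1:])):
            raise ConfigurationError("wave centers must be ordered P < Q < R < S < T")
        if self.r.amplitude_uv <= 0:
            raise ConfigurationError("R amplitude must be > 0")

    def evaluate(self, t_ms: np.ndarray) -> np.ndarray:
        """Template voltage (uV) at times relative to the R peak."""
        v = np.zeros_like(t_ms, dtype=float)
        for k in (self.p, self.q, self.r, self.s, self.t):
            v += k.evaluate(t_ms)
        v += (self.hf_amplitude_uv
              * np.exp(-0.5 * (t_ms / self.hf_width_ms) ** 2)
              * np.cos(2.0 * np.pi * self.hf_freq_hz * t_ms / 1000.0))
        return v


@dataclass(frozen=True)
class SubjectProfile:
    """Covariates plus latent LVEF for one synthetic subject."""

    subject_id: str
    sex: str                 # "male" | "female"
    age: float               # years
    smoking: bool
    diabetes: bool
    hypertension: bool
    lvef: float              # percent, in [10, 80]

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ConfigurationError(f"sex must be male/female, got {self.sex!r}")
        if not 10.0 <= self.lvef <= 80.0:
            raise ConfigurationError(f"LVEF {self.lvef} outside [10, 80]")

    @property
    def ef_cutoff(self) -> float:
        return MALE_EF_CUTOFF if self.sex == "male" else FEMALE_EF_CUTOFF


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs of the synthetic cohort.

    Defaults emulate the screening cohort the pipeline is designed for:
    n=624 subjects, 20.2% below the sex-specific normal LVEF cutoff and
    10.9% below 40%, one 60-s resting lead-I record per subject.
    """

    n_subjects: int = 624
    prev_below_normal: float = 0.202
    prev_lt40: float = 0.109
    # Per-unit-severity shifts of the generating beat parameters, in units
    # of the corresponding control-population SD.
    effect_sizes: dict = field(default_factory=lambda: {
        "t_amp": 1.5,      # T amplitude falls
        "qrs_width": 1.0,  # R-kernel sigma grows (QRS widens)
        "hf_amp": 1.0,     # high-frequency QRS content falls
    })
    # Control-population SDs of those parameters (scatter between subjects).
    param_sds: dict = field(default_factory=lambda: {
        "t_amp": 60.0,     # uV
        "qrs_width": 1.2,  # ms
        "hf_amp": 5.0,     # uV
    })
    hr_mean_bpm: float = 70.0
    sdnn_target_ms: float = 40.0
    noise_rms_uv: float = 15.0
    baseline_wander_uv: float = 0.0   # 0.2 Hz sinusoid amplitude; default off
    sampling_rate_hz: float = 1000.0
    duration_s: float = 60.0
    male_fraction: float = 0.418
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.prev_lt40 <= self.prev_below_normal <= 1.0):
            raise ConfigurationError(
                "need 0 <= prev_lt40 <= prev_below_normal <= 1 "
                f"(got {self.prev_lt40}, {self.prev_below_normal})")
        if self.sampling_rate_hz < 500.0:
            raise ConfigurationError("sampling rate must be >= 500 Hz")
        if self.duration_s <= 0:
            raise ConfigurationError("duration must be > 0")
        # The HF burst needs headroom below Nyquist.
        if self.sampling_rate_hz < 2.0 * 250.0:
            raise ConfigurationError(
                "sampling rate too low for 150-250 Hz QRS content")


@dataclass
class ECGRecord:
    """A sampled single-lead voltage series plus generating ground truth."""

    subject_id: str
    sampling_rate_hz: float
    samples_uv: np.ndarray
    ground_truth: dict | None = None

    @property
    def duration_s(self) -> float:
        return len(self.samples_uv) / self.sampling_rate_hz


def severity_from_lvef(lvef: float) -> float:
    """Monotone morphology-degradation score: 0 for normal EF, 1 at EF 40."""
    return float(np.clip((MORPHOLOGY_EF_REF - lvef) / SEVERITY_SCALE, 0.0, 2.0))


def generate_cohort(config: CohortConfig) -> list[SubjectProfile]:
    """Draw a cohort of subject profiles from the configured LVEF mixture.

    LVEF comes from a three-component mixture: normal (>= 55%), mildly
    reduced (40 <= EF < 52), and severely reduced (< 40%), with component
    weights matching the configured prevalences. Sex-specific cutoffs are
    applied downstream when labelling, not here.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    u = rng.random(n)
    profiles: list[SubjectProfile] = []
    for i in range(n):
        sex = "male" if rng.random() < config.male_fraction else "female"
        if u[i] < config.prev_lt40:
            # severe: N(32, 5) truncated to [15, 39.5]
            lvef = _trunc_normal(rng, 32.0, 5.0, 15.0, 39.5)
        elif u[i] < config.prev_below_normal:
            # mildly reduced: N(46, 3) truncated to [40, 51.5] — below the
            # male cutoff, hence below either sex-specific cutoff
            lvef = _trunc_normal(rng, 46.0, 3.0, 40.0, 51.5)
        else:
            # normal: N(62, 4) truncated to [55, 78] — at or above both cutoffs
            lvef = _trunc_normal(rng, 62.0, 4.0, 55.0, 78.0)
        profiles.append(SubjectProfile(
            subject_id=f"S{i:04d}",
            sex=sex,
            age=float(np.clip(rng.normal(58.0, 16.0), 18.0, 90.0)),
            smoking=bool(rng.random() < 0.167),
            diabetes=bool(rng.random() < 0.131),
            hypertension=bool(rng.random() < 0.595),
            lvef=round(lvef, 1),
        ))
    return profiles


def _trunc_normal(rng: np.random.Generator, mu: float, sd: float,
                  lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mu, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mu, lo, hi))


def generate_rr_series(hr_mean_bpm: float, sdnn_target_ms: float,
                       n_beats: int, seed: int | np.random.Generator = 0
                       ) -> np.ndarray:
    """RR intervals (ms): Gaussian around 60000/HR, truncated at 250 ms."""
    if hr_mean_bpm <= 0:
        raise ConfigurationError("heart rate must be > 0")
    if sdnn_target_ms < 0:
        raise ConfigurationError("SDNN target must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    mean_rr = 60000.0 / hr_mean_bpm
    rr = rng.normal(mean_rr, sdnn_target_ms, size=n_beats)
    return np.maximum(rr, 250.0)


def subject_template(profile: SubjectProfile, config: CohortConfig,
                     rng: np.random.Generator) -> BeatTemplateParams:
    """Beat template for one subject: LVEF-linked shifts + Gaussian scatter."""
    sev = severity_from_lvef(profile.lvef)
    es, sd = config.effect_sizes, config.param_sds
    base = BeatTemplateParams()
    t_amp = (base.t.amplitude_uv
             - sev * es["t_amp"] * sd["t_amp"]
             + rng.normal(0.0, sd["t_amp"]))
    t_amp = float(np.clip(t_amp, 30.0, 600.0))
    r_sigma = (base.r.width_ms
               + sev * es["qrs_width"] * sd["qrs_width"]
               + rng.normal(0.0, sd["qrs_width"]))
    r_sigma = float(np.clip(r_sigma, 6.0, 20.0))
    hf_amp = (base.hf_amplitude_uv
              - sev * es["hf_amp"] * sd["hf_amp"]
              + rng.normal(0.0, sd["hf_amp"]))
    hf_amp = float(np.clip(hf_amp, 2.0, 60.0))
    # between-subject scatter of the T-wave position (repolarisation timing)
    t_center = float(np.clip(base.t.center_ms + rng.normal(0.0, 8.0),
                             base.s.center_ms + 120.0, 360.0))
    # Q and S widen with R so the whole QRS broadens coherently.
    qs_scale = r_sigma / base.r.width_ms
    return BeatTemplateParams(
        p=base.p,
        q=dataclasses.replace(base.q, width_ms=base.q.width_ms * qs_scale),
        r=dataclasses.replace(base.r, width_ms=r_sigma),
        s=dataclasses.replace(base.s, width_ms=base.s.width_ms * qs_scale),
        t=dataclasses.replace(base.t, amplitude_uv=t_amp, center_ms=t_center),
        hf_amplitude_uv=hf_amp,
        hf_freq_hz=base.hf_freq_hz,
        hf_width_ms=base.hf_width_ms,
    )


def synthesize_record(profile: SubjectProfile, config: CohortConfig,
                      seed: int) -> ECGRecord:
    """Render one 60-s lead-I record for a subject.

    The record is a train of identical subject-specific template beats at
    R times given by the RR series, plus white Gaussian noise of the
    configured RMS and (optionally) a 0.2 Hz baseline-wander sinusoid.
    """
    rng = np.random.default_rng(seed)
    template = subject_template(profile, config, rng)
    fs = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * fs))
    mean_rr = 60000.0 / config.hr_mean_bpm
    n_beats = int(np.ceil(config.duration_s * 1000.0 / mean_rr)) + 3
    rr = generate_rr_series(config.hr_mean_bpm, config.sdnn_target_ms,
                            n_beats, rng)
    r_times_ms = 400.0 + np.cumsum(np.concatenate([[0.0], rr[:-1]]))
    r_times_ms = r_times_ms[r_times_ms < config.duration_s * 1000.0 - 100.0]

    t_ms = np.arange(n_samples) * (1000.0 / fs)
    signal = np.zeros(n_samples)
    half_span_ms = 600.0
    for r_ms in r_times_ms:
        lo = max(0, int((r_ms - half_span_ms) * fs / 1000.0))
        hi = min(n_samples, int((r_ms + half_span_ms) * fs / 1000.0))
        signal[lo:hi] += template.evaluate(t_ms[lo:hi] - r_ms)

    if config.baseline_wander_uv > 0:
        signal += config.baseline_wander_uv * np.sin(
            2.0 * np.pi * 0.2 * t_ms / 1000.0)
    if config.noise_rms_uv > 0:
        signal += rng.normal(0.0, config.noise_rms_uv, size=n_samples)

    rr_used = np.diff(r_times_ms)
    truth = {
        "lvef": profile.lvef,
        "severity": severity_from_lvef(profile.lvef),
        "r_times_ms": r_times_ms.tolist(),
        "mean_rr_ms": float(np.mean(rr_used)) if len(rr_used) else float("nan"),
        "sdnn_ms": float(np.std(rr_used)) if len(rr_used) else float("nan"),
        "t_amp_uv": template.t.amplitude_uv,
        "t_center_ms": template.t.center_ms,
        "r_sigma_ms": template.r.width_ms,
        "hf_amp_uv": template.hf_amplitude_uv,
        # 3-sigma extent of the Q and S kernels bounds the true QRS support
        "qrs_on_ms": template.q.center_ms - 3.0 * template.q.width_ms,
        "qrs_off_ms": template.s.center_ms + 3.0 * template.s.width_ms,
    }
    return ECGRecord(subject_id=profile.subject_id, sampling_rate_hz=fs,
                     samples_uv=signal, ground_truth=truth)


def generate_study(config: CohortConfig
                   ) -> tuple[list[SubjectProfile], list[ECGRecord]]:
    """Cohort profiles plus one record per subject, all from ``config.seed``."""
    profiles = generate_cohort(config)
    seeds = np.random.SeedSequence(config.seed).spawn(len(profiles))
    records = [
        synthesize_record(p, config, seed=int(s.generate_state(1)[0] % (2**31)))
        for p, s in zip(profiles, seeds)
    ]
    return profiles, records
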