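"""Synthetic ECG cohort generator with a known electrolyte→morphology forward model.

The generator is a statistical stand-in for a clinical ECG archive: it does not
attempt electrophysiological realism (no torso or ionic-current model), but it
gives precise, analytic control over exactly the waveform features through which
serum electrolytes manifest on the ECG — the T-wave amplitude (potassium-like
analytes) and the repolarization-interval length (calcium-like analytes). This
makes parameter recovery and the "predictable vs unpredictable analyte"
contrast directly testable.

Each beat is a sum of Gaussian wavelets (P, Q, R, S, T) with a per-lead
amplitude map over the 8 independent leads, repeated at RR intervals with
seeded jitter and a random start phase. Concentration ``c`` acts on the beat
through an :class:`EffectModel`:

* T-wave amplitude is scaled by ``1 + t_amplitude_coeff * (c - reference)``,
* the S-to-T-onset interval is shifted by ``repol_interval_coeff * (c - reference)``
  seconds.

With all coefficients at zero the waveform is independent of concentration.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from datetime import date, datetime, timedelta

import numpy as np

from .records import (
    Cohort,
    ECGRecord,
    LabMeasurement,
    PatientRecord,
    INDEPENDENT_LEADS,
    TWELVE_LEADS,
    LeadMismatchError,
)

__all__ = [
    "AnalyteSpec",
    "EffectModel",
    "NoiseSpec",
    "InvalidConfigError",
    "ANALYTES",
    "STRONG_EFFECT",
    "WEAK_EFFECT",
    "NULL_EFFECT",
    "DEFAULT_NOISE",
    "NO_NOISE",
    "sample_cohort",
    "synthesize_ecg",
    "make_twelve_lead",
    "beat_schedule",
    "t_wave_windows",
]


class InvalidConfigError(ValueError):
    """Raised for physically or statistically inconsistent generator settings."""


@dataclass(frozen=True)
class AnalyteSpec:
    """Marginal concentration distribution and clinical bounds of one analyte.

    ``hypo_bound``/``hyper_bound`` are the clinical thresholds below/above
    which a value counts as abnormally low/high.
    """

    name: str
    mean: float
    sd: float
    unit_label: str
    hypo_bound: float
    hyper_bound: float
    distribution: str = "truncnormal"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise InvalidConfigError("analyte sd must be positive")
        if not self.hypo_bound < self.mean < self.hyper_bound:
            raise InvalidConfigError("bounds must satisfy hypo < mean < hyper")
        if self.distribution not in ("truncnormal", "lognormal"):
            raise InvalidConfigError(f"unknown distribution {self.distribution!r}")


#: Analyte presets: marginal moments and hypo/hyper bounds of the four
#: analytes studied. Creatinine's sd is comparable to its mean, so a
#: log-normal marginal is used for it instead of a heavily truncated Gaussian;
#: its clinical bounds default to mean±2sd.
ANALYTES: dict[str, AnalyteSpec] = {
    "potassium": AnalyteSpec("potassium", 3.99, 0.50, "mmol/l", 3.5, 5.5),
    "calcium": AnalyteSpec("calcium", 2.29, 0.13, "mmol/l", 2.0, 2.75),
    "sodium": AnalyteSpec("sodium", 138.93, 3.82, "mmol/l", 130.0, 150.0),
    "creatinine": AnalyteSpec(
        "creatinine", 90.55, 71.00, "umol/l",
        90.55 - 2 * 71.00 if 90.55 - 2 * 71.00 > 0 else 20.0,
        90.55 + 2 * 71.00,
        distribution="lognormal",
    ),
}


@dataclass(frozen=True)
class EffectModel:
    """How concentration modulates beat morphology.

    ``t_amplitude_coeff`` is a dimensionless relative T-amplitude change per
    unit concentration; ``repol_interval_coeff`` is in seconds per unit
    concentration; both act on ``(c - reference_concentration)``.
    """

    t_amplitude_coeff: float = 0.0
    repol_interval_coeff: float = 0.0
    reference_concentration: float = 4.0


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances, in millivolt (amplitudes) and Hz (frequency)."""

    baseline_wander_amp: float = 0.0
    powerline_amp: float = 0.0
    powerline_freq: float = 50.0  # Swedish mains; set 60 for US-dialect data
    white_sd: float = 0.0

    def __post_init__(self) -> None:
        if min(self.baseline_wander_amp, self.powerline_amp, self.white_sd) < 0:
            raise InvalidConfigError("noise amplitudes must be >= 0")


NULL_EFFECT = EffectModel(0.0, 0.0, 4.0)
WEAK_EFFECT = EffectModel(0.05, 0.002, 4.0)
STRONG_EFFECT = EffectModel(0.5, 0.02, 4.0)
NO_NOISE = NoiseSpec()
DEFAULT_NOISE = NoiseSpec(
    baseline_wander_amp=0.05, powerline_amp=0.02, powerline_freq=50.0, white_sd=0.02
)

# ----------------------------------------------------------------------------
# Beat template: Gaussian wavelets with per-lead amplitude maps.
# Offsets are seconds from beat onset; widths are Gaussian sigmas in seconds.
# Lead order: I, II, V1, V2, V3, V4, V5, V6.
# ----------------------------------------------------------------------------

_WAVE_OFFSET = {"P": 0.10, "Q": 0.20, "R": 0.23, "S": 0.26}
_WAVE_WIDTH = {"P": 0.025, "Q": 0.010, "R": 0.012, "S": 0.012, "T": 0.050}
_BASE_AMP = {"P": 0.10, "Q": -0.10, "R": 1.00, "S": -0.25, "T": 0.30}
_LEAD_SCALE = {
    "P": np.array([0.8, 1.0, 0.3, 0.4, 0.5, 0.6, 0.7, 0.7]),
    "Q": np.array([0.5, 0.8, 0.2, 0.3, 0.5, 0.8, 1.0, 0.9]),
    "R": np.array([0.7, 1.0, 0.25, 0.5, 0.9, 1.1, 1.0, 0.9]),
    "S": np.array([0.4, 0.6, 1.2, 1.0, 0.7, 0.4, 0.3, 0.2]),
    "T": np.array([0.6, 1.0, 0.35, 0.8, 1.0, 0.9, 0.8, 0.7]),
}
#: Baseline S-to-T-onset interval (seconds) at the reference concentration.
_BASE_S_TO_T_ONSET = 0.08
#: T center sits one T-width past its onset.
_T_ONSET_TO_CENTER = 0.05
_RR_JITTER_SD = 0.03  # relative RR jitter


def _beat_onsets(rng: np.random.Generator, heart_rate: float, duration: float) -> np.ndarray:
    """Beat onset times (s); first beat starts at a random phase within one RR."""
    rr = 60.0 / heart_rate
    onsets = [-rr + rng.uniform(0.0, rr)]
    while onsets[-1] < duration:
        onsets.append(onsets[-1] + rr * (1.0 + _RR_JITTER_SD * rng.standard_normal()))
    return np.array(onsets)


def beat_schedule(heart_rate: float, duration: float, seed: int) -> np.ndarray:
    """The beat onsets :func:`synthesize_ecg` will use for the same seed.

    Exposed so downstream code (annotation of wave windows, tests) can locate
    individual waves without re-deriving them from the waveform.
    """
    return _beat_onsets(np.random.default_rng(seed), heart_rate, duration)


def _t_center_offset(effect: EffectModel, concentration: float) -> float:
    """Seconds from beat onset to T-wave center; validates positivity."""
    s_to_t = _BASE_S_TO_T_ONSET + effect.repol_interval_coeff * (
        concentration - effect.reference_concentration
    )
    if s_to_t <= 0:
        raise InvalidConfigError(
            f"repolarization interval {s_to_t:.4f}s <= 0 at concentration {concentration}"
        )
    return _WAVE_OFFSET["S"] + s_to_t + _T_ONSET_TO_CENTER


def synthesize_ecg(
    concentration: float,
    patient: PatientRecord,
    effect: EffectModel,
    noise: NoiseSpec,
    heart_rate: float = 70.0,
    fs: float = 256.0,
    duration: float = 8.0,
    seed: int = 0,
    acquisition_time: datetime | None = None,
    ecg_id: str = "E0",
) -> ECGRecord:
    """Generate one 8-lead trace for a given concentration.

    Deterministic in ``seed``: beat phase/jitter and all noise terms are
    drawn from a generator seeded with it.
    """
    if fs < 100:
        raise InvalidConfigError("fs must be >= 100 Hz")
    if duration <= 0:
        raise InvalidConfigError("duration must be positive")
    if not 30 <= heart_rate <= 220:
        raise InvalidConfigError("heart rate outside [30, 220] bpm")

    rng = np.random.default_rng(seed)
    onsets = _beat_onsets(rng, heart_rate, duration)
    n = round(fs * duration)
    t = np.arange(n) / fs
    trace = np.zeros((8, n))

    t_center = _t_center_offset(effect, concentration)
    t_scale = 1.0 + effect.t_amplitude_coeff * (
        concentration - effect.reference_concentration
    )
    for onset in onsets:
        for wave in ("P", "Q", "R", "S", "T"):
            center = onset + (_WAVE_OFFSET[wave] if wave != "T" else t_center)
            amp = _BASE_AMP[wave] * (t_scale if wave == "T" else 1.0)
            bump = np.exp(-0.5 * ((t - center) / _WAVE_WIDTH[wave]) ** 2)
            trace += amp * _LEAD_SCALE[wave][:, None] * bump[None, :]

    if noise.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=8)
        trace += noise.baseline_wander_amp * np.sin(
            2 * np.pi * 0.33 * t[None, :] + phase[:, None]
        )
    if noise.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=8)
        trace += noise.powerline_amp * np.sin(
            2 * np.pi * noise.powerline_freq * t[None, :] + phase[:, None]
        )
    if noise.white_sd > 0:
        trace += noise.white_sd * rng.standard_normal(trace.shape)

    return ECGRecord(
        ecg_id=ecg_id,
        patient_id=patient.patient_id,
        acquisition_time=acquisition_time or datetime(2012, 1, 1),
        fs=fs,
        trace=trace.astype(np.float32),
        lead_labels=INDEPENDENT_LEADS,
    )


def t_wave_windows(
    heart_rate: float,
    duration: float,
    fs: float,
    seed: int,
    effect: EffectModel,
    concentration: float,
    half_width_sigmas: float = 2.0,
) -> list[tuple[int, int]]:
    """Sample-index windows centered on each T wave of a seeded trace."""
    onsets = beat_schedule(heart_rate, duration, seed)
    center = _t_center_offset(effect, concentration)
    half = half_width_sigmas * _WAVE_WIDTH["T"]
    n = round(fs * duration)
    windows = []
    for onset in onsets:
        lo = int(round((onset + center - half) * fs))
        hi = int(round((onset + center + half) * fs))
        if lo >= 0 and hi < n:
            windows.append((lo, hi))
    return windows


def make_twelve_lead(record: ECGRecord) -> ECGRecord:
    """Append the four mathematically redundant leads to an 8-lead trace.

    Einthoven/Goldberger identities: III = II − I, aVR = −(I+II)/2,
    aVL = I − II/2, aVF = II − I/2.
    """
    if record.lead_labels != INDEPENDENT_LEADS:
        raise LeadMismatchError(
            f"expected leads {INDEPENDENT_LEADS}, got {record.lead_labels}"
        )
    idx = {name: i for i, name in enumerate(record.lead_labels)}
    one, two = record.trace[idx["I"]], record.trace[idx["II"]]
    derived = np.stack([two - one, -(one + two) / 2.0, one - two / 2.0, two - one / 2.0])
    return replace(
        record,
        trace=np.concatenate([record.trace, derived.astype(record.trace.dtype)]),
        lead_labels=TWELVE_LEADS,
    )


# ----------------------------------------------------------------------------
# Cohort sampling
# ----------------------------------------------------------------------------

#: Age distribution of the emulated emergency-department population.
_AGE_MEAN, _AGE_SD = 61.26, 19.61
_AGE_LO, _AGE_HI = 18.0, 95.0
_MALE_FRACTION = 0.4938

_STUDY_START = date(2009, 1, 1)
_STUDY_END = date(2017, 12, 31)


def _count_from_spec(rng: np.random.Generator, spec) -> int:
    """Resolve a per-patient count distribution spec to a draw >= 1."""
    if isinstance(spec, int):
        if spec < 1:
            raise InvalidConfigError("counts must be >= 1")
        return spec
    kind, param = spec
    if kind == "poisson":  # 1 + Poisson(param)
        return 1 + int(rng.poisson(param))
    raise InvalidConfigError(f"unknown count distribution {kind!r}")


def _draw_concentration(
    rng: np.random.Generator, analyte: AnalyteSpec, sd_scale: float
) -> float:
    sd = analyte.sd * sd_scale
    if analyte.distribution == "lognormal":
        # match mean and sd of the log-normal exactly
        var = sd**2
        mu2 = analyte.mean**2
        sigma2 = math.log(1.0 + var / mu2)
        mu = math.log(analyte.mean) - sigma2 / 2.0
        return float(rng.lognormal(mu, math.sqrt(sigma2)))
    lo = 0.05 * analyte.mean  # physiologic positivity floor
    for _ in range(100):
        c = rng.normal(analyte.mean, sd)
        if c > lo:
            return float(c)
    return lo  # pragma: no cover — unreachable for realistic specs


def sample_cohort(
    analyte: AnalyteSpec,
    n_patients: int,
    ecgs_per_patient=("poisson", 0.7),
    labs_per_patient=("poisson", 0.7),
    age_variance_slope: float = 0.3,
    seed: int = 0,
    effect: EffectModel = STRONG_EFFECT,
    noise: NoiseSpec = DEFAULT_NOISE,
    fs: float = 256.0,
    duration: float = 8.0,
    target_noise_sd: float | None = None,
    target_noise_slope: float = 0.0,
    encounter_offset_minutes: float = 90.0,
    revisit_prob: float = 0.12,
    quality_jitter: float = 0.75,
) -> Cohort:
    """Sample a full synthetic cohort.

    Parameters
    ----------
    age_variance_slope:
        Strength of the age-dependence of the target spread: the conditional
        concentration sd is ``analyte.sd * sqrt(1 + slope * z_age)`` (clipped
        below at 10% of the marginal variance), with ``z_age`` the
        standardized age. The sqrt form keeps the *marginal* sd at the
        analyte's nominal value while making the spread increase with age.
    target_noise_sd:
        Measurement-noise sd of the lab assay around the patient's true
        concentration; defaults to ``0.1 * analyte.sd``. With
        ``target_noise_slope`` > 0 the noise sd additionally grows linearly
        with the standardized concentration (heteroscedastic labs).
    encounter_offset_minutes:
        ECG and lab timestamps are drawn uniformly within ± this window of a
        per-encounter time, so that pairs both inside and outside the ±60 min
        linking window arise.
    revisit_prob:
        Probability of a second encounter 30–500 days after admission; these
        produce post-cutoff ECGs for pre-cutoff patients, exercising the
        temporal-leakage removal.
    quality_jitter:
        Per-ECG signal-quality variation: each trace's white-noise sd is
        multiplied by a lognormal factor ``exp(quality_jitter * N(0,1))``.
        Clinical ECG archives mix clean and heavily disturbed recordings,
        and this input-quality heterogeneity is what lets a heteroscedastic
        model associate hard-to-read traces with larger predictive
        variance. Set 0 for homogeneous quality.
    """
    if n_patients < 1:
        raise InvalidConfigError("n_patients must be >= 1")
    if target_noise_sd is None:
        target_noise_sd = 0.1 * analyte.sd
    if target_noise_sd < 0:
        raise InvalidConfigError("target_noise_sd must be >= 0")

    rng = np.random.default_rng(seed)
    patients: list[PatientRecord] = []
    ecgs: list[ECGRecord] = []
    labs: list[LabMeasurement] = []
    study_days = (_STUDY_END - _STUDY_START).days

    ecg_counter = lab_counter = 0
    for i in range(n_patients):
        pid = f"P{i:06d}"
        while True:
            age = rng.normal(_AGE_MEAN, _AGE_SD)
            if _AGE_LO <= age <= _AGE_HI:
                break
        sex = "male" if rng.uniform() < _MALE_FRACTION else "female"
        admission = _STUDY_START + timedelta(days=int(rng.integers(0, study_days + 1)))
        patients.append(PatientRecord(pid, float(age), sex, admission))

        z_age = (age - _AGE_MEAN) / _AGE_SD
        sd_scale = math.sqrt(max(0.1, 1.0 + age_variance_slope * z_age))

        encounters = [datetime.combine(admission, datetime.min.time())
                      + timedelta(seconds=int(rng.integers(0, 86400)))]
        if rng.uniform() < revisit_prob:
            encounters.append(encounters[0] + timedelta(days=float(rng.uniform(30, 500))))

        for enc_time in encounters:
            conc = _draw_concentration(rng, analyte, sd_scale)
            n_ecgs = _count_from_spec(rng, ecgs_per_patient)
            n_labs = _count_from_spec(rng, labs_per_patient)
            heart_rate = float(np.clip(rng.normal(75, 8), 50, 110))
            for _ in range(n_ecgs):
                offset = rng.uniform(-encounter_offset_minutes, encounter_offset_minutes)
                ecg_seed = int(rng.integers(0, 2**31 - 1))
                if quality_jitter > 0 and noise.white_sd > 0:
                    ecg_noise = replace(
                        noise,
                        white_sd=noise.white_sd
                        * float(np.exp(quality_jitter * rng.standard_normal())),
                    )
                else:
                    ecg_noise = noise
                ecgs.append(
                    synthesize_ecg(
                        conc,
                        patients[-1],
                        effect,
                        ecg_noise,
                        heart_rate=heart_rate,
                        fs=fs,
                        duration=duration,
                        seed=ecg_seed,
                        acquisition_time=enc_time + timedelta(minutes=offset),
                        ecg_id=f"E{ecg_counter:07d}",
                    )
                )
                ecg_counter += 1
            noise_sd = target_noise_sd * max(
                0.0, 1.0 + target_noise_slope * (conc - analyte.mean) / analyte.sd
            )
            for _ in range(n_labs):
                offset = rng.uniform(-encounter_offset_minutes, encounter_offset_minutes)
                value = conc + rng.normal(0.0, noise_sd) if noise_sd > 0 else conc
                labs.append(
                    LabMeasurement(
                        f"L{lab_counter:07d}",
                        pid,
                        analyte.name,
                        float(value),
                        analyte.unit_label,
                        enc_time + timedelta(minutes=offset),
                    )
                )
                lab_counter += 1

    config = {
        "analyte": asdict(analyte),
        "n_patients": n_patients,
        "ecgs_per_patient": list(ecgs_per_patient)
        if not isinstance(ecgs_per_patient, int)
        else ecgs_per_patient,
        "labs_per_patient": list(labs_per_patient)
        if not isinstance(labs_per_patient, int)
        else labs_per_patient,
        "age_variance_slope": age_variance_slope,
        "effect": asdict(effect),
        "noise": asdict(noise),
        "fs": fs,
        "duration": duration,
        "target_noise_sd": target_noise_sd,
        "target_noise_slope": target_noise_slope,
        "encounter_offset_minutes": encounter_offset_minutes,
        "revisit_prob": revisit_prob,
        "quality_jitter": quality_jitter,
    }
    return Cohort(patients, ecgs, labs, provenance={"config": config, "seed": seed})
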