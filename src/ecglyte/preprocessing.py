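"""ECG preprocessing, ECG↔lab linking, target assignment and patient-level splits.

The preprocessing chain mirrors standard clinical-ECG practice: resample to a
common rate, remove baseline drift with a zero-phase high-pass, remove mains
interference with a zero-phase notch, and zero-pad to a fixed length so every
trace presents the model the same ``leads × samples`` shape.

Dataset construction follows the emergency-department study design: an ECG
enters the dataset iff at least one lab value of the analyte lies within
±60 min of its acquisition (a closed interval on both ends); its target is the
median of all in-window lab values of that patient, with an even count
resolved as the mean of the two central values. Splits are at the patient
level — a temporal test set of patients admitted on/after a cutoff date, and a
random test set among pre-cutoff patients — and post-cutoff ECGs of
development/random-test patients are removed to avoid leakage into the
temporal evaluation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from fractions import Fraction

import numpy as np
from scipy import signal

from .records import (
    ECGRecord,
    LabMeasurement,
    PatientRecord,
    INDEPENDENT_LEADS,
    TWELVE_LEADS,
    LeadMismatchError,
)

__all__ = [
    "ArrayDataset",
    "LinkedExample",
    "DatasetSplits",
    "NormalizationParams",
    "TraceTooLongError",
    "TemporalSplitEmptyError",
    "preprocess_trace",
    "reduce_leads",
    "link_ecg_lab",
    "select_eval_ecgs",
    "split_patients",
    "fit_normalizer",
    "assemble_datasets",
]


class TraceTooLongError(ValueError):
    """Raised when a resampled trace exceeds the fixed model length."""


class TemporalSplitEmptyError(ValueError):
    """Raised when no patient is admitted on/after the temporal cutoff."""


@dataclass(frozen=True)
class LinkedExample:
    """One ECG with its assigned continuous target."""

    ecg_id: str
    patient_id: str
    target: float
    n_labs_in_window: int

    def __post_init__(self) -> None:
        if self.n_labs_in_window < 1:
            raise ValueError("a linked example needs >= 1 lab in window")


@dataclass
class DatasetSplits:
    """Patient-level partition into train/val and the two test sets.

    The sets hold ``ecg_id``s; ``patient_partition`` maps every assigned
    patient to its partition name.
    """

    train: set = field(default_factory=set)
    val: set = field(default_factory=set)
    random_test: set = field(default_factory=set)
    temporal_test: set = field(default_factory=set)
    cutoff_date: date = date(2017, 1, 1)
    fractions: tuple = (0.70, 0.10, 0.20)
    patient_partition: dict = field(default_factory=dict)
    seed: int = 0
    n_removed_post_cutoff: int = 0

    def to_json_dict(self) -> dict:
        return {
            "cutoff_date": self.cutoff_date.isoformat(),
            "fractions": list(self.fractions),
            "seed": self.seed,
            "patient_partition": self.patient_partition,
            "n_removed_post_cutoff": self.n_removed_post_cutoff,
            **{
                k: sorted(getattr(self, k))
                for k in ("train", "val", "random_test", "temporal_test")
            },
        }


@dataclass(frozen=True)
class NormalizationParams:
    """z-score parameters fitted on training targets only (population sd)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")

    def apply(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.mean) / self.sd

    def invert(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def fit_normalizer(train_targets) -> NormalizationParams:
    """Fit z-score parameters (population-sd convention) on training targets."""
    y = np.asarray(train_targets, dtype=float)
    if y.size == 0:
        raise ValueError("no training targets")
    sd = float(y.std())
    if sd == 0:
        raise ValueError("degenerate (constant) training targets: sd is zero")
    return NormalizationParams(float(y.mean()), sd)


# ----------------------------------------------------------------------------
# Trace preprocessing
# ----------------------------------------------------------------------------

def preprocess_trace(
    record: ECGRecord,
    target_fs: float = 400.0,
    target_len: int = 4096,
    highpass_cutoff: float = 0.5,
    notch_freq: float = 50.0,
    notch_q: float = 10.0,
) -> ECGRecord:
    """Resample, filter and zero-pad one trace to ``target_len`` samples.

    Steps, in order: polyphase rational resampling to ``target_fs``; order-4
    Butterworth high-pass (zero-phase, so no group delay); IIR notch at
    ``notch_freq`` (zero-phase); zero-padding at the end. Filtering precedes
    padding so the padded tail stays exactly zero. A resampled trace longer
    than ``target_len`` raises :class:`TraceTooLongError`.
    """
    x = np.asarray(record.trace, dtype=np.float64)
    if record.fs != target_fs:
        frac = Fraction(target_fs / record.fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    n = x.shape[1]
    if n > target_len:
        raise TraceTooLongError(
            f"{n} samples at {target_fs} Hz exceed target length {target_len}"
        )

    nyq = target_fs / 2.0
    sos = signal.butter(4, highpass_cutoff / nyq, btype="highpass", output="sos")
    # even-reflection padding a few filter time-constants long keeps the
    # zero-phase edge transients out of the retained trace
    x = signal.sosfiltfilt(
        sos, x, axis=1, padtype="even",
        padlen=min(n - 1, int(3 * target_fs / highpass_cutoff)),
    )
    if 0 < notch_freq < nyq:
        b, a = signal.iirnotch(notch_freq, notch_q, fs=target_fs)
        padlen = min(n - 1, int(3 * target_fs * notch_q / (np.pi * notch_freq)))
        x = signal.filtfilt(b, a, x, axis=1, padtype="even", padlen=padlen)

    if n < target_len:
        x = np.pad(x, ((0, 0), (0, target_len - n)))
    from dataclasses import replace

    return replace(record, fs=target_fs, trace=x.astype(np.float32))


def reduce_leads(record: ECGRecord) -> ECGRecord:
    """Keep the 8 independent leads (I, II, V1–V6) in the documented order.

    Accepts a 12-lead trace in any lead order, or an already-8-lead trace
    (identity up to reordering).
    """
    labels = record.lead_labels
    if set(labels) == set(INDEPENDENT_LEADS):
        wanted = INDEPENDENT_LEADS
    elif set(labels) == set(TWELVE_LEADS):
        wanted = INDEPENDENT_LEADS
    else:
        raise LeadMismatchError(f"cannot reduce lead set {labels}")
    idx = [labels.index(name) for name in wanted]
    from dataclasses import replace

    return replace(record, trace=record.trace[idx], lead_labels=wanted)


# ----------------------------------------------------------------------------
# Linking and target assignment
# ----------------------------------------------------------------------------

def link_ecg_lab(
    ecgs: list[ECGRecord],
    labs: list[LabMeasurement],
    window_minutes: float = 60.0,
) -> list[LinkedExample]:
    """Assign each ECG the median of its patient's labs within ±window.

    The window is a closed interval: a lab exactly at +60 min is included.
    ECGs with no in-window lab are silently dropped (callers can compare
    lengths to report the count).
    """
    analytes = {l.analyte for l in labs}
    if len(analytes) > 1:
        raise ValueError(f"labs mix analytes {sorted(analytes)}")
    by_patient: dict[str, list[LabMeasurement]] = {}
    for lab in labs:
        by_patient.setdefault(lab.patient_id, []).append(lab)

    window = timedelta(minutes=window_minutes)
    out: list[LinkedExample] = []
    for ecg in ecgs:
        values = [
            lab.value
            for lab in by_patient.get(ecg.patient_id, ())
            if abs(lab.time - ecg.acquisition_time) <= window
        ]
        if values:
            out.append(
                LinkedExample(
                    ecg.ecg_id,
                    ecg.patient_id,
                    float(np.median(values)),
                    len(values),
                )
            )
    return out


def select_eval_ecgs(
    linked: list[LinkedExample],
    ecgs: list[ECGRecord],
    splits: DatasetSplits,
) -> list[LinkedExample]:
    """Keep only each patient's earliest ECG in val and the two test sets.

    Training keeps all ECGs (multiple ECGs per patient act as data
    augmentation there). Linked examples whose ECG is in no partition are
    dropped.
    """
    times = {e.ecg_id: e.acquisition_time for e in ecgs}
    eval_sets = (splits.val, splits.random_test, splits.temporal_test)
    earliest: dict[tuple[int, str], str] = {}
    for ex in linked:
        for si, ecg_set in enumerate(eval_sets):
            if ex.ecg_id in ecg_set:
                key = (si, ex.patient_id)
                if key not in earliest or times[ex.ecg_id] < times[earliest[key]]:
                    earliest[key] = ex.ecg_id
    keep = set(earliest.values())
    out = []
    for ex in linked:
        if ex.ecg_id in splits.train or ex.ecg_id in keep:
            out.append(ex)
    return out


def split_patients(
    patients: list[PatientRecord],
    ecgs: list[ECGRecord],
    cutoff_date: date = date(2017, 1, 1),
    fractions: tuple = (0.70, 0.10, 0.20),
    val_fraction_of_dev: float = 0.10,
    seed: int = 0,
) -> DatasetSplits:
    """Patient-level 70/10/20 split with a temporal test set.

    The temporal test set takes patients with ``admission_date >= cutoff``
    (randomly subsampled to the temporal fraction when more are available).
    Remaining patients are randomly partitioned between development
    (train+val, split ``1 - val_fraction_of_dev`` / ``val_fraction_of_dev``
    by patient) and the random test set, in the ratio of the dev and random
    fractions. ECGs of dev/random-test patients acquired on/after the cutoff
    are removed entirely (leakage into the temporal period).
    """
    dev_frac, temporal_frac, random_frac = fractions
    rng = np.random.default_rng(seed)
    post = [p.patient_id for p in patients if p.admission_date >= cutoff_date]
    if not post:
        raise TemporalSplitEmptyError(f"no patients admitted on/after {cutoff_date}")
    n_temporal = min(len(post), int(round(temporal_frac * len(patients))))
    post = sorted(post)
    rng.shuffle(post)
    temporal_patients = set(post[:n_temporal])

    rest = sorted(p.patient_id for p in patients if p.patient_id not in temporal_patients)
    rng.shuffle(rest)
    n_dev = int(round(len(rest) * dev_frac / (dev_frac + random_frac)))
    dev_patients, random_patients = rest[:n_dev], rest[n_dev:]
    n_val = int(round(len(dev_patients) * val_fraction_of_dev))
    val_patients = set(dev_patients[:n_val])
    train_patients = set(dev_patients[n_val:])

    partition = {pid: "temporal_test" for pid in temporal_patients}
    partition.update({pid: "random_test" for pid in random_patients})
    partition.update({pid: "val" for pid in val_patients})
    partition.update({pid: "train" for pid in train_patients})

    splits = DatasetSplits(
        cutoff_date=cutoff_date,
        fractions=tuple(fractions),
        patient_partition=partition,
        seed=seed,
    )
    cutoff_dt = cutoff_date
    removed = 0
    for ecg in ecgs:
        part = partition.get(ecg.patient_id)
        if part is None:
            continue
        if part != "temporal_test" and ecg.acquisition_time.date() >= cutoff_dt:
            removed += 1  # post-cutoff ECG of a non-temporal patient: leakage
            continue
        getattr(splits, part).add(ecg.ecg_id)
    splits.n_removed_post_cutoff = removed
    return splits


# ----------------------------------------------------------------------------
# End-to-end dataset assembly
# ----------------------------------------------------------------------------

@dataclass
class ArrayDataset:
    """Model-ready arrays for one partition.

    ``X`` is ``(n, leads, samples)`` float32; ``y`` is the continuous target
    in analyte units. Ages and sexes are carried along for stratified
    evaluation.
    """

    X: np.ndarray
    y: np.ndarray
    ecg_ids: np.ndarray
    patient_ids: np.ndarray
    ages: np.ndarray
    sexes: np.ndarray

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx) -> "ArrayDataset":
        return ArrayDataset(
            self.X[idx], self.y[idx], self.ecg_ids[idx],
            self.patient_ids[idx], self.ages[idx], self.sexes[idx],
        )


def assemble_datasets(
    cohort,
    target_fs: float = 400.0,
    target_len: int = 4096,
    highpass_cutoff: float = 0.5,
    notch_freq: float = 50.0,
    window_minutes: float = 60.0,
    cutoff_date: date = date(2017, 1, 1),
    fractions: tuple = (0.70, 0.10, 0.20),
    val_fraction_of_dev: float = 0.10,
    seed: int = 0,
) -> dict:
    """Cohort → preprocessed, linked, split, eval-filtered array datasets.

    Returns a dict with keys ``train``, ``val``, ``random_test``,
    ``temporal_test`` (each an :class:`ArrayDataset`), plus ``splits``
    (:class:`DatasetSplits`) and ``n_unlinked`` (ECGs dropped for lacking an
    in-window lab).
    """
    processed = [
        preprocess_trace(
            reduce_leads(e) if set(e.lead_labels) == set(TWELVE_LEADS) else e,
            target_fs=target_fs,
            target_len=target_len,
            highpass_cutoff=highpass_cutoff,
            notch_freq=notch_freq,
        )
        for e in cohort.ecgs
    ]
    linked = link_ecg_lab(processed, cohort.labs, window_minutes=window_minutes)
    n_unlinked = len(processed) - len(linked)
    splits = split_patients(
        cohort.patients,
        processed,
        cutoff_date=cutoff_date,
        fractions=fractions,
        val_fraction_of_dev=val_fraction_of_dev,
        seed=seed,
    )
    linked = select_eval_ecgs(linked, processed, splits)

    traces = {e.ecg_id: e.trace for e in processed}
    demo = {p.patient_id: (p.age, p.sex) for p in cohort.patients}
    out: dict = {"splits": splits, "n_unlinked": n_unlinked}
    for part in ("train", "val", "random_test", "temporal_test"):
        ecg_set = getattr(splits, part)
        rows = [ex for ex in linked if ex.ecg_id in ecg_set]
        rows.sort(key=lambda ex: ex.ecg_id)
        out[part] = ArrayDataset(
            X=np.stack([traces[ex.ecg_id] for ex in rows])
            if rows
            else np.zeros((0, 8, target_len), dtype=np.float32),
            y=np.array([ex.target for ex in rows], dtype=float),
            ecg_ids=np.array([ex.ecg_id for ex in rows]),
            patient_ids=np.array([ex.patient_id for ex in rows]),
            ages=np.array([demo[ex.patient_id][0] for ex in rows], dtype=float),
            sexes=np.array([demo[ex.patient_id][1] for ex in rows]),
        )
    return out
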