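"""Core record types shared across the pipeline.

Concentrations are in the analyte's clinical unit (mmol/l for potassium,
calcium and sodium; µmol/l for creatinine). Trace amplitudes are in
millivolt, times are timezone-naive :class:`datetime.datetime`.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np

#: The 8 independent leads of the standard 12-lead ECG, in the fixed
#: order used throughout the package.
INDEPENDENT_LEADS: tuple[str, ...] = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: The four augmented/derived leads, linear combinations of I and II.
DERIVED_LEADS: tuple[str, ...] = ("III", "aVR", "aVL", "aVF")

TWELVE_LEADS: tuple[str, ...] = INDEPENDENT_LEADS + DERIVED_LEADS


class LeadMismatchError(ValueError):
    """Raised when a trace does not carry the expected set of leads."""


@dataclass
class ECGRecord:
    """One multi-lead ECG trace.

    Attributes
    ----------
    trace:
        Array of shape ``(n_leads, n_samples)``, millivolt.
    lead_labels:
        Ordered lead names; length must equal ``trace.shape[0]``.
    """

    ecg_id: str
    patient_id: str
    acquisition_time: datetime
    fs: float
    trace: np.ndarray
    lead_labels: tuple[str, ...] = INDEPENDENT_LEADS

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace)
        if self.trace.ndim != 2:
            raise ValueError("trace must be 2-D (leads x samples)")
        if self.trace.shape[1] < 1:
            raise ValueError("trace must have at least one sample")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.lead_labels = tuple(self.lead_labels)
        if len(self.lead_labels) != self.trace.shape[0]:
            raise LeadMismatchError(
                f"{len(self.lead_labels)} lead labels for a "
                f"{self.trace.shape[0]}-lead trace"
            )

    @property
    def n_samples(self) -> int:
        return self.trace.shape[1]


@dataclass
class LabMeasurement:
    """One blood-test result."""

    lab_id: str
    patient_id: str
    analyte: str
    value: float
    unit: str
    time: datetime

    def __post_init__(self) -> None:
        if not np.isfinite(self.value):
            raise ValueError("lab value must be finite")


@dataclass
class PatientRecord:
    """Demographics and admission date of one patient."""

    patient_id: str
    age: float
    sex: str  # "male" | "female"
    admission_date: date

    def __post_init__(self) -> None:
        if not 18 <= self.age <= 110:
            raise ValueError(f"age {self.age} outside [18, 110]")
        if self.sex not in ("male", "female"):
            raise ValueError(f"unknown sex {self.sex!r}")


@dataclass
class Cohort:
    """A simulated (or imported) study population.

    ``provenance`` records the generator configuration and seed so any
    cohort can be regenerated bit-identically.
    """

    patients: list[PatientRecord]
    ecgs: list[ECGRecord]
    labs: list[LabMeasurement]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {p.patient_id for p in self.patients}
        for e in self.ecgs:
            if e.patient_id not in ids:
                raise ValueError(f"ECG {e.ecg_id} references unknown patient")
        for lab in self.labs:
            if lab.patient_id not in ids:
                raise ValueError(f"lab {lab.lab_id} references unknown patient")

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_ecgs(self) -> int:
        return len(self.ecgs)

    @property
    def n_labs(self) -> int:
        return len(self.labs)
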