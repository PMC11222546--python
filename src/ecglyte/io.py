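"""Cohort container: one directory holding traces (HDF5), metadata (CSV) and provenance (JSON).

Layout::

    <dir>/
      traces.h5        # dataset "traces": n_ecgs x leads x samples, float32, chunked
                       # dataset "fs": per-trace sampling rate
      ecgs.csv         # ecg_id, patient_id, acquisition_time (ISO-8601), fs
      labs.csv         # lab_id, patient_id, analyte, value, unit, time
      patients.csv     # patient_id, age, sex, admission_date
      provenance.json  # generator config + seed + schema_version

The round trip is lossless: traces are stored and regenerated as float32
bit-exactly, all metadata fields are preserved.
"""
from __future__ import annotations

import json
from datetime import date, datetime
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .records import Cohort, ECGRecord, LabMeasurement, PatientRecord

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised on schema-version mismatch or a malformed container."""


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort to a container directory (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    if cohort.ecgs:
        lengths = {e.trace.shape for e in cohort.ecgs}
        if len(lengths) != 1:
            raise FormatError("all traces in a cohort must share one shape")
        traces = np.stack([e.trace for e in cohort.ecgs]).astype(np.float32)
        lead_labels = cohort.ecgs[0].lead_labels
    else:
        traces = np.zeros((0, 0, 0), dtype=np.float32)
        lead_labels = ()
    with h5py.File(path / "traces.h5", "w") as f:
        chunks = (1,) + traces.shape[1:] if traces.shape[0] else None
        f.create_dataset("traces", data=traces, chunks=chunks)
        f.create_dataset("fs", data=np.array([e.fs for e in cohort.ecgs]))
        f.attrs["lead_labels"] = list(lead_labels)

    pd.DataFrame(
        {
            "ecg_id": [e.ecg_id for e in cohort.ecgs],
            "patient_id": [e.patient_id for e in cohort.ecgs],
            "acquisition_time": [e.acquisition_time.isoformat() for e in cohort.ecgs],
            "fs": [e.fs for e in cohort.ecgs],
        }
    ).to_csv(path / "ecgs.csv", index=False)
    pd.DataFrame(
        {
            "lab_id": [l.lab_id for l in cohort.labs],
            "patient_id": [l.patient_id for l in cohort.labs],
            "analyte": [l.analyte for l in cohort.labs],
            "value": [repr(l.value) for l in cohort.labs],  # repr: round-trip exact
            "unit": [l.unit for l in cohort.labs],
            "time": [l.time.isoformat() for l in cohort.labs],
        }
    ).to_csv(path / "labs.csv", index=False)
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.patients],
            "age": [repr(p.age) for p in cohort.patients],
            "sex": [p.sex for p in cohort.patients],
            "admission_date": [p.admission_date.isoformat() for p in cohort.patients],
        }
    ).to_csv(path / "patients.csv", index=False)

    with open(path / "provenance.json", "w") as f:
        json.dump(
            {"schema_version": SCHEMA_VERSION, **cohort.provenance}, f, indent=1
        )
    return path


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort container written by :func:`write_cohort`."""
    path = Path(path)
    try:
        with open(path / "provenance.json") as f:
            provenance = json.load(f)
    except FileNotFoundError as err:
        raise FormatError(f"{path} is not a cohort container") from err
    version = provenance.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise FormatError(
            f"schema version {version!r} != supported {SCHEMA_VERSION}"
        )

    with h5py.File(path / "traces.h5", "r") as f:
        traces = f["traces"][...]
        fs = f["fs"][...]
        lead_labels = tuple(f.attrs["lead_labels"])

    ecg_meta = pd.read_csv(path / "ecgs.csv", dtype={"ecg_id": str, "patient_id": str})
    lab_meta = pd.read_csv(
        path / "labs.csv", dtype={"lab_id": str, "patient_id": str, "value": str}
    )
    pat_meta = pd.read_csv(path / "patients.csv", dtype={"patient_id": str, "age": str})

    patients = [
        PatientRecord(
            r.patient_id, float(r.age), r.sex, date.fromisoformat(r.admission_date)
        )
        for r in pat_meta.itertuples()
    ]
    ecgs = [
        ECGRecord(
            r.ecg_id,
            r.patient_id,
            datetime.fromisoformat(r.acquisition_time),
            float(fs[i]),
            traces[i],
            lead_labels,
        )
        for i, r in enumerate(ecg_meta.itertuples())
    ]
    labs = [
        LabMeasurement(
            r.lab_id, r.patient_id, r.analyte, float(r.value), r.unit,
            datetime.fromisoformat(r.time),
        )
        for r in lab_meta.itertuples()
    ]
    return Cohort(patients, ecgs, labs, provenance=provenance)
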