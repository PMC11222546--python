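from datetime import date, datetime

import numpy as np
import pytest

from ecglyte.records import ECGRecord, LabMeasurement, PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def patient():
    return PatientRecord("P0", 60.0, "female", date(2013, 5, 1))


def make_ecg(ecg_id="E0", patient_id="P0", t=None, fs=400.0, trace=None, leads=None):
    """Small helper for hand-built ECG records."""
    if trace is None:
        trace = np.zeros((8, 100), dtype=np.float32)
    kwargs = {}
    if leads is not None:
        kwargs["lead_labels"] = leads
    return ECGRecord(ecg_id, patient_id, t or datetime(2013, 5, 1, 12, 0), fs, trace, **kwargs)


def make_lab(lab_id="L0", patient_id="P0", value=4.0, t=None, analyte="potassium"):
    return LabMeasurement(lab_id, patient_id, analyte, value, "mmol/l",
                          t or datetime(2013, 5, 1, 12, 0))
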