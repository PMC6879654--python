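import numpy as np
import pytest

from traumanet.cohort import PatientRecord
from traumanet.synthetic import AIS_REGIONS


def make_patient(
    pid,
    age=40.0,
    sex="male",
    iss=25,
    clock=600,
    mechanism="MVA",
    **kwargs,
):
    return PatientRecord(
        patient_id=pid,
        age=age,
        sex=sex,
        iss=iss,
        ais={r: 1 for r in AIS_REGIONS},
        injury_clock_time=clock,
        mechanism=mechanism,
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def patient_factory():
    return make_patient
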