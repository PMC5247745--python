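import pytest
from hypothesis import HealthCheck, settings

from mblater.records import PatientRecord

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: a patient with every score component absent
_BASELINE = dict(
    id="p0",
    age=40.0,
    sex="F",
    bmi=24.0,
    af_type="paroxysmal",
    af_history=2.0,
    bbb=False,
    lad=40.0,
    lad_index=20.0,
    lvef=60.0,
    egfr=90.0,
    egfr_bsa=90.0,
    chf=False,
    hypertension=False,
    diabetes=False,
    stroke_tia=False,
    vascular_disease=False,
    copd=False,
    smoker=False,
    metabolic_syndrome=False,
    eraf=False,
)


def make_record(**overrides) -> PatientRecord:
    return PatientRecord(**{**_BASELINE, **overrides})


@pytest.fixture
def record_factory():
    return make_record
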