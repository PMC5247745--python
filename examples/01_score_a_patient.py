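"""Score one patient with all seven risk scores.

A 68-year-old man with persistent AF, a 48 mm left atrium and an early
recurrence during the blanking period is at high risk of very late
recurrence: his MB-LATER total of 4 (out of 6) puts him well above the
>=2 cutoff, while the thromboembolic scores (CHADS2 etc.) barely react
because their components track stroke risk, not arrhythmia relapse.
"""

from mblater import PatientRecord, SCORERS

patient = PatientRecord(
    id="example-1",
    age=68, sex="M", bmi=29.5,
    af_type="persistent", af_history=9.0,
    bbb=False, lad=48.0, lad_index=23.5,
    lvef=55.0, egfr=72.0, egfr_bsa=66.0,
    chf=False, hypertension=True, diabetes=False, stroke_tia=False,
    vascular_disease=False, copd=False, smoker=False,
    metabolic_syndrome=True, eraf=True,
)

for name, scorer in SCORERS.items():
    result = scorer(patient)
    parts = ", ".join(f"{c}={p}" for c, p in result.components if p)
    print(f"{name:13s} {result.total}  ({parts or 'no components present'})")
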