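"""Clinical risk scores for AF recurrence after catheter ablation.

Seven integer-point scores: MB-LATER (very late recurrence, the score
this package is built around) and six comparators — APPLE, ALARMc,
BASE-AF2, CHADS2, CHA2DS2-VASc and HATCH.  Each scorer is a pure
function from a :class:`~mblater.records.PatientRecord` to a
:class:`ScoreResult`; point assignments are fixed (nothing is estimated
from data here).

Inequality strictness follows the published definitions literally:
LA >= 47 mm and LAD >= 43 mm are inclusive; age > 65, LAD index > 23,
BMI > 28, LAD > 40 and AF history > 6 years are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .records import AFType, PatientRecord, Sex, records_from_frame

SCORE_NAMES = [
    "MB-LATER",
    "APPLE",
    "ALARMc",
    "BASE-AF2",
    "CHADS2",
    "CHA2DS2-VASc",
    "HATCH",
]

#: Documented attainable range (min, max) of each score.
SCORE_RANGES = {
    "MB-LATER": (0, 6),
    "APPLE": (0, 5),
    "ALARMc": (0, 5),
    "BASE-AF2": (0, 6),
    "CHADS2": (0, 6),
    "CHA2DS2-VASc": (0, 9),
    "HATCH": (0, 7),
}


@dataclass(frozen=True)
class ScoreResult:
    """Total points of one score with the per-component breakdown."""

    score_name: str
    total: int
    components: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.total != sum(p for _, p in self.components):
            raise ValueError("total must equal the sum of component points")
        lo, hi = SCORE_RANGES[self.score_name]
        if not lo <= self.total <= hi:
            raise ValueError(
                f"{self.score_name} total {self.total} outside range [{lo}, {hi}]"
            )


def _result(name: str, components: list[tuple[str, int]]) -> ScoreResult:
    return ScoreResult(name, sum(p for _, p in components), tuple(components))


def _npaf(p: PatientRecord) -> bool:
    """Non-paroxysmal AF: persistent or long-standing persistent."""
    return p.af_type in (AFType.persistent, AFType.longstanding_persistent)


def mb_later(p: PatientRecord) -> ScoreResult:
    """MB-LATER: Male, BBB, LA >= 47 mm, Type of AF, ERAF (0-6 points).

    AF type is ordinal: 0 for paroxysmal, 1 for persistent, 2 for
    long-standing persistent; each other component scores 1 point.
    """
    af_points = {
        AFType.paroxysmal: 0,
        AFType.persistent: 1,
        AFType.longstanding_persistent: 2,
    }[p.af_type]
    return _result(
        "MB-LATER",
        [
            ("male", int(p.sex is Sex.male)),
            ("bbb", int(p.bbb)),
            ("la_ge_47mm", int(p.lad >= 47.0)),
            ("af_type", af_points),
            ("eraf", int(p.eraf)),
        ],
    )


def apple(p: PatientRecord) -> ScoreResult:
    """APPLE (0-5): age > 65, persistent AF, LAD >= 43, eGFR < 60, LVEF < 50.

    "Persistent" here includes long-standing persistent AF; eGFR is on
    the ml/min/1.73 m^2 scale.
    """
    return _result(
        "APPLE",
        [
            ("age_gt_65", int(p.age > 65.0)),
            ("persistent_af", int(_npaf(p))),
            ("lad_ge_43mm", int(p.lad >= 43.0)),
            ("lvef_lt_50", int(p.lvef < 50.0)),
            ("egfr_lt_60", int(p.egfr_bsa < 60.0)),
        ],
    )


def alarmc(p: PatientRecord) -> ScoreResult:
    """ALARMc (0-5): NPAF, LA enlargement, eGFR < 68, MetS, cardiomyopathy.

    LA enlargement is approximated by LAD index > 23 mm/m^2 and
    cardiomyopathy by LVEF < 50%; eGFR is on the ml/min scale.
    """
    return _result(
        "ALARMc",
        [
            ("npaf", int(_npaf(p))),
            ("lad_index_gt_23", int(p.lad_index > 23.0)),
            ("egfr_lt_68", int(p.egfr < 68.0)),
            ("metabolic_syndrome", int(p.metabolic_syndrome)),
            ("cardiomyopathy", int(p.lvef < 50.0)),
        ],
    )


def base_af2(p: PatientRecord) -> ScoreResult:
    """BASE-AF2 (0-6): BMI > 28, LAD > 40, smoking, ERAF, AF > 6 y, NPAF."""
    return _result(
        "BASE-AF2",
        [
            ("bmi_gt_28", int(p.bmi > 28.0)),
            ("lad_gt_40mm", int(p.lad > 40.0)),
            ("smoking", int(p.smoker)),
            ("eraf", int(p.eraf)),
            ("af_history_gt_6y", int(p.af_history > 6.0)),
            ("npaf", int(_npaf(p))),
        ],
    )


def chads2(p: PatientRecord) -> ScoreResult:
    """CHADS2 (0-6): CHF, hypertension, age >= 75, diabetes, stroke/TIA x2."""
    return _result(
        "CHADS2",
        [
            ("chf", int(p.chf)),
            ("hypertension", int(p.hypertension)),
            ("age_ge_75", int(p.age >= 75.0)),
            ("diabetes", int(p.diabetes)),
            ("stroke_tia", 2 * int(p.stroke_tia)),
        ],
    )


def cha2ds2_vasc(p: PatientRecord) -> ScoreResult:
    """CHA2DS2-VASc (0-9); age >= 75 scores 2 and supersedes age 65-74."""
    return _result(
        "CHA2DS2-VASc",
        [
            ("chf", int(p.chf)),
            ("hypertension", int(p.hypertension)),
            ("age_ge_75", 2 * int(p.age >= 75.0)),
            ("diabetes", int(p.diabetes)),
            ("stroke_tia", 2 * int(p.stroke_tia)),
            ("vascular_disease", int(p.vascular_disease)),
            ("age_65_74", int(65.0 <= p.age < 75.0)),
            ("female", int(p.sex is Sex.female)),
        ],
    )


def hatch(p: PatientRecord) -> ScoreResult:
    """HATCH (0-7): hypertension, age > 75, stroke/TIA x2, COPD, CHF x2."""
    return _result(
        "HATCH",
        [
            ("hypertension", int(p.hypertension)),
            ("age_gt_75", int(p.age > 75.0)),
            ("stroke_tia", 2 * int(p.stroke_tia)),
            ("copd", int(p.copd)),
            ("chf", 2 * int(p.chf)),
        ],
    )


SCORERS: dict[str, Callable[[PatientRecord], ScoreResult]] = {
    "MB-LATER": mb_later,
    "APPLE": apple,
    "ALARMc": alarmc,
    "BASE-AF2": base_af2,
    "CHADS2": chads2,
    "CHA2DS2-VASc": cha2ds2_vasc,
    "HATCH": hatch,
}


def mb_later_components(p: PatientRecord) -> dict[str, int]:
    """Indicator (or ordinal, for AF type) values of the five MB-LATER components."""
    return dict(mb_later(p).components)


def score_cohort(
    frame: pd.DataFrame, score_names: list[str] | None = None
) -> pd.DataFrame:
    """Score every patient of a cohort table with the requested systems.

    Returns a DataFrame indexed like ``frame`` with one integer column
    per score (column names are the score names).
    """
    names = list(SCORE_NAMES) if score_names is None else list(score_names)
    unknown = [n for n in names if n not in SCORERS]
    if unknown:
        raise KeyError(f"unknown score(s): {unknown}; known: {SCORE_NAMES}")
    records = records_from_frame(frame)
    data = {n: [SCORERS[n](r).total for r in records] for n in names}
    return pd.DataFrame(data, index=frame.index)
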