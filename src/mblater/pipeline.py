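"""End-to-end study orchestration.

Reproduces the derivation-and-evaluation procedure behind a clinical
recurrence score: simulate (or load) a landmark cohort, screen candidate
predictors with univariate Cox models (dichotomizing continuous
candidates at their Youden-optimal cutoff), assemble a point score from
the significant clinical variables, then evaluate all scoring systems
(AUC, cutoff metrics, reclassification and discrimination improvement
against the reference score, decision curves, Kaplan-Meier strata).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import evaluation as ev
from . import survival as sv
from .cohort import SimulationConfig, person_time_incidence, simulate_cohort
from .records import read_cohort, validate_cohort
from .scores import SCORE_NAMES, score_cohort

log = logging.getLogger("mblater")


@dataclass(frozen=True)
class CandidateVariable:
    """One candidate predictor for the univariate Cox screen.

    ``kind`` is ``binary``, ``continuous`` or ``af_type`` (the ordinal
    AF-type variable, screened as its non-paroxysmal indicator).
    ``clinical`` marks variables eligible for score assembly; the screen
    reports procedural variables too but never selects them.
    """

    name: str
    kind: str
    clinical: bool = True

    def values(self, frame: pd.DataFrame) -> np.ndarray:
        if self.name == "male":
            return (frame["sex"] == "M").to_numpy(dtype=float)
        if self.kind == "af_type":
            return (frame["af_type"] != "paroxysmal").to_numpy(dtype=float)
        col = _CANDIDATE_COLUMNS.get(self.name, self.name)
        return frame[col].to_numpy(dtype=float)


_CANDIDATE_COLUMNS = {
    "age": "age_years",
    "bmi": "bmi_kg_m2",
    "af_history": "af_history_years",
    "lad": "lad_mm",
    "lvef": "lvef_pct",
    "egfr": "egfr_ml_min",
}

#: Default candidate list: the clinical variables of the cohort schema.
DEFAULT_CANDIDATES = [
    CandidateVariable("age", "continuous"),
    CandidateVariable("male", "binary"),
    CandidateVariable("bmi", "continuous"),
    CandidateVariable("af_history", "continuous"),
    CandidateVariable("af_type", "af_type"),
    CandidateVariable("bbb", "binary"),
    CandidateVariable("lad", "continuous"),
    CandidateVariable("lvef", "continuous"),
    CandidateVariable("egfr", "continuous"),
    CandidateVariable("chf", "binary"),
    CandidateVariable("hypertension", "binary"),
    CandidateVariable("diabetes", "binary"),
    CandidateVariable("stroke_tia", "binary"),
    CandidateVariable("vascular_disease", "binary"),
    CandidateVariable("copd", "binary"),
    CandidateVariable("smoker", "binary"),
    CandidateVariable("metabolic_syndrome", "binary"),
    CandidateVariable("eraf", "binary"),
]


@dataclass
class ScreenedVariable:
    name: str
    kind: str
    clinical: bool
    hr: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    cutoff: float | None = None
    hr_dichotomized: float | None = None
    ci95_dichotomized: tuple[float, float] | None = None
    p_dichotomized: float | None = None
    selected: bool = False
    note: str = ""

    @property
    def selection_p(self) -> float | None:
        """The p-value the selection rule uses (dichotomized if available)."""
        return self.p_dichotomized if self.p_dichotomized is not None else self.p_value


@dataclass
class DerivationResult:
    """Outcome of the univariate screen and the assembled selection."""

    screened: list[ScreenedVariable]
    selected: list[str]
    cutoffs: dict[str, float]
    p_threshold: float


def _fit(values, times, events) -> sv.CoxFit | None:
    try:
        return sv.cox_univariate(values, times, events)
    except sv.DegenerateDataError:
        return None


def screen_candidates(
    cohort: pd.DataFrame,
    candidates: list[CandidateVariable] | None = None,
    p_threshold: float = 0.05,
) -> DerivationResult:
    """Univariate Cox screen over candidate predictors.

    Continuous candidates are additionally dichotomized at their
    Youden-optimal cutoff (score >= cutoff positive, against final event
    status) and re-screened; the selection rule then uses the
    dichotomized p-value.  Selected = clinical variables with selection
    p-value below ``p_threshold``.
    """
    candidates = DEFAULT_CANDIDATES if candidates is None else candidates
    if not candidates:
        raise ValueError("candidate list is empty")
    times = cohort["followup_months"].to_numpy(dtype=float)
    events = cohort["vlraf_event"].to_numpy(dtype=int)
    if events.sum() == 0:
        raise sv.DegenerateDataError("cohort has no events")

    screened: list[ScreenedVariable] = []
    for cand in candidates:
        row = ScreenedVariable(cand.name, cand.kind, cand.clinical)
        values = cand.values(cohort)
        fit = _fit(values, times, events)
        if fit is None:
            row.note = "degenerate (constant covariate)"
            screened.append(row)
            continue
        if fit.converged:
            row.hr, row.ci95, row.p_value = fit.hr, fit.ci95, fit.p_value
        else:
            row.note = "monotone likelihood (separation)"
        if cand.kind == "continuous":
            cut = ev.youden_cutoff(values, events)
            if not cut.anti_discriminating:
                row.cutoff = cut.threshold
                indicator = (values >= cut.threshold).astype(float)
                dfit = _fit(indicator, times, events)
                if dfit is not None and dfit.converged:
                    row.hr_dichotomized = dfit.hr
                    row.ci95_dichotomized = dfit.ci95
                    row.p_dichotomized = dfit.p_value
        p = row.selection_p
        row.selected = bool(cand.clinical and p is not None and p < p_threshold)
        screened.append(row)

    selected = [r.name for r in screened if r.selected]
    cutoffs = {r.name: r.cutoff for r in screened if r.selected and r.cutoff is not None}
    n_sig = sum(1 for r in screened if r.selection_p is not None and r.selection_p < p_threshold)
    log.info(
        "screened %d candidates: %d significant, %d selected (clinical only)",
        len(screened), n_sig, len(selected),
    )
    return DerivationResult(screened, selected, cutoffs, p_threshold)


@dataclass
class ScoreDefinition:
    """An assembled point score: component -> maximum points.

    Binary components score 1 point; the AF-type component is ordinal
    (0 paroxysmal / 1 persistent / 2 long-standing persistent, maximum
    2).  Continuous components carry the cutoff at which they fire.
    """

    components: dict[str, int]
    cutoffs: dict[str, float] = field(default_factory=dict)

    @property
    def max_points(self) -> int:
        return sum(self.components.values())


def assemble_score(result: DerivationResult) -> ScoreDefinition:
    """Turn the screen's selection into a point-score definition."""
    if not result.selected:
        raise ValueError("empty selection: no variables to assemble")
    components: dict[str, int] = {}
    for row in result.screened:
        if not row.selected:
            continue
        components[row.name] = 2 if row.kind == "af_type" else 1
    return ScoreDefinition(components, dict(result.cutoffs))


def apply_score_definition(frame: pd.DataFrame, definition: ScoreDefinition) -> pd.Series:
    """Compute the assembled score's total for every cohort row."""
    total = pd.Series(0, index=frame.index, dtype=int)
    for name, maxpts in definition.components.items():
        cand = next((c for c in DEFAULT_CANDIDATES if c.name == name), None)
        kind = cand.kind if cand else "binary"
        if kind == "af_type":
            total += frame["af_type"].map(
                {"paroxysmal": 0, "persistent": 1, "longstanding_persistent": 2}
            ).astype(int)
        elif kind == "continuous":
            cut = definition.cutoffs[name]
            values = CandidateVariable(name, "continuous").values(frame)
            total += (values >= cut).astype(int)
        else:
            values = CandidateVariable(name, "binary").values(frame)
            total += values.astype(int)
    return total


class StudyConfig(BaseModel):
    """Configuration for a full study run (simulate or load, then evaluate)."""

    cohort_csv: Optional[str] = None
    simulation: Optional[SimulationConfig] = None
    scores: list[str] = Field(default_factory=lambda: list(SCORE_NAMES))
    reference_score: str = "MB-LATER"
    p_threshold: float = 0.05
    dca_threshold_start: float = 0.05
    dca_threshold_stop: float = 0.50
    dca_threshold_step: float = 0.01

    @model_validator(mode="after")
    def _check(self) -> "StudyConfig":
        if (self.cohort_csv is None) == (self.simulation is None):
            raise ValueError("provide exactly one of cohort_csv or simulation")
        if self.reference_score not in self.scores:
            raise ValueError("reference score must be among the evaluated scores")
        return self

    @classmethod
    def from_json(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            return cls.model_validate(json.load(fh))


def _dca_thresholds(config: StudyConfig) -> np.ndarray:
    n = int(round((config.dca_threshold_stop - config.dca_threshold_start)
                  / config.dca_threshold_step)) + 1
    return np.round(config.dca_threshold_start
                    + config.dca_threshold_step * np.arange(n), 10)


def run_study(config: StudyConfig, output_dir: str | Path | None = None) -> dict:
    """Execute the full pipeline; returns a JSON-serializable report.

    With ``output_dir`` set, writes report.json plus CSV exports of the
    Kaplan-Meier strata, ROC points and decision curves.  The run is
    fully reproducible: the same config (and seed) yields a
    byte-identical report.
    """
    if config.cohort_csv is not None:
        cohort = read_cohort(config.cohort_csv)
        source = {"cohort_csv": config.cohort_csv}
    else:
        cohort = simulate_cohort(config.simulation)
        validate_cohort(cohort)
        source = {"simulated": True, "seed": config.simulation.seed,
                  "n_candidates": config.simulation.n_candidates}
    n = len(cohort)
    events = cohort["vlraf_event"].to_numpy(dtype=int)
    times = cohort["followup_months"].to_numpy(dtype=float)
    log.info("cohort: %d patients, %d events", n, int(events.sum()))

    report: dict = {
        "source": source,
        "n_patients": n,
        "n_events": int(events.sum()),
        "event_fraction_pct": round(100.0 * events.mean(), 1) if n else None,
    }
    frames: dict[str, pd.DataFrame] = {}

    totals = score_cohort(cohort, config.scores)
    thresholds = _dca_thresholds(config)

    # overall cumulative incidence at 2 and 3 years post ablation
    try:
        km_all = sv.kaplan_meier(times, events)
        report["cumulative_incidence_pct"] = {
            str(t): _ci_dict(sv.cumulative_incidence(km_all, float(t)))
            for t in (24, 36)
        }
        report["person_time_incidence_per_100py"] = round(
            person_time_incidence(cohort), 1
        )
    except (sv.DegenerateDataError, ValueError) as exc:
        report["cumulative_incidence_pct"] = {"error": str(exc)}

    per_score: dict = {}
    risks: dict[str, np.ndarray] = {}
    roc_rows, dca_frames = [], []
    for name in config.scores:
        s = totals[name].to_numpy(dtype=float)
        entry: dict = {}
        try:
            auc = ev.roc_auc(s, events)
            entry["auc"] = round(auc.auc, 3)
            entry["auc_ci95"] = [round(auc.ci95[0], 3), round(auc.ci95[1], 3)]
            cut = ev.youden_cutoff(s, events)
            entry["cutoff"] = cut.threshold
            cm = ev.confusion_metrics(ev.confusion_at_threshold(s, events, cut.threshold))
            entry["sensitivity_pct"] = cm.sensitivity
            entry["specificity_pct"] = cm.specificity
            entry["ppv_pct"] = cm.ppv
            entry["npv_pct"] = cm.npv
            mapping = ev.fit_risk_mapping(s, events)
            risks[name] = mapping.predict(s)
            entry["risk_mapping_separated"] = mapping.separated
            dc = ev.decision_curve(risks[name], events, thresholds)
            dcf = dc.to_frame()
            dcf.insert(0, "score", name)
            dca_frames.append(dcf)
            for thr in np.unique(s):
                pred = s >= thr
                roc_rows.append({
                    "score": name, "threshold": float(thr),
                    "sensitivity": float(pred[events == 1].mean()),
                    "specificity": float((~pred)[events == 0].mean()),
                })
        except (ev.SingleClassError, sv.DegenerateDataError, ValueError) as exc:
            entry["error"] = str(exc)
        per_score[name] = entry
    report["scores"] = per_score

    ref = config.reference_score
    comparisons: dict = {}
    for name in config.scores:
        if name == ref:
            continue
        if ref not in risks or name not in risks:
            comparisons[name] = {"error": "risk mapping unavailable"}
            continue
        nri_res = ev.nri(risks[ref], risks[name], events)
        idi_res = ev.idi(risks[ref], risks[name], events)
        comparisons[name] = {
            "nri_pct": round(nri_res.nri, 1),
            "nri_p": _round_p(nri_res.p_value),
            "idi": round(idi_res.idi, 3),
            "idi_p": _round_p(idi_res.p_value),
        }
    report["reference_score"] = ref
    report["comparisons_vs_reference"] = comparisons

    # Kaplan-Meier strata by reference-score cutoff, with log-rank
    ref_entry = per_score.get(ref, {})
    km_rows = []
    if "cutoff" in ref_entry:
        cutoff = ref_entry["cutoff"]
        s = totals[ref].to_numpy(dtype=float)
        lo_mask, hi_mask = s < cutoff, s >= cutoff
        strata = {}
        if lo_mask.any() and hi_mask.any():
            lr = sv.log_rank(times[lo_mask], events[lo_mask],
                             times[hi_mask], events[hi_mask])
            for label, mask in ((f"<{cutoff:g}", lo_mask), (f">={cutoff:g}", hi_mask)):
                curve = sv.kaplan_meier(times[mask], events[mask])
                cf = curve.to_frame()
                cf.insert(0, "stratum", label)
                km_rows.append(cf)
                strata[label] = {"n": int(mask.sum()),
                                 "events": int(events[mask].sum())}
            report["km_stratified"] = {
                "cutoff": cutoff,
                "strata": strata,
                "log_rank_chi2": round(lr.statistic, 3),
                "log_rank_p": _round_p(lr.p_value),
            }
        else:
            report["km_stratified"] = {"error": "one stratum is empty"}

    try:
        derivation = screen_candidates(cohort, p_threshold=config.p_threshold)
        definition = assemble_score(derivation)
        report["derivation"] = {
            "selected": derivation.selected,
            "cutoffs": {k: round(v, 3) for k, v in derivation.cutoffs.items()},
            "assembled_components": definition.components,
            "assembled_max_points": definition.max_points,
            "screened": [
                {
                    "name": r.name, "kind": r.kind, "clinical": r.clinical,
                    "hr": _round_opt(r.hr), "p": _round_p_opt(r.p_value),
                    "cutoff": _round_opt(r.cutoff),
                    "hr_dichotomized": _round_opt(r.hr_dichotomized),
                    "p_dichotomized": _round_p_opt(r.p_dichotomized),
                    "selected": r.selected, "note": r.note,
                }
                for r in derivation.screened
            ],
        }
    except (sv.DegenerateDataError, ValueError, ev.SingleClassError) as exc:
        report["derivation"] = {"error": str(exc)}

    report = _to_python(report)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        if km_rows:
            pd.concat(km_rows).to_csv(out / "km_curves.csv", index=False)
        if roc_rows:
            pd.DataFrame(roc_rows).to_csv(out / "roc_points.csv", index=False)
        if dca_frames:
            pd.concat(dca_frames).to_csv(out / "dca_curves.csv", index=False)
    return report


def _to_python(obj):
    """Recursively convert numpy scalars so the report is JSON-clean."""
    if isinstance(obj, dict):
        return {k: _to_python(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_python(v) for v in obj]
    if isinstance(obj, np.floating):
        return float(obj)
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj


def _ci_dict(ci) -> dict:
    return {
        "estimate": round(100.0 * ci.estimate, 1),
        "ci95": [round(100.0 * ci.ci95[0], 1), round(100.0 * ci.ci95[1], 1)],
        "extrapolated": ci.extrapolated,
    }


def _round_p(p: float) -> float:
    return round(p, 4)


def _round_opt(v) -> float | None:
    return None if v is None else round(v, 3)


def _round_p_opt(v) -> float | None:
    return None if v is None else round(v, 4)
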