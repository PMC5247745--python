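"""Discrimination, reclassification and clinical-utility metrics.

ROC AUC via the Mann-Whitney rank formulation with midrank tie handling
and a DeLong confidence interval; Youden-index cutoff selection;
confusion-matrix rates; a one-variable logistic calibration mapping
integer score points onto the probability scale; continuous (and
optionally categorical) net reclassification improvement; integrated
discrimination improvement; and decision-curve net benefit.

Cutoff semantics throughout: a patient is test-positive when
score >= threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


class SingleClassError(ValueError):
    """Both outcome classes are required but only one is present."""


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if y.min() == y.max():
        raise SingleClassError("both event and non-event labels are required")
    return y


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci95: tuple[float, float]
    se: float


def roc_auc(scores, labels) -> AUCResult:
    """AUC by midrank Mann-Whitney; 95% CI from DeLong's variance."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size

    # placement values: fraction of the other class below, ties count 1/2
    v10 = np.array([(neg < p).mean() + 0.5 * (neg == p).mean() for p in pos])
    v01 = np.array([(pos > q).mean() + 0.5 * (pos == q).mean() for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.975)
    ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    return AUCResult(auc, ci, se)


@dataclass(frozen=True)
class CutoffResult:
    """Youden-optimal threshold (positive when score >= threshold)."""

    threshold: float
    youden: float
    sensitivity: float
    specificity: float
    anti_discriminating: bool


def youden_cutoff(scores, labels) -> CutoffResult:
    """Threshold maximising sensitivity + specificity - 1.

    Ties in the Youden index are broken toward the lower threshold (the
    more sensitive rule).  A best index <= 0 flags the score as
    anti-discriminating at every threshold.
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    best = None
    for thr in np.unique(s):  # ascending, so ties keep the lowest
        pred = s >= thr
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    j, thr, sens, spec = best
    return CutoffResult(float(thr), j, sens, spec, anti_discriminating=j <= 0)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ConfusionMetrics:
    """Sensitivity/specificity/PPV/NPV, percent scale, one decimal.

    A rate whose denominator is zero is undefined and reported as None.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None


def _pct(num: int, den: int) -> float | None:
    return None if den == 0 else round(100.0 * num / den, 1)


def confusion_metrics(c: ConfusionCounts) -> ConfusionMetrics:
    return ConfusionMetrics(
        sensitivity=_pct(c.tp, c.tp + c.fn),
        specificity=_pct(c.tn, c.tn + c.fp),
        ppv=_pct(c.tp, c.tp + c.fp),
        npv=_pct(c.tn, c.tn + c.fn),
    )


def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    y = _check_binary(labels)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionCounts(
        tp=int((pred & (y == 1)).sum()),
        fp=int((pred & (y == 0)).sum()),
        fn=int((~pred & (y == 1)).sum()),
        tn=int((~pred & (y == 0)).sum()),
    )


@dataclass(frozen=True)
class RiskMapping:
    """Logistic calibration from score points to event probability.

    When the logistic fit separates, ``separated`` is True and the
    mapping falls back to per-stratum empirical event rates (clipped
    away from 0 and 1); ``intercept``/``slope`` are then None.
    """

    intercept: float | None
    slope: float | None
    separated: bool = False
    empirical: dict[float, float] = field(default_factory=dict)

    def predict(self, scores) -> np.ndarray:
        s = np.asarray(scores, dtype=float)
        if not self.separated:
            eta = self.intercept + self.slope * s
            return 1.0 / (1.0 + np.exp(-eta))
        lo = min(self.empirical)
        hi = max(self.empirical)
        out = np.empty(s.shape)
        for i, v in np.ndenumerate(s):
            key = min(max(v, lo), hi)
            # nearest known stratum for unseen score values
            nearest = min(self.empirical, key=lambda k: abs(k - key))
            out[i] = self.empirical[nearest]
        return out


_EPS = 1e-6


def fit_risk_mapping(scores, labels) -> RiskMapping:
    """Maximum-likelihood one-variable logistic fit of event on score."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)

    def _fallback() -> RiskMapping:
        emp = {
            float(v): float(np.clip(y[s == v].mean(), _EPS, 1 - _EPS))
            for v in np.unique(s)
        }
        return RiskMapping(None, None, separated=True, empirical=emp)

    if np.ptp(s) == 0:
        return _fallback()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, sm.add_constant(s)).fit(disp=0, maxiter=200)
        except Exception:
            return _fallback()
    intercept, slope = float(res.params[0]), float(res.params[1])
    if not res.mle_retvals.get("converged", False) or abs(slope) > 15:
        return _fallback()
    return RiskMapping(intercept, slope)


@dataclass(frozen=True)
class IDIResult:
    """Integrated discrimination improvement (difference of discrimination
    slopes) with a paired-difference z-test."""

    idi: float
    se: float
    p_value: float


def idi(new_risks, old_risks, labels) -> IDIResult:
    y = _check_binary(labels)
    new = np.asarray(new_risks, dtype=float)
    old = np.asarray(old_risks, dtype=float)
    if new.shape != old.shape or new.shape != y.shape:
        raise ValueError("risk vectors and labels must have equal length")
    if np.any((new <= 0) | (new >= 1) | (old <= 0) | (old >= 1)):
        raise ValueError("risks must lie strictly in (0, 1)")
    d = new - old
    de, dn = d[y == 1], d[y == 0]
    value = float(de.mean() - dn.mean())
    var = (de.var(ddof=1) / de.size if de.size > 1 else 0.0) + (
        dn.var(ddof=1) / dn.size if dn.size > 1 else 0.0
    )
    se = float(np.sqrt(var))
    p = float(2 * stats.norm.sf(abs(value) / se)) if se > 0 else (1.0 if value == 0 else 0.0)
    return IDIResult(value, se, p)


@dataclass(frozen=True)
class NRIResult:
    """Category-free net reclassification improvement, percent scale.

    ``nri`` = event component + non-event component; each component is
    a net proportion in [-100, 100]; the total lies in [-200, 200].
    """

    nri: float
    event_component: float
    nonevent_component: float
    se: float
    p_value: float


def nri(new_risks, old_risks, labels) -> NRIResult:
    """Continuous NRI: any upward (downward) risk movement counts; ties
    count to neither direction."""
    y = _check_binary(labels)
    new = np.asarray(new_risks, dtype=float)
    old = np.asarray(old_risks, dtype=float)
    if new.shape != old.shape or new.shape != y.shape:
        raise ValueError("risk vectors and labels must have equal length")
    up = new > old
    down = new < old
    ne, nn = int((y == 1).sum()), int((y == 0).sum())
    p_up_e = up[y == 1].mean()
    p_dn_e = down[y == 1].mean()
    p_up_n = up[y == 0].mean()
    p_dn_n = down[y == 0].mean()
    ev = p_up_e - p_dn_e
    nev = p_dn_n - p_up_n
    value = ev + nev
    var_e = (p_up_e + p_dn_e - ev**2) / ne
    var_n = (p_dn_n + p_up_n - nev**2) / nn
    se = float(np.sqrt(max(var_e + var_n, 0.0)))
    p = float(2 * stats.norm.sf(abs(value) / se)) if se > 0 else (1.0 if value == 0 else 0.0)
    return NRIResult(
        float(100.0 * value), float(100.0 * ev), float(100.0 * nev),
        float(100.0 * se), p
    )


def nri_categorical(new_risks, old_risks, labels, cutpoints) -> NRIResult:
    """Categorical NRI with user-supplied risk-category cut-points."""
    edges = np.asarray(sorted(cutpoints), dtype=float)
    new_cat = np.digitize(np.asarray(new_risks, dtype=float), edges)
    old_cat = np.digitize(np.asarray(old_risks, dtype=float), edges)
    return nri(new_cat, old_cat, labels)


@dataclass(frozen=True)
class DecisionCurve:
    """Net benefit per threshold probability, with reference strategies."""

    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "net_benefit": self.net_benefit,
                "treat_all": self.treat_all,
                "treat_none": self.treat_none,
            }
        )


def decision_curve(risks, labels, thresholds) -> DecisionCurve:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt), flagging risk >= pt."""
    y = _check_binary(labels)
    r = np.asarray(risks, dtype=float)
    pt = np.asarray(thresholds, dtype=float)
    if np.any((pt <= 0) | (pt >= 1)):
        raise ValueError("thresholds must lie strictly in (0, 1)")
    n = y.size
    prev = y.mean()
    nb = np.empty(pt.shape)
    for i, p in enumerate(pt):
        flag = r >= p
        tp = (flag & (y == 1)).sum() / n
        fp = (flag & (y == 0)).sum() / n
        nb[i] = tp - fp * p / (1 - p)
    treat_all = prev - (1 - prev) * pt / (1 - pt)
    treat_none = np.zeros_like(pt)
    return DecisionCurve(pt, nb, treat_all, treat_none)
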