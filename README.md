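# mblater

Clinical risk scores for **very late recurrence of atrial fibrillation
(VLRAF)** — any atrial tachyarrhythmia >30 s documented more than 12
months after catheter ablation, in patients who looked "cured" at one
year.  The package is built for biostatisticians and arrhythmia
researchers who want to compute, re-derive, or stress-test the
**MB-LATER** score and its comparators on their own cohorts or on
fully synthetic ones.

## What it implements

**Scores.**  MB-LATER (**M**ale, **B**undle branch block, **LA** ≥ 47 mm,
**T**ype of AF, **ER**AF) plus six comparators: APPLE, ALARMc, BASE-AF2,
CHADS₂, CHA₂DS₂-VASc and HATCH.  MB-LATER awards 1 point per binary
component and 0/1/2 for paroxysmal/persistent/long-standing persistent
AF, so totals run 0–6; a total ≥ 2 flags high recurrence risk.

**Synthetic cohorts.**  A seeded generator draws candidate patients
with realistic covariate marginals (63.9% male, 4.4% BBB, LA diameter
40.2 ± 5.2 mm, 18.8% early recurrence …), assigns each a latent
recurrence time from an exponential proportional-hazards model on the
five MB-LATER components (hazard ratios 3.37, 6.08, 4.27, 6.63, 3.00),
and applies the landmark selection flow: recurrences between the
3-month blanking period and the 12-month landmark exclude a patient;
survivors are censored uniformly at 13–48 months.  The baseline hazard
is calibrated so ~15% of the delivered cohort has a VLRAF.

**Survival statistics**, written from first principles: Kaplan–Meier
with Greenwood variance, cumulative incidence with normal-scale CIs,
the two-group log-rank test, and univariate Cox regression
(Newton–Raphson on the Efron partial likelihood, Wald inference,
separation detection).

**Score evaluation.**  ROC AUC (midrank Mann–Whitney, DeLong CI),
Youden-index cutoffs, confusion-matrix rates, a logistic risk mapping
from points to probabilities, category-free NRI and IDI with analytic
p-values, and decision-curve net benefit
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t).

**Pipeline.**  The derivation procedure end to end: univariate Cox
screen over clinical candidates (continuous variables dichotomized at
their Youden cutoff and re-screened), selection at p < 0.05, point
assembly, and a full evaluation report — also exposed as a thin CLI
(`mblater simulate|score|derive|evaluate|run-study`).

## Worked example

```python
from mblater import SimulationConfig, simulate_cohort, score_cohort, roc_auc

cohort = simulate_cohort(SimulationConfig(n_candidates=1500, seed=11))
y = cohort["vlraf_event"].to_numpy(int)
totals = score_cohort(cohort)
for name in totals:
    print(name, round(roc_auc(totals[name], y).auc, 3))
```

prints (seed 11):

```
MB-LATER 0.783
APPLE 0.637
ALARMc 0.627
BASE-AF2 0.677
CHADS2 0.517
CHA2DS2-VASc 0.461
HATCH 0.5
```

MB-LATER discriminates best because the cohort's recurrence hazard was
generated on its components; the recurrence-specific comparators
(APPLE, ALARMc, BASE-AF2) share some components and land mid-range,
while the thromboembolic scores hover near chance.  The `examples/`
directory walks through each capability — scoring a patient, simulating
a cohort, survival analysis, head-to-head evaluation with NRI/IDI and
decision curves, and re-deriving the score from scratch — each script
printing and explaining its numbers.

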