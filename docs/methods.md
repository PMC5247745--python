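# Methods

## Setting

After catheter ablation for atrial fibrillation, recurrences are
classified by when they occur: within the 3-month *blanking period*
(ERAF — not counted as treatment failure), between 3 and 12 months
(LRAF), or beyond 12 months (VLRAF, "very late").  A VLRAF risk score
is derived and evaluated on the *landmark population*: patients still
arrhythmia-free at 12 months.  Everything in this package — the
simulator, the survival machinery, the evaluation stack — operates on
that population.

## Scoring conventions

Seven fixed-point scores are implemented as pure functions of a
validated patient record.  Conventions that matter:

- Threshold strictness follows the published definitions literally:
  LA ≥ 47 mm and LAD ≥ 43 mm are inclusive; age > 65 (APPLE),
  LAD index > 23 mm/m², BMI > 28 kg/m², LAD > 40 mm and AF history
  > 6 years are strict.
- eGFR is carried on two scales as two independent fields —
  ml/min (ALARMc's threshold of 68) and ml/min/1.73 m² (APPLE's
  threshold of 60) — because the scores define their cutoffs in
  different units.  No conversion happens inside a scorer.
- The LA diameter index (LAD / body surface area) is likewise a stored
  field: it stands in for the normalized LA area that ALARMc originally
  used, and "cardiomyopathy" is operationalized as LVEF < 50%.
- APPLE's "persistent AF" component includes long-standing persistent
  AF; BASE-AF2 and ALARMc use the same non-paroxysmal grouping.
- Age boundaries for CHADS₂/CHA₂DS₂-VASc are ≥ 75 (with 65–74 scoring
  1 in CHA₂DS₂-VASc); HATCH uses > 75 as conventionally tabulated.
- Records are complete-case: a missing field is a hard rejection naming
  the field.  No imputation.

## The synthetic cohort generator

The generator's job is to make every downstream stage testable with a
known ground truth, at the study's own operating point.

**Covariates** are sampled independently by default: Bernoulli flags at
the study cohort's prevalences, truncated normals for continuous
measurements (age 56.9 ± 11.8 truncated to 18–75; LA diameter
40.2 ± 5.2 mm; LVEF 60.5 ± 8.1%; eGFR 81.8 ± 20.4 ml/min), AF type
multinomial 92/32/9 over paroxysmal/persistent/long-standing.  The
BSA-normalised eGFR has no published mean, so its parameters (72 ±
19.6) were set once so that ~27% fall below the APPLE threshold, the
comparator-component prevalence in the same cohort.  Body surface area
(used only to derive the LA index) is sampled by sex, 2.05 ± 0.15 m²
for men and 1.85 ± 0.13 m² for women.  An optional Gaussian-copula
correlation matrix over the documented covariate order supports
sensitivity analyses; identity (independence) is the default because no
correlation structure is published.

**Recurrence times** follow a proportional-hazards model with linear
predictor Σ βₖ·xₖ over the five MB-LATER component indicators, with
default βₖ = ln HRₖ from the published univariate fits (male 3.37,
BBB 6.08, LA ≥ 47 4.27, non-paroxysmal AF 6.63, ERAF 3.00).  The
default time-to-event law is exponential (constant hazard), consistent
with the steadily accruing cumulative incidence the study reports; a
Weibull shape parameter is available for sensitivity work.  Time runs
from the end of the blanking period.

ERAF is drawn as a Bernoulli(0.188) covariate that enters the hazard
directly, like the other four components.  (An alternative would be to
generate ERAF *from* short latent recurrence times; making it a genuine
hazard covariate was chosen because it makes the ERAF→VLRAF association
quantitative and parameter recovery well-defined.)

**Selection flow.**  Candidates whose latent recurrence falls in
(3, 12] months are excluded (LRAF).  Survivors receive administrative
censoring uniform on 13–48 months; observed follow-up is the earlier of
recurrence and censoring.  Every delivered event time therefore exceeds
12 months by construction.  Because exclusion targets early recurrence,
the delivered cohort's hazard-linked marginals (ERAF, non-paroxysmal
AF) sit *below* the candidate-level targets — the same attenuation a
real landmark cohort undergoes; prevalence targets are therefore
specified, and tested, at the candidate level.

**Baseline rate.**  The zero-score hazard (1.17 × 10⁻³ events/month)
was calibrated once by bisection on large simulations so the delivered
cohort's event fraction is ≈ 15%, the study's observed VLRAF rate, and
then frozen.  Under the exponential law the memoryless property makes
post-landmark hazard ratios immune to the selection step, so Cox fits
on the delivered cohort estimate the generating coefficients without
landmark bias.

**What the generator does not emulate:** correlations between
covariates (left atria are not larger in men, by default), procedural
covariates (fluoroscopy/RF time, lesion sets), non-proportional or
time-varying hazards, loss to follow-up that depends on risk, and
measurement error in echo/lab values.  Passing tests therefore
demonstrate internal statistical correctness at the study's operating
point, not external validity on any real cohort.

## Survival machinery

- **Kaplan–Meier** on the grid of all distinct observed times, with
  Greenwood variance; at tied times events precede censorings.
  Cumulative incidence is 1 − S(t) with a normal-scale CI from the
  Greenwood standard error, clipped to [0, 1]; queries beyond the last
  observed time return the last value flagged as extrapolated.
- **Log-rank** with the hypergeometric variance; a zero variance
  (no events, or one group exhausted before any event) yields statistic
  0 rather than an error.
- **Univariate Cox** maximizes the Efron-corrected partial likelihood
  by Newton's method with step-halving, capped at 50 iterations,
  convergence at |Δβ| < 10⁻⁹.  Efron (not Breslow) because follow-up is
  effectively month-granular, so tied event times are the norm.
  Inference is Wald (the mainstream package default).  A monotone
  likelihood — complete separation, e.g. all events in one arm — is
  detected (|β| escaping past 25 or a vanishing information) and
  reported as `converged=False` with the boundary direction, never as a
  finite estimate.  The score statistic at β = 0 is exposed; without
  ties it equals the log-rank statistic (checked in the tests).
- Time origin: all subjects enter at the 12-month landmark, so risk
  sets are identical whether times are expressed since ablation or
  since landmark; the package keeps the ablation clock throughout.

## Evaluation stack

- **AUC** by the midrank Mann–Whitney formulation (final event status
  as the label for every subject, censored or not — the fixed landmark
  makes event status the quantity the score predicts); CI by DeLong's
  placement variance.  Verified against an exhaustive pairwise oracle
  and, for the CI, against an independent reference implementation.
- **Cutoffs** maximize the Youden index with "score ≥ threshold"
  positive; ties break toward the lower (more sensitive) threshold; a
  best index ≤ 0 flags an anti-discriminating score.  Confusion rates
  are reported on the percent scale at one decimal; a zero-denominator
  rate is undefined (None), never 0.
- **Risk mapping.**  Integer scores enter NRI/IDI/decision curves
  through a one-variable logistic calibration (maximum likelihood via
  statsmodels).  Under separation the fit is flagged and the mapping
  falls back to clipped per-stratum empirical event rates.
- **NRI** is category-free (any upward/downward movement counts, ties
  to neither side), reported in percent with the standard asymptotic
  variance; printed improvement values in the 50–95% range only make
  sense on the continuous version's scale.  A categorical variant with
  user-supplied cut-points is provided but not default.  **IDI** is the
  difference in discrimination slopes with a paired z-test.
- **Decision curves** report NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) with
  treat-all and treat-none references, over thresholds 0.05–0.50 in
  steps of 0.01 by default (p_t = 1 is undefined and rejected).
- Reporting precision: three decimals for AUC and IDI, one decimal for
  percent scales.

## Derivation pipeline

The screen fits a univariate Cox model per candidate; continuous
candidates are additionally dichotomized at their Youden-optimal cutoff
and re-screened, and the selection rule uses the dichotomized p-value —
this mirrors how an LA-diameter cutoff near 47 mm arises from a
continuous variable that is itself borderline.  Selection keeps
clinical variables with p < 0.05; procedural variables can be screened
but never enter the score (explicit allow-list).  Assembly gives every
binary component 1 point and AF type 0/1/2.

Two consequences are worth stating plainly.  First, dichotomizing at a
data-driven cutoff and re-testing is multiple testing: the
false-selection rate for continuous candidates exceeds the nominal 5%,
so large simulated cohorts occasionally admit weak extras (age, AF
history) alongside the five generating components.  The type-I
calibration test therefore exercises the plain Cox path on binary
candidates, where the nominal level is the right reference.  Second,
hazard ratios are non-collapsible: with all five components active, a
*univariate* fit of one component is attenuated by the omitted others
even though they are independent, so parameter-recovery checks simulate
one component at a time (only that coefficient nonzero, baseline rate
4.2 × 10⁻³ to hold the event fraction near 15%), where the univariate
model is the generating model.

## Problem sizes

Simulation-backed checks use cohorts of ~5,000 patients over 20 seeds
for parameter recovery, 500 replicate cohorts of ~700 for type-I
calibration, 20 cohorts of ~900 for the AUC-ordering property, and
~30,000 patients for the event-fraction calibration check; exhaustive
oracles enumerate all instances up to 8 subjects (and sampled instances
up to 12).  These sizes were chosen so Monte-Carlo error is small
against each check's tolerance.

## Known limitations

- Synthetic cohorts cannot validate the score externally; they verify
  the machinery and reproduce the study's operating point by
  construction.
- The logistic risk mapping assumes a linear logit in score points;
  genuinely non-monotone score-risk relationships only survive through
  the separation fallback.
- NRI/IDI p-values are analytic, not bootstrap.
- No multivariable Cox, proportional-hazards diagnostics, or
  time-dependent (incident/dynamic) ROC: the derivation procedure being
  reproduced uses univariate screening and event-status ROC.
- The published per-100-patient-year incidence figure is not
  recoverable from the published summary numbers under any standard
  person-time definition; the simulator reports person-time incidence
  but no calibration targets it.
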