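"""Re-derive the score from scratch on a simulated cohort.

Runs the full derivation procedure: univariate Cox screen over the
clinical candidates (continuous ones dichotomized at their
Youden-optimal cutoff and re-screened), selection at p < 0.05, and
point assembly (1 point per binary component, 0/1/2 for AF type).
On a large cohort generated under the five-component hazard, the five
generating components come out selected with the LA diameter cut near
47 mm.  Expect the Youden re-screen to occasionally pull in additional
weak continuous variables (age, AF history): dichotomizing at a
data-driven cutoff and re-testing inflates the false-selection rate —
the price of this derivation style, visible here by construction
because the generator owns the truth.
"""

from mblater import SimulationConfig, assemble_score, screen_candidates, simulate_cohort

cohort = simulate_cohort(SimulationConfig(n_candidates=3500, seed=101))
result = screen_candidates(cohort, p_threshold=0.05)

print(f"{'candidate':18s} {'HR':>6s} {'p':>8s} {'cutoff':>7s} {'p(dich)':>8s} sel")
for row in result.screened:
    hr = f"{row.hr:.2f}" if row.hr is not None else "-"
    p = f"{row.p_value:.4f}" if row.p_value is not None else "-"
    cut = f"{row.cutoff:.1f}" if row.cutoff is not None else "-"
    pd_ = f"{row.p_dichotomized:.4f}" if row.p_dichotomized is not None else "-"
    print(f"{row.name:18s} {hr:>6s} {p:>8s} {cut:>7s} {pd_:>8s} "
          f"{'*' if row.selected else ''}")

definition = assemble_score(result)
print(f"\nassembled score: {definition.components}")
print(f"maximum points:  {definition.max_points}")
print(f"cutoffs:         { {k: round(v, 1) for k, v in definition.cutoffs.items()} }")
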