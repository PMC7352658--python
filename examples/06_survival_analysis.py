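"""Survival analysis on the treated, immunocompetent sub-cohort.

Filters the cohort to intact immune status + first-line chemotherapy,
fits per-sex Kaplan-Meier curves, screens variables at their
recursive-partitioning cutoffs, and fits a backward-eliminated Cox model.
"""

from pcnslkit import survival, synthetic

cohort = synthetic.generate_cohort(synthetic.default_cohort_config(seed=11))
sub = survival.filter_survival_cohort(cohort.dropna(subset=["os_months", "event"]))
print(f"survival cohort after filtering: n = {len(sub)} of {len(cohort)}")

for sex in ("female", "male"):
    grp = sub[sub["sex"] == sex]
    curve = survival.km_fit(grp["os_months"], grp["event"])
    med = f"{curve.median_os_months:.1f} months" if curve.median_defined else "not reached"
    print(f"median OS ({sex}): {med}")

variables = ["age", "ecog", "foxp3", "enhancing_cm3", "deep_pct"]
screen = survival.univariable_screen(sub.dropna(subset=variables), variables, alpha=0.1)
selected = sorted(screen[screen["selected"]]["variable"].unique())
print(f"variables with log-rank p < 0.1 in any stratum: {selected}")

cox = survival.cox_backward(sub.dropna(subset=selected), selected, retention_alpha=0.1)
print(f"eliminated (in order): {cox.eliminated}")
for term in cox.terms:
    print(f"  {term.variable:<14s} HR {term.hr:5.2f} "
          f"(95% CI {term.ci95_low:.2f}-{term.ci95_high:.2f}), p = {term.p:.3f}")
# Retained hazard ratios > 1 mark adverse prognostic factors per unit (or
# per category for dichotomized terms); elimination stops when all p < 0.1.
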