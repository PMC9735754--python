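"""Logistic regression on the grouped study cohort, with separation surfaced.

The study design has zero cytology-negative cases with positive follow-up, so
the cytology coefficient's likelihood is monotone: its MLE is unbounded and
any finite number printed for it is a software stopping artifact.  What stays
identifiable is the DNA-ploidy odds ratio within cytology-positive cases —
the closed-form cross-product ratio — and the fitter reports exactly that.
"""
from ploidyscope import (
    conditional_odds_ratio,
    fit_logistic_firth,
    fit_logistic_grouped,
    grouped_cohort_from_frame,
)
from ploidyscope.synthetic import cohort_to_frame, generate_cohort, load_study_cohort

spec, _ = load_study_cohort()
cohort = grouped_cohort_from_frame(cohort_to_frame(generate_cohort(spec, seed=0)))

fit = fit_logistic_grouped(cohort, ["cytology", "icm"])
print("two-predictor maximum-likelihood fit:")
print(f"  separated coefficients: {fit.separation}")
print(f"  OR(icm) = {fit.odds_ratios['icm']:.1f}, 95% CI "
      f"({fit.wald_ci['icm'][0]:.2f}, {fit.wald_ci['icm'][1]:.2f})")

cond = conditional_odds_ratio(cohort, "icm", stratum={"cytology": 1})
print("\nclosed-form conditional OR (ploidy verdict, within cytology-positive):")
print(f"  cells {cond['cells']}")
print(f"  OR = {cond['or']:.1f}, 95% CI ({cond['ci'][0]:.2f}, {cond['ci'][1]:.2f})")

firth = fit_logistic_firth(cohort, ["cytology", "icm"])
print("\nFirth bias-reduced alternative (finite under separation, penalized):")
for name, or_ in firth.odds_ratios.items():
    print(f"  OR({name}) = {or_:.2f}")
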