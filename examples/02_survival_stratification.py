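"""Stratify patients on a signature score and quantify the survival gap.

Scores one simulated cohort with a planted 24-gene signature (mean of
z-scored expression), selects the best cutpoint by maximally selected
log-rank statistics (permutation p), compares it with the upper-tertile
split, and summarizes both groups with Kaplan-Meier medians, a log-rank
test, and a Cox hazard ratio.
"""

import pandas as pd

from stromasig import (
    CohortSpec,
    categorize_by_quantile,
    cox_fit,
    generate_cohort,
    km_estimate,
    logrank_test,
    maxstat_cutpoint,
    signature_score,
)

expr, surv, truth = generate_cohort(CohortSpec(n_samples=250, seed=42))
score = signature_score(expr, truth.module_genes)

cut = maxstat_cutpoint(score, surv, minprop=0.1, n_perm=1000, seed=7)
print(f"maxstat cutpoint: {cut.cutpoint:.3f} "
      f"(score quantile {float((score <= cut.cutpoint).mean()):.2f}), "
      f"max |z| = {cut.max_stat:.2f}, permutation p = {cut.p_perm:.4f}")

tert_labels, tert_thr = categorize_by_quantile(score, q=2 / 3)
print(f"upper-tertile threshold: {tert_thr:.3f} "
      f"({(tert_labels == 'high').mean():.0%} of samples high)")

for group in ("low", "high"):
    km = km_estimate(surv.subset(list(cut.groups.index[cut.groups == group])))
    lo, hi = km.median_ci
    print(f"  {group:4s}: median OS {km.median:.1f} months (95% CI {lo:.1f}-{hi:.1f})")

lr = logrank_test(surv, cut.groups)
print(f"log-rank: chi2 = {lr.chi2:.2f}, p = {lr.p:.2g}")

cox = cox_fit(surv, pd.DataFrame({"high": (cut.groups == "high").astype(float)}))
row = cox.summary.loc["high"]
print(f"Cox HR high vs low: {row.hazard_ratio:.2f} "
      f"(95% CI {row.ci_lower:.2f}-{row.ci_upper:.2f}, p = {row.p:.2g})")
# HR > 1 with a shorter median in the high group reproduces the design:
# survival worsens with the latent stromal factor the signature tracks.
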