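"""Survival evaluation: the Cox model roster with cross-validated
concordance.

Fits the incremental model roster (clinical baseline; + functional tumor
volume; + phenotype) on a synthetic cohort using the planted phenotype as
covariate, reporting 5-fold cross-validated Harrell c averaged over
replicates, the Kaplan-Meier log-rank split, and the likelihood-ratio test
for the phenotype term.
"""

from deltarad import (SimulationConfig, cv_cstatistic, fit_cox,
                      logrank_test, lr_test)
from deltarad.synthetic import simulate_clinical

cfg = SimulationConfig(n_subjects=200, seed=3)
clin, latent = simulate_clinical(cfg)
clin["ftv2"] = latent["vol_t2_cm3"]
clin["phenotype"] = (clin["true_phenotype"] == 2).astype(float)

stat, p = logrank_test(clin["rfs_years"], clin["event"], clin["phenotype"])
print(f"log-rank by phenotype: chi2 = {stat:.1f}, p = {p:.2e} "
      "(planted log-HR 1.5 separates the curves)\n")

roster = {
    "baseline (age, HR, HER2)": ["age", "hr_status", "her2_status"],
    "baseline + FTV2": ["age", "hr_status", "her2_status", "ftv2"],
    "baseline + FTV2 + phenotype": ["age", "hr_status", "her2_status",
                                    "ftv2", "phenotype"],
}
fits = {}
for name, covs in roster.items():
    cv = cv_cstatistic(clin, covs, folds=5, replicates=50, seed=1)
    fits[name] = fit_cox(clin, covs)
    lo, hi = cv.percentile_interval
    print(f"{name:32s} c = {cv.mean_c:.3f}  [{lo:.3f}, {hi:.3f}]")

stat, df, p = lr_test(fits["baseline + FTV2"],
                      fits["baseline + FTV2 + phenotype"])
print(f"\nlikelihood-ratio test for the phenotype term: "
      f"chi2({df}) = {stat:.1f}, p = {p:.2e}")
print("the concordance gain over the volume model is the value the "
      "phenotype adds beyond tumor size")
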