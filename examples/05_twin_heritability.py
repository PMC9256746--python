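"""Twin correlations and ACE variance decomposition of the ADHD trait.

MZ pairs share all additive genetic variance, DZ/sibling pairs half; the
gap between their correlations identifies heritability (a2), with shared
(c2) and unique (e2) environment completing the decomposition.
"""

from twinmorph import (CohortConfig, assess_fit, fit_ace, generate_cohort,
                       make_pairs, pair_correlation, ur_resample)

cohort = generate_cohort(CohortConfig(n_subjects=11502, n_mz_pairs=317,
                                      n_dz_pairs=1413, seed=7))
covariates = ["age_months", "site_id"]

mz = make_pairs(cohort, "MZ", "adhd_t", covariates, seed=1)
dz = make_pairs(cohort, "DZ", "adhd_t", covariates, seed=1)
r_mz = pair_correlation(mz)
r_dz = pair_correlation(dz)
ur = ur_resample(cohort, "adhd_t", covariates, n_rep=100, seed=1)
print(f"MZ pairs: n = {mz.n_pairs}, r = {r_mz.r:.3f} "
      f"[{r_mz.ci_low:.3f}, {r_mz.ci_high:.3f}]")
print(f"DZ pairs: n = {dz.n_pairs}, r = {r_dz.r:.3f} "
      f"[{r_dz.ci_low:.3f}, {r_dz.ci_high:.3f}]")
print(f"UR pairs (100 shuffles): mean r = {ur['mean_r']:.3f}")

fit = fit_ace(mz, dz)
print(f"ACE: a2 = {fit.a2:.2f} [{fit.ci_a2[0]:.2f}, {fit.ci_a2[1]:.2f}], "
      f"c2 = {fit.c2:.2f}, e2 = {fit.e2:.2f} -> {fit.classification}")
flags = assess_fit(fit)
print(f"fit: chi2/df = {fit.chi2_df:.2f}, RMSEA = {fit.rmsea:.3f}, "
      f"TLI = {fit.tli:.2f} -> good fit: {flags['good_fit']}")
# r_MZ roughly doubles r_DZ and the unrelated baseline sits near zero.  The
# ML decomposition agrees with the generating heritability (0.59) within its
# CI; Pearson correlations of the floored, right-skewed T score sit slightly
# below the latent twin correlations, which the fit indices absorb.
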