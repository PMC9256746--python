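# Methods

`twinmorph` reimplements, as a tested library, the statistical core of a
twin-informed voxel-based-morphometry (VBM) analysis of ADHD traits in a
large child cohort: covariate-adjusted trait statistics, voxelwise
trait–volume inference with family-wise-error (FWE) control, and ACE
variance decomposition of traits and their volumetric correlates. Because
the motivating cohort data are access-restricted, the package ships a
synthetic cohort generator that reproduces the cohort's structure and the
published summary statistics; every analysis stage is validated against
that generator, closed-form oracles, and simulation-based calibration.

## The ACE model and its estimator

A trait measured in monozygotic (MZ) and dizygotic/sibling (DZ) pairs is
decomposed into additive genetic (A), shared environmental (C) and unique
environmental (E) variance. With path variances v_A, v_C, v_E, the
within-pair covariance matrices are

    Cov_MZ = [[v, v_A + v_C], [v_A + v_C, v]]
    Cov_DZ = [[v, 0.5 v_A + v_C], [0.5 v_A + v_C, v]],   v = v_A + v_C + v_E

reflecting additive-genetic correlations of 1.0 (MZ) and 0.5 (DZ), a fully
shared C and an uncorrelated E. Traits enter residualized against
covariates over the full sample and standardized, with pair means fixed at
zero, so the likelihood is a zero-mean bivariate normal per group, fitted
from the per-group sufficient statistics (pair counts and 2×2 scatter
matrices). Reported components a², c², e² are the variance components
normalized to sum to one; 95% CIs are estimate ± 1.96·SE with SEs from the
observed information via the delta method.

**Unbounded components (default).** The optimizer is a multi-start
quasi-Newton (L-BFGS-B with analytic gradients; Falconer start plus four
seeded jitters, then a polish step) over (v_A, v_C, v_E) with v_E > 0 and
positive-definiteness enforced, but v_A and v_C *not* constrained to be
nonnegative. Truncating components at zero censors sampling noise
one-sidedly: when the true shared-environment share is zero — as for the
ADHD trait here — spurious positive ĉ² survives while negative draws are
clipped, and the heritability estimate inherits a downward bias of about
0.03 at the study's pair counts (317 MZ, 1,413 DZ). Leaving the components
unbounded is the standard remedy in the twin-modelling literature and makes
the estimator mean-unbiased (measured recovery bias below 0.012 for every
generating value used in the tests); slightly negative estimates are
reported as such. `bound_components=True` restores the classic
nonnegativity constraints. Classification of a² (< 0.30 low, 0.30–0.60
moderate, > 0.60 high) uses the estimate clipped to [0, 1].

**Fit indices.** The saturated reference model has, per zygosity group, a
free within-pair covariance and a common member variance (means fixed at
zero), i.e. 4 parameters against the ACE model's 3, giving χ² =
2(lnL_sat − lnL_ACE) on df = 1. The independence baseline (zero within-pair
covariance, one variance per group) yields the TLI; RMSEA =
√(max(χ²−df, 0)/(df·N_pairs)). Good fit is declared disjunctively at
χ²/df < 2, RMSEA < 0.06 or TLI > 0.95.

**Falconer oracle.** On exact population covariances the ML fit must equal
the closed form a² = 2(r_MZ − r_DZ), c² = r_MZ − a², to 1e-4; this is
asserted in the tests and the optimum is additionally required never to
fall below the likelihood at the Falconer starting point.

**Pair construction.** Covariates are removed by OLS residualization over
the full sample before pairing (equivalent to linear fixed effects inside
the model, but separable and testable); within-pair member order is
randomized once under a seed, matching a single-entry S1/S2 presentation.
Unrelated (UR) reference pairs are built by shuffling the sample, splitting
it in half and pairing index-wise, repeated 100 times; the mean correlation
and mean regression line over repetitions form the null baseline. True
siblings are not excluded from UR pairing; at cohort scale the effect is
negligible (≤ 2·n_pairs/n² probability mass per repetition).

**Group comparison of heritability.** Differences in a² between
independently fitted groups are tested as z = (a²₁ − a²₂)/√(SE₁² + SE₂²)
against a normal reference — an explicit construction choice, since only
the *existence* of such a test is given in the source analyses.

## Scalar association statistics

All adjusted comparisons are OLS constructions: the adjusted two-sample t
test is the t of a 0/1 group dummy with covariates; ANCOVA is the
nested-model F for the group factor; partial correlation is recovered from
the regression t as r = t/√(t² + df). Categorical covariates (site,
scanner, zygosity, race) enter as one-hot dummies, first level as
reference. The slope test between independent samples uses
t = (b₁ − b₂)/√(SE₁² + SE₂²) with df = n₁ + n₂ − 2(k+1); this SE-combination
variant is oracle-tested against direct evaluation but is a documented
choice, not a claim about any particular textbook variant. Effect sizes
follow d = 2t/√df (regression contexts) and d = t·√(1/n₁ + 1/n₂)
(two-sample contexts); the latter is algebraically the standardized mean
difference and both are verified against group-statistics definitions. The
sex-by-trait interaction model adds a family-level random intercept fitted
by maximum likelihood (statsmodels MixedLM); when the family variance
estimate collapses to zero the model degrades to OLS with a logged notice.
Multiple-comparison control is configurable (none | Bonferroni), with
α/m = 0.05/8 as the documented default for the eight ROI slope tests.

## Voxelwise inference

Maps are smoothed with a separable Gaussian kernel, σ = FWHM/(2√(2 ln 2))
per axis scaled by voxel size, reflective boundary (total intensity is
conserved; asserted to 1e-6). The voxelwise GLM computes, per masked voxel,
the adjusted regression t of the predictor with a df constant across
voxels; on a one-voxel grid it agrees with the scalar regression to 1e-10.

FWE control uses max-|t| permutation instead of Gaussian-random-field
theory: the predictor is residualized against the covariates
(Kennedy-style), permuted, and the (1−α)·(B+1) order statistic of the
permuted maximum |t| — with the observed statistic included in the null
set — is the critical value. This choice trades the random-field machinery
(resel and smoothness estimation, which belongs to the original software
stack rather than to the analysis itself) for a procedure whose error rate
is directly verifiable by simulation: over 200 amplitude-zero datasets on a
24³ grid the family-wise rejection rate at α = 0.05 is measured inside
[0.02, 0.09]. Permuting the residualized predictor is known to be slightly
liberal at very small n, which the calibration band accommodates. Only
voxel-level (peak) FWE is implemented; no cluster-extent p values, TFCE or
random-field theory.

Clusters are connected components of the significance mask per t sign
(default 18-connectivity, configurable 6/26), each reporting peak voxel,
peak t and size, sorted by size. Exclusive masking (A ∧ ¬B) and unweighted
ROI means complete the stage; joint ROIs are per-sex cluster unions and
sex-specific ROIs their exclusive masks.

## Image quality screen

Each subject's masked voxel vector is Pearson-correlated with every other
subject's; subjects whose mean correlation falls strictly below 0.70 are
flagged. The default mask keeps voxels with nonzero cross-subject
variance — whether the original screen used a mask is unknown, so this is a
package decision. Zero-variance subjects are recorded as unevaluable and
flagged rather than silently passed. The visual slice inspection that
accompanied the original screen is out of scope.

## The synthetic cohort generator

The generator emulates the study conditions: 11,502 children
(5,464 girls, ~47.5%), 317 MZ and 1,413 DZ/sibling pairs (634 and 2,826
subjects; DZ twins and same-age siblings pooled into one class), age
~N(119, 7.45²) months shared within pairs, 21 sites and 3 scanner models
assigned per family, per-subject TIV ~N(1400/1500 (F/M), 130²).

Traits are built in three layers:

1. **ACE latent.** A standardized latent with the exact twin covariance
   structure above (A shared 1.0/0.5 within MZ/DZ, C shared within pairs,
   E independent). Twin correlations of the latent converge to a² + c²
   (MZ) and 0.5a² + c² (DZ); asserted at 10,000 pairs to 0.02.
2. **Cross-trait structure and covariate channels.** A trait can target a
   covariate-adjusted partial correlation with an earlier trait per sex
   scope; the latent mixing weight is obtained by inverting the (affine)
   response of the realized observed-scale partial correlation, measured
   once with a fixed internal seed at n = 200,000. Confounding enters
   through a smooth age+TIV channel shared across traits (sign per trait,
   making adjusted and unadjusted correlations differ) and per-trait
   site/scanner offset channels; each trait devotes a configurable small
   variance share (default 5%, 20% for ROI volumes) to these channels. The
   composite latent is standardized empirically per sex, because convex
   marginal transforms amplify sampling noise in the latent SD into the
   observed moments.
3. **Marginal transform.** A rank-preserving quantile map onto the per-sex
   marginal: a plain (optionally clipped) normal, or floor-plus-gamma for
   the ADHD T score (score = 50 + gamma deviate, capped at 80 — the score
   range is reported inconsistently as 50–70 and 50–80 in the source; the
   cap of 80 is used). Parameters are solved by Gauss–Hermite
   moment-matching of the *bounded* distribution, so the realized mean and
   SD hit their per-sex targets (boys 53.61/5.98, girls 52.71/5.08 for the
   T score; 75.60/15.09 and 73.67/13.98 for 2-back accuracy) within 1% at
   n = 50,000. Tail rates above the clinical cutoffs are checked as a soft
   diagnostic only (the printed 7.5%/3.2% for boys at T ≥ 65/70 correspond
   to 6–7%/3.5% under the calibrated gamma; a two-moment family cannot pin
   the tail exactly and no third moment is published).

Quantile mapping preserves ranks but attenuates Pearson correlations of
strongly skewed marginals: observed-scale twin correlations of the T score
run a few hundredths below the latent ones. The acceptance-level ACE
recovery therefore simulates standardized pairs directly (as the
printed variance components describe the latent scale), while
observed-scale fits in the pipeline carry the attenuation as real data
would. Medication flags are assigned logistically on the T score with the
intercept solved for the target prevalence (stimulants 8.2%,
antidepressants 1.5%, other 0.2%), so medicated children show markedly
higher symptom scores.

Volume maps are abstract smooth fields, not anatomy: a TIV-scaled fixed
smooth template (the shared "anatomy" that drives inter-subject
correlations in the QC screen), subject-specific smooth Gaussian noise, and
planted spherical clusters whose amplitude multiplies the subject's
standardized trait value, optionally restricted to one sex. What passing
tests show is therefore that the *statistical machinery* behaves correctly
under a data-generating process with the published moments and dependence
structure — not that it would reproduce anatomical effect locations,
non-Gaussian artefacts, motion-related QC failures, site-specific scanner
physics, or item-level score construction, none of which are modelled.

## Problem sizes and numerical choices

- ACE recovery: 100 replicates of 317 MZ + 1,413 DZ pairs per generating
  value (≈ 7 s total); generator calibration checks use one 50,000-subject
  male cohort.
- FWE calibration: 200 null datasets, 30 subjects, 24³ grid, 250
  permutations (≈ 30 s). ANCOVA type-I: 1,000 simulations at n = 90. The
  mixed-model interaction type-I check uses 500 simulated datasets at
  n = 160 (the mixed-model fit dominates its runtime); its rate is
  asserted within 0.05 ± 0.02.
- The demonstration pipeline (2,000 subjects, 60 MZ/280 DZ pairs, 24³
  grid, 300 permutations) runs in well under a minute on one CPU; at these
  pair counts ACE intervals are wide and single-run estimates can sit at
  the admissible boundary — study-scale pair counts are needed for stable
  decompositions.
- Optimizer: L-BFGS-B, ftol 1e-15, gtol 1e-10, Hessian by central
  differences (step 1e-5 relative); permutation thresholds use the exact
  order-statistic convention; degenerate inputs (constant predictors,
  rank-deficient designs, empty masks, zero-variance traits) raise errors
  naming the offending quantity.

## Known limitations

- The UR construction may pair true relatives (negligible at scale, see
  above).
- SEs for components estimated near a constrained boundary (with
  `bound_components=True`) are delta-method approximations; the unbounded
  default avoids the issue.
- The generator's cross-trait calibration guarantees the *target* partial
  correlations; correlations among several traits all targeting the same
  source trait arise implicitly and are not independently controlled.
- Voxel "coordinates" are 0-based indices plus an affine-scaled mm
  position; no anatomical space is implied.
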