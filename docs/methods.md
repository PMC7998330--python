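# Methods

## The biometric model

A twin pair's adjusted phenotype vector y = (y1, y2) is modelled as
bivariate normal with a common mean and a covariance determined by the
variance components. With additive genetic variance a², shared
environment c² (or dominance d²), and unique environment e²:

- variance (both twins, both zygosities): V = a² + c² + d² + e²
- MZ covariance: a² + c² + d²
- DZ covariance: a²/2 + c² + d²/4

The 1/2 and 1/4 are the expected proportions of additive and dominance
genetic sharing in dizygotic pairs. C and D are never estimated jointly:
with twins reared together the ACDE model is not identified, so the model
space is ACE, ADE, AE, CE, E. E is never dropped because it absorbs
measurement error; during optimization e² is floored at 1e-6 of the total
variance.

Variances are constrained equal across twin order and zygosity groups, as
the model implies. Real cohorts show some MZ/DZ variance heterogeneity,
which is the main reason summary-statistic refits of published tables
agree with the original raw-data fits to about ±0.01–0.02 rather than
exactly.

## Likelihoods

Two equivalent fitting routes are provided.

**Summary-statistic ML.** Given per-zygosity 2×2 sample covariance (or
correlation) matrices S_g and pair counts n_g, the deviance is

    F = Σ_g n_g [ ln det Σ_g + tr(S_g Σ_g⁻¹) ]

with the 2π constants omitted; every model comparison uses differences,
so the convention cancels (asserted by a test). Groups are weighted by
n_g, the ML convention. `SummaryStats.from_pairs` computes S_g about the
group's double-entry mean with equal diagonals, so the statistics are
invariant to the arbitrary ordering of co-twins.

**Raw-data ML.** The full bivariate-normal deviance (2π included) over
all pairs, with a single common mean estimated alongside the components.
When the raw data's moments equal the summary moments the two routes give
the same estimates (verified to 1e-4).

## Estimation

Components are parameterized to be non-negative by construction. For
summary fits the standardized proportions are the free parameters and the
common variance V is profiled out in closed form
(V̂ = Σ n_g tr(S_g R_g⁻¹) / 2Σ n_g, where R_g is the unit-diagonal
correlation structure), reducing AE/CE to a one-dimensional and ACE/ADE
to a two-dimensional bounded problem. One-dimensional problems are solved
by bounded Brent to xatol 1e-12; two-dimensional ones by Nelder-Mead with
five starts (one moment-based, the rest drawn from a seeded stream), plus
exact one-dimensional solves of the two boundary profiles (either
non-E component at zero), since the MLE frequently sits on a boundary.
Raw-data fits optimize (mean, path coefficients) by multi-start
Nelder-Mead, squaring the paths to enforce non-negativity. Convergence is
reported honestly: a fit that exhausts its restarts is returned with
`converged = False` and excluded from model selection with a warning.

A useful check: when rMZ = 2·rDZ exactly, the AE stationary point is
â² = rMZ; the optimizer reproduces this to 1e-6. When the total variance
is *fixed*, the AE estimate always lies between min and max of
(rMZ, 2·rDZ); with V free the estimate can overshoot that bracket by a
few thousandths (confirmed against a brute-force 1e-6 grid scan), so the
corresponding invariant test carries a 5e-3 slack.

## Confidence intervals

Component CIs are likelihood-based: the 95% bound is the standardized
value at which the profile deviance — re-minimized over all other free
parameters — rises by the χ²(1) quantile 3.841 above its minimum, found
by bisection and clipped to [0, 1]. A component estimated on the zero
boundary yields a one-sided interval with low = 0 (logged). Calibration
at the study's own geometry (62/46 pairs, a² = 0.7) gives empirical
coverage inside [0.90, 0.99] over 200 replicates (tested).

Intrapair correlations use the ML common correlation of an exchangeable
bivariate normal (identical to the Pearson correlation of the
double-entered data, and to the one-way intraclass correlation). Their
default CI is the Fisher z-transform with SE 1/√(n−3); a
profile-likelihood alternative is available via `ci_method="profile"`.
Published tables from SEM software typically print likelihood-based
correlation CIs, so the Fisher interval matches them only approximately
(to ~0.03 at these n).

## Model selection

Nested submodels are compared to the full ACE model by the likelihood
ratio test (statistic = Δ(−2lnL), plain χ² reference with df = dropped
parameters). The most parsimonious model is the AIC minimizer
(AIC = −2lnL + 2k); ties break toward fewer parameters, then toward the
genetic model (AE over CE). The plain χ² p-value is the default because
published twin tables report it; the 50:50 χ² boundary mixture —
theoretically preferable when a variance component is tested on its zero
boundary — is available via `boundary_mixture=True`. When the full-model
MLE already has ĉ² = 0, dropping C costs nothing and the LRT p-value is
exactly 1, which is why well-behaved AE rows print "model fit = 1". ADE
enters the comparison only on request (`include_ade=True`), mirroring the
usual post-hoc use of ADE after C proves negligible.

## Covariate adjustment

Phenotypes are residualized by pooled OLS before entering the pair
likelihood: raw densitometry on age + sex + BMI, T-scores (young-adult
reference) on age + BMI, Z-scores (age/sex-matched reference) on BMI
only. Sex is coded F→0, M→1; no age² or interaction terms by default.
Pre-residualization ignores twin clustering; at these sample sizes the
difference from modelling covariates in the SEM means is negligible, and
decoupling the stages keeps each reproducible in isolation. Covariates
that are constant in a subset (sex after a female-only filter) are
dropped with a logged warning. `score_from_reference` computes
(x − mean)/SD against a stratified reference curve for synthetic
pipelines; production T/Z scores normally come from the densitometer.

## Synthetic cohorts

The generator draws complete same-sex pairs from the generative model the
analysis assumes. Defaults emulate a mid-sized middle-aged registry
cohort: 62 MZ and 46 DZ pairs (216 individuals), age ~ N(54.2, 14.3)
shared within pair, 72% female, BMI ~ N(25.63, 4.72) with within-pair
correlation 0.5 (BMI is itself familial; the value is configurable), and
a lumbar-spine-like phenotype: mean 1.0 g/cm², residual SD 0.15, truth
a² = 0.8, c² = 0, e² = 0.2 — inside the 0.61–0.84 heritability range
such studies report. Latent scores correlate 1 (MZ) / 0.5 (DZ) for A,
1 / 0.25 for D; C is shared exactly; E is independent:

    y = mean + β·(covariates, centered) + √V (√a²·A + √c²·C + √d²·D + √e²·E)

Default covariate slopes (−0.002 g/cm² per year of age, +0.05 for male
sex, +0.005 per BMI unit) are of realistic sign and magnitude for bone
density and exist mainly to give the adjustment stage genuine confounding
to remove. All draws come from one `numpy` Generator seeded from the
config, in a fixed order, so output is reproducible byte-for-byte.

What the generator does **not** emulate: MZ/DZ variance or covariate
heterogeneity, non-normal phenotype tails, age–sex interactions,
selection effects of volunteer registries, and missing or incomplete
pairs. Passing recovery tests therefore demonstrates correctness of the
estimation machinery under the model's own assumptions, not robustness
to violations of them.

## Numerical conventions and edge cases

- Deviance tolerance: nested-model deviances may beat the full model by
  at most 1e-6 (optimizer slack); beyond that the LRT raises instead of
  reporting a negative statistic.
- Non-positive-definite candidate covariances are penalized with a large
  finite value rather than raising inside the optimizer.
- Zero-variance phenotypes, |r| = 1 correlations, empty cohorts and
  subsets that break pairs all produce structured errors or flagged report
  rows, never silent results.
- Problem sizes in the test suite: Monte-Carlo consistency checks use
  20,000 pairs; parameter recovery uses 20 replicates of 5,000 pairs per
  zygosity; CI calibration 200 replicates and model-selection consistency
  100 replicates at the 62/46 study geometry.

## Known limitations

- Univariate models only: no bivariate/multivariate decomposition, no
  sex-limitation models (the target design has no opposite-sex pairs),
  no threshold models for binary traits.
- Summary-statistic refits cannot reproduce a published raw-data analysis
  exactly when the original means/variance structure is unprinted; the
  residual discrepancy is about ±0.01 on standardized components at
  these sample sizes.
- AICc and multiple-testing corrections across phenotypes are not
  applied (phenotypes are analyzed independently, as is conventional for
  these report tables); both would be easy extensions.
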