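# Methods

`twindelta` analyzes longitudinal change in continuous phenotypes measured on
monozygotic (MZ) and dizygotic (DZ) twin pairs at two occasions.  The analyzed
quantity throughout is the within-individual change score
Δ = value(time 2) − value(time 1).  This note records the models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The classical twin decomposition of Δ

Phenotypic variance is partitioned into additive genetic (A), shared
environmental (C), dominance genetic (D) and unique environmental (E)
components.  With twins reared together, C and D are not jointly
identifiable, so two full models exist — ACE and ADE — with expected
within-pair correlations of Δ

    MZ: a² + c² + d²        DZ: ½a² + c² + ¼d²

(standardized components; at most one of c², d² nonzero).  The ADE model is
conventionally preferred when the MZ correlation exceeds twice the DZ
correlation; the package computes that heuristic and also fits both full
models and picks the one with lower AIC, which governs the pipeline (the
heuristic is reported alongside).  Nested sub-models AE, CE and E are
compared with the full model by likelihood-ratio tests; the DE model is
biologically implausible (dominance without additive effects cannot explain
DZ correlations that low relative to MZ) and is never fitted.

Fitting is full maximum likelihood on pair-ordered deltas: each pair
contributes a bivariate-normal term with covariance built from the expected
twin correlations and a common total variance.  Parameterization is by path
coefficients (component SDs); squaring them enforces nonnegativity and makes
exact zeros attainable at the boundary.  The mean model optionally adjusts
for sex, baseline age and baseline trait value; mean coefficients are
profiled out by generalized least squares at every likelihood evaluation,
so the optimizer only searches the 1–3 path coefficients.  Because the
covariance matrix is identical for all pairs within a zygosity, the profiled
likelihood is evaluated from precomputed cross-moments (Σxᵀx, Σxᵀy, Σy·y),
making each evaluation independent of sample size.

Optimization is Nelder–Mead with multiple starts: a Falconer moment start
(a² = 2(rMZ − rDZ), c² = 2rDZ − rMZ, clipped to the simplex; for ADE the
dominance share is seeded from the MZ/DZ excess) plus four seeded Dirichlet
random restarts, keeping the best.  ADE likelihoods can be multi-modal at
small sample sizes, hence the restarts.

### Model selection

The selection rule is parsimony-first: nested models whose LRT against the
full model has p > α (default 0.05) are candidates; the candidate with the
fewest free parameters wins, with AIC breaking ties among equal-size
candidates; if no nested model survives, the full model is kept.  A nested
model can therefore be selected even when its AIC exceeds the full model's.
LRT p-values use the plain χ² upper tail with df equal to the parameter
difference, with no boundary mixture (½χ²₀ + ½χ²₁).  This is deliberate — it
reproduces the convention of printing p = 1.00 at X² = 0.00 — and is
conservative for boundary hypotheses: the realized type-I error of dropping
a truly-zero component sits near 2–3% at nominal 5%, which the calibration
tests assert as a 2–9% band.

### Confidence intervals

Component CIs are percentile bootstrap: pairs are resampled with replacement
within each zygosity, the selected model is refitted per replicate (two
optimizer starts per refit), and per-component percentiles are taken.
Replicates that fail to converge are dropped and counted, with a warning
above 5%.  Profile-likelihood intervals are a reasonable alternative; the
bootstrap was chosen because it needs no boundary corrections for components
at 0 and directly yields intervals inside [0, 1].

## Intraclass correlation of Δ

Per zygosity, the ICC is the ML fit of an exchangeable bivariate normal:
both co-twins share marginal variance σ² and correlate ρ, giving
ICC = ρ = σs²/(σs² + σe²) with between-pair variance σs² = ρσ² and
within-pair variance σe² = (1 − ρ)σ².  The estimator alternates two exact
updates — GLS for the mean coefficients given (σ², ρ), then the closed-form
exchangeable MLE from residual cross-moments — which converges in a handful
of iterations and is invariant to within-pair ordering by construction.
Negative estimates are allowed (ρ is clipped only at ±0.999999 to keep the
GLS step nonsingular).  This ML/double-entry convention differs from the
one-way ANOVA moment estimator by small-sample factors; the ANOVA form is
kept in the test suite as an independent oracle.  ICC CIs and the MZ = DZ
comparison both use pair-level bootstrap (percentile interval; two-sided
percentile-of-zero p for the difference).  Covariate adjustment, when
enabled, happens in the mean model of the likelihood, not by
pre-residualization, keeping one estimation framework.

## Mixed model for the mean change

Significance of the mean change is tested per trait with a Gaussian mixed
model on all individual×occasion records:

    y = β₀ + β₁·age + β₂·sex + β₃·time + g + p + ε

where g is a genetic random effect correlated 1.0 between MZ and 0.5 between
DZ co-twins, p is an individual random intercept linking a person's two
occasions, and ε is residual noise.  Each pair forms a block of up to four
observations; incomplete blocks (missing values after cleaning) are handled
by subsetting the block covariance.  Estimation is ML (not REML) with
variances optimized on the log scale (L-BFGS-B, three fixed starts) and
fixed effects profiled by GLS, keeping log-likelihoods comparable across
nested variance structures.  The test of change is the Wald statistic
β₃/SE(β₃) against the standard normal; an LRT-based alternative remains
possible from the reported log-likelihood.  The individual random
intercept across occasions is included by default and can be dropped via the
`free` argument.

## Data cleaning

Fixed per-trait order: natural-log transform (optional, for right-skewed
positive traits) → 3-SD mask → Δ.  The mask computes the mean and sample SD
once, pooled over both occasions on the analysis (post-transform) scale, and
sets values with |x − mean| > 3·SD to missing in a single pass — it is not
iterated to a fixed point, so a second application could in principle mask
further values after the SD shrinks; single-pass is the documented contract.
Whether masking should be done per occasion or on the raw scale is
switchable (`k_sd`, `log` flags); pooled-transformed is the default.
Pairs in which either co-twin lacks Δ are excluded from the pair-likelihood
stages (ICC, twin models), while all available records still enter the mixed
model.

## Synthetic cohorts

The generator draws each biometric component as a mixture of a pair-shared
and an individual standard-normal score with sharing weights equal to the
expected cross-twin correlations (A: 1/0.5, C: 1/1, D: 1/0.25, E: 0/0),
scaled by √(proportion)·total SD — reproducing the covariance algebra
exactly rather than approximately.  Separate component sets drive baseline
level and change.  Age is uniform over the configured range and shared
within a pair (twins share a birth date); sex is Bernoulli per individual;
time-2 values add the mean change, the age gain over follow-up, and the
change deviation.  Log-normal traits exponentiate the normal-scale model, so
the downstream log transform recovers it exactly.

Two ready-made designs mirror the reference study's structure: a large
northern-European-style cohort (226 MZ + 276 DZ pairs, ages 18–67, 54%
female, 12-year follow-up) and a smaller east-Asian-style cohort (101 MZ +
80 DZ, ages 23–64, 68% female, 7-year follow-up), each with 12 log-normal
metabolic traits whose change architectures follow the published best-model
estimates (AE-like with a² ≈ 0.36–0.49 for most traits in the first design;
AE for blood biochemistry and CE for body-mass traits in the second).
Baseline means and SDs are plausible log-scale values for the respective
units, chosen once.

What the generator does **not** emulate: attrition between occasions (the
analyzed samples were complete pairs, so the simulator assumes completeness),
measurement error distinct from unique environment, opposite-sex DZ pair
effects, age-dependent variance, or the real cohorts' exact marginal
distributions.  Passing tests therefore demonstrate estimator correctness
under the classical model's own assumptions, not robustness to violations of
them.

## Numerical conventions and edge cases

- Tolerances: twin-model Nelder–Mead stops at xatol 1e-9 / fatol 1e-11; the
  ICC coordinate updates stop at 1e-12; mixed-model log-variances are
  bounded in [−25, 6] relative to the phenotypic variance (the lower bound
  makes noise-free data well-posed).
- Non-positive-definite pair covariances return +∞ from the likelihood so
  optimizers reject them without exceptions.
- LRT statistics are floored at 0; a nested log-likelihood exceeding the
  full one beyond 1e-6 triggers a refit warning.
- Ties: the AIC full-model rule and the selection rule both break ties
  toward ACE / the lower-AIC candidate.
- Degenerate inputs raise early with the offending record or trait named:
  nonpositive values under the log transform, zero SD in the mask (warns,
  masks nothing), fewer than 3 complete pairs for the ICC, zero delta
  variance.
- Pipeline reproducibility: every stochastic stage receives a seed derived
  from the root seed and the (trait, stage) pair via SHA-256, so adding or
  removing one trait does not shift the randomness of the others.

## Problem sizes used in validation

Desk checks on the published ICC table are exact and instantaneous.  The
simulation-based validation uses 5 000 pairs per zygosity for consistency
checks (component recovery within ±0.04, ICC within ±0.03), 100 replicates
for model-selection recovery, 200 replicates for LRT/Wald type-I error and
bootstrap coverage (at 500 pairs per replicate), and 400 bootstrap
replicates inside coverage loops.  These sizes keep Monte-Carlo error
comfortably below the asserted bands.

## Known limitations

- Two occasions cannot support growth-curve or level–change covariance
  modeling; only the difference score is analyzed.
- No sex-limitation or opposite-sex DZ models.
- The naive χ² reference for boundary LRTs is conservative (documented
  above).
- The exchangeable ICC assumes bivariate normality of Δ within pairs;
  heavy-tailed deltas would call for rank-based alternatives not provided
  here.
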