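# twindelta

Genetic and environmental decomposition of **longitudinal change** in twin
cohorts.

Levels of metabolic phenotypes (lipids, glucose, blood pressure, body-mass
traits) are well studied in twins, but the *rate of change* of these traits in
adults is the more direct signal of disorder-related modification.  With two
measurement occasions on monozygotic (MZ) and dizygotic (DZ) pairs, the
within-individual difference Δ = y(t₂) − y(t₁) becomes a phenotype of its own,
and the classical twin machinery applies to it: variance of Δ is split into
additive genetic (A), shared environmental (C), dominance (D) and unique
environmental (E) parts using the expected twin correlations

```
r_MZ = a² + c² + d²          r_DZ = ½a² + c² + ¼d²
```

The package is written for biostatisticians and genetic epidemiologists who
want this analysis as a tested, scriptable pipeline rather than a one-off
analysis: a synthetic-cohort generator with known architecture, the standard
cleaning rules (log transform, 3-SD mask), a kinship-structured mixed model
for the mean change, zygosity-specific intraclass correlations (ICC) with
bootstrap CIs, and ACE/ADE maximum-likelihood fits with LRT/AIC model
selection.  See `docs/methods.md` for the models and numerical choices.

## Components

| module | what it does |
| --- | --- |
| `twindelta.simulate` | two-occasion twin cohorts with exact A/C/D/E sharing for level and change |
| `twindelta.preprocess` | log transform, pooled 3-SD outlier mask, Δ construction |
| `twindelta.mixed` | ML mixed model `y = β₀+β₁age+β₂sex+β₃time + g + p + ε` with MZ/DZ kinship correlation; Wald test of β₃ |
| `twindelta.icc` | exchangeable bivariate-normal ICC per zygosity, bootstrap CIs, MZ=DZ test |
| `twindelta.biometric` | ACE/ADE/AE/CE/E fits, Falconer starts, LRT, AIC, parsimony-first selection, bootstrap component CIs |
| `twindelta.pipeline` / `twindelta.cli` | end-to-end runs, CSV/JSON reports, `twindelta` console command |

## Worked example

```python
from twindelta import (
    generate_cohort, preprocess_trait, fit_longitudinal_mixed,
    estimate_icc, fit_twin_model, choose_full_model_aic, select_best_model,
    bootstrap_components_ci,
)
from twindelta.biometric import NESTED_MODELS
from twindelta.simulate import danish_like_config

cohort = generate_cohort(danish_like_config(seed=1))   # 226 MZ + 276 DZ pairs
cleaned, deltas, masked = preprocess_trait(cohort, "TC", log=True)

mixed = fit_longitudinal_mixed(cleaned, "TC")
print(f"mean change (time effect): {mixed.beta['time']:.3f}  p = {mixed.p_time:.2e}")

mz, dz = estimate_icc(deltas, "MZ"), estimate_icc(deltas, "DZ")
print(f"ICC_MZ = {mz.icc:.2f}   ICC_DZ = {dz.icc:.2f}")

fits = {m: fit_twin_model(deltas, m) for m in ("ACE", "ADE")}
full = choose_full_model_aic(fits["ACE"], fits["ADE"])
nested = {m: fit_twin_model(deltas, m) for m in NESTED_MODELS[full]}
sel = select_best_model(fits[full], nested)
best = sel.best_fit
print(f"full model: {full}   best model: {sel.best_model}")
print(f"best-model components: a2={best.components.a2:.2f} "
      f"c2={best.components.c2:.2f} e2={best.components.e2:.2f}")
ci = bootstrap_components_ci(deltas, sel.best_model, reps=200, seed=1)
print("95% CI a2:", tuple(round(v, 2) for v in ci["a2"]))
```

Output:

```
mean change (time effect): 0.043  p = 1.35e-29
ICC_MZ = 0.52   ICC_DZ = 0.20
full model: ADE   best model: AE
best-model components: a2=0.52 c2=0.00 e2=0.48
95% CI a2: (0.42, 0.62)
```

Reading this: total cholesterol was simulated with a mean log-scale increase
of ≈0.044 over follow-up and a change architecture of a² = 0.48 — the fitted
mean change (0.043, p ≈ 10⁻²⁹) recovers the trend; the MZ intra-pair
correlation of ΔTC (0.52) is more than double the DZ one (0.20), so the ADE
full model is entertained, but dominance is not needed (the LRT against AE is
non-significant) and the parsimonious AE model is selected, attributing about
half the variance in ΔTC to additive genetics — matching the generating value
within sampling error, with a pair-resampling bootstrap CI of 0.42–0.62.

The same analysis runs from the shell:

```
twindelta simulate --config config.yaml --out cohort.csv
twindelta icc     --in cohort.csv --trait TC --boot 1000 --seed 1 --out icc.csv
twindelta twinfit --in cohort.csv --trait TC --boot 1000 --seed 1 --out twin.json
twindelta report  --config config.yaml --out results/
```

`report` writes one CSV per table family (descriptives + change tests, ICCs,
full models, best models, per-model AICs), a full-precision JSON bundle, and
a run log; reruns with the same config and seed are byte-identical.

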