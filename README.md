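# psortransit

Posttreatment prognosis of psoriasis skin lesions, modeled as transition
diagrams among severity stages.

Plaque psoriasis severity is rated on the 5-point Investigator's Global
Assessment (IGA, 0–4), collapsed here into four stages: IGA 0/1 (clear /
almost clear), IGA 2, IGA 3 and IGA 4. For a cohort of patients starting
one of three therapies — **traditional** (topicals, phototherapy),
**systemic** (nonbiologic systemic drugs) or **biologic** — the quantity of
interest is the 4×4 matrix of transition probabilities

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>ij</sub> = Pr(stage j at follow-up | stage i at baseline, therapy)*

estimated separately for two follow-up windows (0–1 month and 1–12 months)
and contrasted between therapies. Because therapy choice in observational
registries is confounded with severity, the pipeline estimates these
matrices on a matched pseudo-population:

1. **Multiple imputation** of missing baseline covariates by chained
   equations (predictive mean matching for continuous, logistic draws for
   binary covariates), producing *M* completed data sets.
2. **Tri-directional 1:1 nearest-neighbor matching with replacement** on
   Mahalanobis distance over 17 baseline covariates: every patient anchors
   a triple holding itself plus its nearest neighbor in each of the other
   two arms; reuse is handled by frequency weights.
3. **Transition estimation** per therapy, window and imputation, with the
   last visit inside a window defining the outcome and
   last-observation-carried-forward (LOCF) for patients without one; cell
   variances are binomial, *p(1−p)/n<sub>row</sub>*.
4. **Rubin-rule pooling** across imputations
   (*T = W + (1+1/M)·B*), 95% CIs, and elementwise between-therapy
   contrast matrices pooled the same way.
5. **Reporting**: Graphviz-DOT transition diagrams with a full-precision
   JSON twin, and CSV tables rounded to two decimals.

No registry data are distributed; a synthetic-cohort generator
(`psortransit.simulate`) reproduces the statistical structure of the study
cohort — published arm shares, covariate marginals, confounded assignment,
per-therapy latent transition kernels, and missing-at-random masking — with
a serialized ground truth so every stage is testable end to end.

## Worked example

```python
from psortransit import (TruthParameters, generate_cohort, apply_missingness,
                         impute, match_three_groups, estimate_transitions,
                         pool_rubin, contrast)

params = TruthParameters(n=2000, seed=42)
cohort, truth = generate_cohort(params)
cohort = apply_missingness(cohort, params)
print("arm sizes:", cohort.therapy_counts().to_dict())

imputed = impute(cohort, m=5, cycles=5, seed=42)
matched = [match_three_groups(c) for c in imputed.cohorts]
bio = [estimate_transitions(c, m, "biologic", "w1")
       for c, m in zip(imputed.cohorts, matched)]
trad = [estimate_transitions(c, m, "traditional", "w1")
        for c, m in zip(imputed.cohorts, matched)]

pooled = pool_rubin(bio)
i, j = 3, 0   # IGA 4 -> IGA 0/1
print(f"biologic IGA4->IGA0/1, 0-1 mo: "
      f"{pooled.p[i,j]:.2f} (95% CI {pooled.ci_lo[i,j]:.2f}-{pooled.ci_hi[i,j]:.2f})")
diff = contrast(bio, trad)
print(f"biologic - traditional:        "
      f"{diff.d[i,j]:.2f} (95% CI {diff.ci_lo[i,j]:.2f} to {diff.ci_hi[i,j]:.2f})")
```

prints

```
arm sizes: {'traditional': 1040, 'biologic': 672, 'systemic': 288}
biologic IGA4->IGA0/1, 0-1 mo: 0.07 (95% CI 0.03-0.10)
biologic - traditional:        0.04 (95% CI 0.01 to 0.08)
```

The point estimate 0.07 is the pooled probability that a severe (IGA 4)
patient on biologics is clear or almost clear within a month, *including*
the patients with no one-month visit, whom LOCF keeps at their baseline
stage (hence the value is far below the latent kernel's 0.23 — roughly 70%
of severe patients have no visit in the window). The contrast +0.04 says
biologics clear severe lesions more often than traditional therapy in the
matched populations, the same direction and magnitude reported for the real
cohort (+0.06).

The same pipeline is available from the shell:

```bash
psortransit run --seed 42 --out results/      # full pipeline from config defaults
psortransit simulate --n 2000 --seed 42 --out cohort/
psortransit impute --in cohort/ --m 20 --out imputed/
psortransit match --in imputed/ --out matched/
psortransit transitions --in imputed/ --matched matched/ --out est/
psortransit pool --in est/ --out results/
psortransit report --in results/ --out diagrams/
```

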