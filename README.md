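# binmi

Binned multiple imputation for missing covariates in epigenome-wide
association studies (EWAS).

## The problem

An EWAS fits one regression per CpG site,

```
methylation_j ~ age + sex + smoking        (j = 1 … N_CpG)
```

with N_CpG in the hundreds of thousands and, typically, a few hundred to
a few thousand individuals.  When a covariate such as smoking status is
partly missing, the standard fallback is a complete-case (C-C) analysis,
which discards individuals and loses power.  Multiple imputation (MI)
can recover that power, but a valid imputation model must contain every
outcome of the analysis model — here, every CpG site — which is
impossible when sites outnumber cases.  Leaving an analyzed site out of
the imputation model attenuates its association estimate toward the
null.

`binmi` implements the practical middle ground: impute the covariate
**per bin of sites**, so that each site's EWAS uses an imputation
informed by that site, and pool with Rubin's rules.  The strategies are:

| strategy | imputation models | imputation model |
|---|---|---|
| `complete_case` | 0 | — (drop incomplete rows) |
| `separate` | N_CpG | smoking ~ site + age + sex |
| `random_bins` | ceil(N/b) | smoking ~ b sites + age + sex |
| `naive` | 1 | smoking ~ C-C-significant sites + age + sex |
| `wu` | 1 | smoking ~ BIC-selected sites + age + sex |
| `wu_bins` | ceil((N−s)/(b−s)) | smoking ~ b sites incl. the s selected + age + sex |
| `ipw` | 0 | weighted C-C analysis (inverse-probability weights) |

Smoking (never/former/current, reference never) is imputed by
polytomous logistic regression; per-site fits across the m completed
data sets are pooled by Rubin's rules (total variance
`T = W + (1 + 1/m) B`, Barnard–Rubin degrees of freedom), and a site is
called significant when either smoking coefficient has `p < alpha / N_CpG`.

A synthetic-data module generates the test bed: cohorts with ~70.5%
males, age ≈ N(55.4, 8) years, smoking marginals (38.6, 56.7, 4.7)%,
standardized per-site methylation with a minority of sites carrying
smoking effects of 0.15–0.60 SD, and two missing-at-random mechanisms
(MM1: smoking missing with probability 0.75 for males aged ≥ 57;
MM2: 0.50 for that group, 0.125 for everyone else — both ≈ 22–24%
missingness).

## Worked example

```bash
binmi simulate --n 464 --sites 2000 --true-sites 40 --mechanism MM1 \
    --seed 11 --out-dir example
binmi run --strategy random-bins --bin-size 45 --m 20 --seed 5 \
    --methylation example/methylation.tsv \
    --covariates example/covariates.csv \
    --schema example/schema.yaml --out example/results.tsv
```

```
45 bins, seed 5
16 significant sites (1.2s); wrote example/results.tsv
```

The run partitioned the 2,000 sites into 45 random bins of ≤ 45 sites,
imputed the ~22% missing smoking values 20 times per bin from age, sex,
and the bin's methylation, fitted the EWAS per completed data set, and
pooled.  The complete-case analysis of the same data finds 13
significant sites with a mean former-smoker SE of 0.1129; the binned
imputation finds 16 at a mean SE of 0.1085 — the power gain MI exists
for.  The same comparison from the library:

```python
from binmi import StudyConfig, run_simulation_study

study = run_simulation_study(StudyConfig(seed=20260927))
print(study.groupby("strategy")[["tp_pct", "fp_pct", "mean_se_former"]].mean())
```

```
                  tp_pct     fp_pct  mean_se_former
strategy
complete_case    70.0854     1.1012          0.1103
random_bins_150  77.6880    13.8257          0.0985
random_bins_45   74.3699    10.9160          0.1059
separate         73.7179     3.2452          0.1076
```

(10 replicates of 464 individuals x 2,000 sites under MM1, m = 20.)
`tp_pct` is the percentage of complete-data-significant sites a
strategy recovers; `fp_pct` the percentage of its discoveries the
complete data did not flag; `mean_se_former` the mean pooled SE of the
former-smoker coefficient across sites, which falls as the imputation
model gains information: complete-case > separate > bins (10:1) >
bins (3:1).

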