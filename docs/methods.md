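# Methods

## Model and procedure

The analysis model at each CpG site j is ordinary least squares on the
fully standardized methylation value,

    y_j = b0 + b1 age + b2 sex + b3 1[former] + b4 1[current] + e,

with sex coded 0/1 (female = 0), age in years (uncentered), and
never-smokers as the smoking reference.  The coefficients of interest
are b3 and b4 (SD units of methylation per smoking category).  A site is
declared associated with smoking when min(p_former, p_current) <
alpha / N_CpG — the "either coefficient" reading of a genome-wide
Bonferroni rule.  A per-site joint Wald F over both smoking terms is
available for single (unpooled) fits via `significant_sites(...,
test="joint-F")`; the min-p rule is the default and the only rule
implemented for pooled fits, because a pooled joint test requires
multivariate pooling machinery that the procedure does not otherwise
need.  Note the min-p rule tests two coefficients per site, so the
genome-wide false-positive expectation is ~2·alpha rather than alpha;
the null-calibration tests check that rate.

Only covariate missingness is modelled.  Methylation is required
complete; covariate missingness is handled by one of the strategies in
the README table, all of which share the same downstream EWAS and
pooling path.

### Imputation

Smoking status is imputed by polytomous (multinomial) logistic
regression on age, sex, and the methylation values of the bin's sites.
Following the behaviour of the `polyreg` method in the R package mice,
the model is fitted **once** on the complete cases by ridge-penalized
Newton iteration, and each of the m imputations independently draws a
category for every missing case from the fitted probabilities.  The
between-imputation variance B then reflects category-draw uncertainty.
An alternative `param_uncertainty="bootstrap"` mode refits the model on
a bootstrap resample of the complete cases for every imputation, which
additionally propagates parameter uncertainty (textbook "proper" MI) at
the cost of larger B; it is the more conservative choice, and the
package's own comparisons show it noticeably widens pooled SEs for
weakly informed models (e.g. single-site imputation).  The default
reproduces the mice-based procedure the binning strategies were
designed around.

Numerical details of the multinomial solver: reference category first,
coefficients initialized at zero, penalty 0.5·ridge·n·||beta||² on
non-intercept coefficients (default ridge 1e-5 — negligible shrinkage at
the optimum but keeps separated fits finite), Newton steps inf-norm
capped at 4.0 so that (near-)separated likelihoods are climbed stably,
convergence on the penalized score with tolerance 1e-6·n, at most 25
iterations for imputation fits (fitted probabilities converge well
before the coefficients under separation) and 60 for the BIC fits used
in stepwise selection.  The solver is batched over design matrices:
every bin of equal size — and, in stepwise selection, every candidate
site — is fitted in one vectorized Newton solve, which is what makes the
separate-sites strategy (one model per site) tractable on one CPU.

A bootstrap resample that loses an observed category is redrawn (at
most 10 attempts).  Categories absent from the observed data cannot be
imputed; with a single observed category the imputation degenerates to a
deterministic fill.  Bins whose predictor count (sites + age + sex +
intercept) reaches the number of complete cases are refused with advice
to use smaller bins.

Continuous covariates (chained-equations mode) use predictive mean
matching: an OLS fit gives the observed cases' predicted means, a
Bayesian-bootstrap (Dirichlet-weighted) refit gives the missing cases',
and each missing case borrows the observed value of one of its 5
nearest donors.  A Bayesian normal-linear method (`method="normal"`) is
also provided.  Chained equations initialize missing cells from the
observed marginals and revisit incomplete variables in order of
increasing missingness for `n_cycles` cycles (default 10, above the
common default of 5 since the cost is minor); the m imputations are
independent chains.  Auxiliary covariates may enter imputation models
while staying out of the EWAS.

### Pooling

Per-site estimates across the m completed data sets are pooled by
Rubin's rules: qbar = mean of estimates, W = mean squared SE, B =
between-imputation variance (denominator m − 1), T = W + (1 + 1/m)·B,
with Barnard–Rubin small-sample degrees of freedom against the
complete-data df (n − number of estimable model parameters).  B
computed from numerically identical estimates is snapped to exactly
zero (tolerance eps²·(1 + qbar²)), in which case the pooled result
equals the single fit with df = df_com.  The results table reports one
df per site — the smaller of the two smoking coefficients' adjusted dfs
(conservative); per-coefficient dfs are available from the pooling
function.  A smoking level absent from the data drops its design column
and the coefficient is reported NaN ("inestimable"), which propagates
through pooling.

### Strategy bookkeeping

Random bins shuffle the site list once (seeded) and cut consecutive
chunks, so the bin count is ceil(N/b) and the last bin may be smaller.
Wu bins chunk the non-selected sites into groups of b − s and add the s
selected sites to every bin: ceil((N − s)/(b − s)) bins.  In the output
table every site appears exactly once — for Wu bins the selected sites
are analyzed within the first bin.  Naive selection takes all
Bonferroni-significant complete-case sites (ascending p).  Wu selection
ranks candidates by the complete-case min-p (ties broken by site ID),
takes the top 100, and runs forward-stepwise search from the base model
smoking ~ age + sex, adding the candidate with the largest decrease in
BIC = −2 logL + q·log n until no candidate decreases it.  The
separate-sites strategy refuses to run above 20,000 sites unless
forced, as a guard against accidentally launching the array-scale
workload.

### Inverse probability weighting

The IPW comparator fits a logistic model of the complete-case indicator
on fully observed predictors (default age and sex; any fully observed
column, e.g. a derived risk-group indicator, can be supplied), weights
complete cases by 1/p̂ (optionally stabilized by the marginal
completeness rate, and trimmed symmetrically at the 0.01/0.99 weight
quantiles by default), and runs a weighted least-squares EWAS with HC0
sandwich standard errors.  Quasi-separation — a fully complete stratum
— is tolerated because complete-case weights remain finite; the fit is
rejected only if some complete case's fitted completeness probability
collapses toward zero.  Only this one generic variant is provided.

## Synthetic data

The generator emulates a blood-methylation cohort: sex ~
Bernoulli(0.705) (male), age ~ round(N(55.4, 8²)) truncated to
[18, 100], smoking ~ (0.386, 0.567, 0.047) over (never, former,
current), optionally linked to age/sex by a multinomial-logit model.
The age SD of 8 years is a free choice calibrated so that the
males-57-and-over stratum is ~31% of the cohort and the two built-in
missingness mechanisms blank a comparable ~22–24% of smoking values.
"Aged 57 or over" is inclusive.  Methylation is generated directly on
the standardized scale: null sites are standard normal; each of the
n_true planted sites adds effects of magnitude uniform on 0.15–0.60 SD
(the span of strong-to-weak smoking associations on a 450k array) to
former and current smokers with a common random sign, after which every
row is re-standardized (so realized effects are slightly below the
generating values).  Sites are independent by default; an optional
equicorrelated block structure is available because real arrays are
locally correlated, but no specific structure is assumed anywhere.

What the generator does **not** emulate: bounded bimodal beta-values,
cell-type composition, batch effects, genomic positions, or realistic
inter-site correlation.  Passing tests therefore demonstrate the
statistical behaviour of the missing-data machinery under a clean MAR
design, not robustness to array artefacts.

All randomness descends from one integer seed through named
SHA-256-derived streams (cohort / methylation / missingness / each
bin × imputation), so stages are reproducible in isolation, per-bin work
may be scheduled in any order, and two runs with equal seed and config
are bit-identical.

## Evaluation conventions

"Truth" for scoring is always the EWAS on the same replicate's complete
(no-missingness) data, never the generating coefficients; the
true-positive rate is the percentage of complete-data-significant sites
a method recovers, and the false-positive rate is the percentage of the
method's discoveries the complete data did not flag (a false-discovery
proportion).  A method with zero discoveries gets FP = NaN and is
excluded from FP averaging; replicates with an empty truth set are
flagged and excluded from TP/FP averaging.  FP percentages are averaged
as the mean of per-replicate ratios.  Mean SEs are reported for the
former-smoker coefficient.  Bias tables compare a method's coefficient
with the complete-data coefficient per site, grouped by (selection
status × sign of the complete-data coefficient).  Unbiasedness suites
measure bias at the *planted* sites: groups defined by estimated
significance inherit a selection artefact (complete-data estimates are
conditionally inflated at sites selected for being significant), which
the planted set avoids.

## Study sizes

The default desk-scale study uses 464 individuals × 2,000 sites with 40
planted effects, MM1, m = 20 imputations, 10 replicates — the cohort
size kept at the reference scale and the site count reduced so the full
strategy comparison runs in about a minute per replicate set on one
CPU.  m = 20 rather than the very conservative 100 follows the
linear/quadratic rules of thumb relating imputations to the missingness
percentage (~22% here).  The bias suites use 100 replicates at 500
sites (m = 10) and the MAR-validity suite 100 replicates at 200 sites
(m = 10) under both mechanisms.  The acceptance script runs 5
replicates at 1,000 sites covering all strategies plus IPW.

## Known limitations

* The default imputation omits parameter uncertainty exactly as mice's
  polyreg does; pooled variances are accordingly slightly liberal.  Use
  the bootstrap mode when proper MI matters more than matching that
  reference behaviour.
* Pooled significance offers only the min-p rule; there is no pooled
  joint test of both smoking coefficients.
* Large bins near the complete-case:variable limit overfit the
  imputation model, shrinking B and admitting more false positives —
  visible in the desk-scale studies as the higher FP of 3:1 bins.
* IPW relies on a correctly specified completeness model; with the
  default smooth predictors it cannot represent threshold mechanisms
  exactly and behaves like the misspecified-model case.
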