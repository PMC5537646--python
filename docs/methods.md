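# Methods

This note documents the models implemented in `geekdex`, the synthetic
cohort the package tests them on, and the numerical and design choices a
maintainer would want to know about.

## The geek index (GI)

The GI is a composite of three child-level measures taken at age 12:
non-verbal IQ (Raven's Standard Progressive Matrices, 0–60 here), CAST
social aloofness (0–13) and CAST restricted/repetitive behaviours (RRB,
0–13). The default composite is

    GI = (IQ + 1) × ((social + 1) + (recode(RRB) + 1))

Two transforms shape it. First, every subscale is shifted by +1 so a true
score of 0 maps to 1; without this, any child scoring 0 on one subscale
would get GI = 0 regardless of the other two. Second, very high RRB
scores are folded down before the shift, so the composite peaks at
*midrange* RRB: the intended phenotype is a focused, aloof, able child —
not one with clinically extreme repetitive behaviour. The exact recode
used on the original data is not public; we use a tent map,
`recode(r) = r` for `r ≤ τ` and `τ − s·(r − τ)` (floored at 0) above,
with τ = 7 (the 0–13 midpoint) and slope s = 1, both configurable. This
is the least-parameterized map with the documented qualitative shape.

Variants: `raw_rrb` skips the fold; `standardized` divides each subscale
(RRB after recoding) by its cohort standard deviation, combines with the
same product structure, and z-scores the composite. We deliberately do
*not* mean-center the subscales before multiplying: the product of
centered, jointly near-normal scores is uncorrelated with every linear
function of the scores (all odd moments vanish), so a fully z-scored
product would measure second moments of the trait rather than the trait,
and could not rank-agree with the other variants. Scale-only
normalization keeps the composite monotone in each subscale, which is
what "the results replicate across variants" requires.

## Synthetic cohort generator

No individual-level data from the motivating twin registry can be
redistributed, so all analyses run on seeded synthetic cohorts.
Per family: zygosity MZ with probability 0.36; paternal age at
conception from a truncated normal (mean 34, sd 6, bounds 18–60 years);
maternal age 29 + 0.7·(paternal − 34) + N(0, 3.5²), clipped to 16–45;
SES standard normal, optionally correlated with paternal age
(`ses_paternal_age_corr`, 0.2 in the `paper_fit` preset) so that
"adjusted" models have real confounding to remove. MZ twins share sex;
DZ twins draw independently.

Each child's latent geek factor is

    G = a(M)·A + d0·D + e(M)·E + β_pa(sex)·(pa − 34) + β_ses·SES + β_ma·(ma − 29)

with A shared 1.0 (MZ) / 0.5 (DZ) within pairs, D 1.0 / 0.25, E
independent, and paths moderated by standardized paternal age M:
a(M) = a0 + βa·M, e(M) = e0 + βe·M. Subscales are linear in G plus
independent Gaussian noise, rounded and clipped to their scale ranges.

Units: the `beta_pa_*` parameters are declared in GI units per year, so
the latent→subscale→composite map must have unit slope. With baselines
(7, 3, 3), loadings (0.075, 0.025, 0.025) and noise sds (1.5, 1.0, 1.0),
the analytic slope is 0.075·8 + 8·(0.025 + 0.025) = 1.0; a large-n
regression of the computed composite on the latent factor confirms
0.995–1.00 after discretization and clipping. These defaults give a GI
distribution (mean ≈ 64, sd ≈ 17) and a crude paternal-age standard
error (≈ 0.03 at 4,000 families) close to the real cohort's printed
scale.

Attainment is generated from the *computed* composite —
`b_gi_attain·(GI − 64) + direct_pa_attain·(pa − 34) + β_ses,att·SES + noise`
— so the mediation chain paternal age → GI → attainment holds exactly by
construction and the outcome-model coefficient on GI is the generating
`b_gi_attain`. STEM outcome counts and the top-2-STEM-grades indicator
are likewise driven by GI (log-odds 0.0392 ≈ log 1.04 per GI unit by
default). Autism flags are generated at 0.4% prevalence solely to
exercise the exclusion-sensitivity path.

What the generator does *not* emulate: registry attrition and
missingness, item-level CAST responses, school-level clustering, and any
non-Gaussian measurement error. One structural consequence worth
flagging: the composite carries large subscale measurement noise
relative to the latent A/E variance (a0 = 2.01, e0 = 1.73 in GI units),
so the *computed* GI of a cohort has a small twin correlation. The twin
variance-component experiments therefore use the dedicated pair-level
simulators (`simulate_twin_pairs`, `simulate_ae_pairs`,
`simulate_gxe_pairs`), which generate the trait directly on the latent
scale — exactly the situation the twin models address. Passing tests
show the estimators recover their generating parameters; they do not
show that a noisy composite is heritable.

The `paper_fit` preset fixes the generating values to the reference
estimates: β_pa = 0.28 (M) / 0.09 (F) GI units/yr, a0 = 2.01, e0 = 1.73,
βa = 0.08, βe = 0.02, GI→attainment 0.17 and a zero direct paternal-age
effect on attainment, making the pooled mediated product ≈ 0.185 × 0.17
≈ 0.03.

## Family-clustered association models

All regressions carry a single random family intercept and are fitted by
maximum likelihood (statsmodels MixedLM); p-values are Wald-z. When the
intercept-variance estimate collapses to the boundary and the Hessian
becomes singular, the fit falls back to OLS with variance 0 — the exact
ML solution at that boundary. The "adjusted" covariate set is fixed to
{maternal age, SES, sex, zygosity}.

The random-intercept *logistic* model is fitted by direct maximization
of the marginal likelihood with 25-node Gauss–Hermite quadrature over
the family intercept (statsmodels has no ML GLMM; its Bayes
approximation would not match the rest of the inference chain).
Separation is detected as diverging coefficients and raised as a
convergence error rather than reported.

The linear-vs-quadratic paternal-age comparison is a standard LRT:
statistic 2·Δloglik against chi-square with 1 df, quadratic term built
on centered age to avoid collinearity. The GI-vs-subscale comparison
z-scores all four outcomes so effect sizes are on a common scale.
Attainment points use a configurable grade map (A* = 8 … G = 1) with
GCSE weight 1 and A-level weight 2. The "geek cluster" comparison cuts
the three subscales at ±1 s.d. (higher CAST social = more aloof) and
reports group means of STEM and Art exam counts, flagging empty groups
with n = 0 rather than raising.

## Quasi-Bayesian mediation

The mediator model (GI ~ paternal age + covariates) and outcome model
(attainment ~ paternal age + GI + covariates), both family-clustered,
are fitted once; `n_sims` parameter vectors are then drawn from each
fit's asymptotic normal distribution. Per draw, ACME = a·b (mediator-
model treatment coefficient × outcome-model mediator coefficient),
direct = the outcome-model treatment coefficient, total = their sum — an
exact identity in this linear, no-interaction setting. Point estimates
are medians over draws, CIs the 2.5/97.5 percentiles, p-values twice the
smaller sign fraction. `n_sims` defaults to 1,000 for CI stability
(reference analyses used 100; that remains available). A family-
resampling nonparametric bootstrap is provided as an alternative engine
and agrees with the parameter-draw engine in the linear case within
Monte-Carlo error. Sex-stratified runs drop sex from the covariates.
Clustering enters only through the model fits; sequential ignorability
and treatment–mediator interactions are out of scope.

## FIML twin models

All twin models maximize the exact per-pair bivariate normal likelihood
with a single grand mean (equal across twin order and zygosity — the
data-generating process is order-symmetric, so a richer means model
would only add noise); a pair with a missing co-twin contributes its
marginal normal density, which is what makes the estimation
full-information. The saturated model per zygosity is parameterized as
(μ, log σ, atanh r), so the correlation respects its bounds; AE/ADE
models are parameterized directly in paths (a, d, e) whose signs are not
identified — fits report magnitudes. The GxE model makes the paths
linear in the standardized family moderator, a_i = a + βa·M_i,
e_i = e + βe·M_i, with the usual MZ/DZ sharing coefficients applied to
a_i²; the trait is residualized on the moderator first so a mean trend
cannot masquerade as variance moderation. The moderation is applied
symmetrically (one moderator value per family), and means are not
moderated.

Optimization is Nelder–Mead from a moment-based start plus 4 random
restarts (seeded); the AE optimum is always included among the ADE and
GxE starts, so the nested log-likelihood ordering holds by construction.
Confidence intervals are Wald from the observed information (numerical
central-difference Hessian), computed on the transformed scale where one
exists (Fisher z for correlations); profile likelihood was considered
and dropped as 10–50× slower with no accuracy gain at the sample sizes
used here. Boundary optima (e.g. a² → 0) are reported as such, with the
information matrix pseudo-inverted and CIs flagged NaN when singular.
The "tetrachoric" label sometimes attached to twin correlations of a
continuous trait is read as FIML-estimated Pearson correlations;
no thresholding is applied.

One statistical point encoded in the tests: when the generating
moderation is zero, the fitted GxE model still gains an O(1) overfitting
increment in log-likelihood over AE (two extra free parameters, ~χ²₂/2),
so the tests assert a small bounded gain rather than equality.

## Problem sizes and tolerances

The recovery experiments run at the designed study sizes: 10,000 pairs
for correlations and GxE (20 replicates), 5,000 pairs per zygosity for
AE (20 replicates), 4,000 families for association and mediation (20
replicates each), 200 small replicates for the LRT type-I-error and
mediation-coverage checks. Tolerances are stated per experiment in the
test suite: ±0.02 on correlations and variance shares (≈3 Monte-Carlo
s.e.), ±0.03 on the moderation slope, ±0.05 on the baseline genetic
path, 0.5 generating standard errors on regression coefficients, ±0.01
on the pooled ACME. Numerical tolerances: twin log-likelihoods match
brute-force density summation to 1e-3 (in practice 1e-8), FIML
correlations match the closed-form double-entry estimate to 1e-3, and
the clustered linear model matches OLS to 1e-4 when clustering is absent.

## Known limitations

* The generator's subscale noise model is Gaussian-rounded; real CAST
  subscales are skewed counts. Recovery results are insensitive to this,
  but descriptive distributions are not registry-realistic.
* The RRB recode and the grade-point map are configurable stand-ins for
  unpublished instrument details.
* No shared-environment (C) models, no bivariate or longitudinal twin
  models, no liability-threshold models.
* Wald CIs can be poor near variance boundaries; they are flagged, not
  repaired.
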