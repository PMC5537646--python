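# geekdex

Twin-cohort simulation and analysis of a **geek index** (GI) — a
composite of non-verbal IQ, social aloofness and restricted/repetitive
behaviours (RRB) measured in children — and of its relationship with
**paternal age at conception** and later **educational attainment**.

The package is aimed at behavioural-genetics and epidemiology
researchers who want a tested, fully reproducible implementation of this
analytic chain on data they can actually share: a seeded synthetic twin
cohort stands in for the (non-distributable) registry data, and every
estimator is validated by recovering known generating parameters.

## What it implements

**Score construction.** GI = (IQ + 1) × ((social + 1) + (RRB′ + 1)),
where RRB′ folds very high RRB scores down so the composite peaks at
midrange RRB, and the +1 shift prevents a single zero subscale from
zeroing the product. Standardized and raw-RRB variants are included.

**Family-clustered association.** Linear mixed models with a random
family intercept (ML), fitted crude and adjusted (maternal age, SES,
sex, zygosity), pooled and by sex, with sensitivity subsets (fathers
≤ 50 years, autism cases excluded), a linear-vs-quadratic likelihood-
ratio test for the paternal-age trend, a random-intercept logistic model
(Gauss–Hermite quadrature) for binary STEM outcomes, and a ±1 s.d.
"geek cluster" group comparison.

**Causal mediation.** Quasi-Bayesian Monte-Carlo mediation of the
paternal-age effect on attainment through GI: parameter vectors are
drawn from the asymptotic distribution of the clustered mediator and
outcome models; per draw ACME = a·b, direct = c′, total = ACME + direct
(exact in the linear case); medians and 2.5/97.5 percentiles are
reported. A family-resampling bootstrap engine is available.

**Twin variance components (FIML).** Saturated twin correlations, AE and
ADE decompositions, and a gene–environment moderation model in which the
additive-genetic and non-shared-environment paths are linear in
standardized paternal age:

    cov(twin1, twin2) = k_A · a(M)²,   a(M) = a + βa·M,  e(M) = e + βe·M

with k_A = 1 (MZ) or ½ (DZ). All pair likelihoods are exact bivariate
normals; incomplete pairs contribute marginal densities. The trait is
residualized on the moderator before the moderation fit.

See `docs/methods.md` for the models, assumptions and numerical choices.

## Worked example

```bash
geekdex simulate --preset paper_fit --seed 7 --out cohort.csv
geekdex twin --cohort cohort.csv --model gxe
```

The `paper_fit` preset generates cohorts whose generating parameters are
the reference estimates (male paternal-age effect 0.28 GI units/yr,
latent paths a = 2.01, e = 1.73, moderation βa = 0.08, βe = 0.02,
GI→attainment 0.17, zero direct effect). The same chain from Python:

```python
import dataclasses
from geekdex import synth, gi, assoc, twin
from geekdex.mediate import mediate

cfg = dataclasses.replace(synth.paper_fit_preset(), seed=7)  # 4,000 families
cohort = gi.score_cohort(synth.simulate_cohort_frame(cfg))

males = cohort[cohort.sex == "M"]
fit = assoc.fit_lmm("gi_default", ["paternal_age", "maternal_age", "ses", "zygosity"], males)
print(f"adjusted male paternal-age effect: {fit.beta('paternal_age'):.3f}"
      f" (se {fit.se('paternal_age'):.3f}, n={fit.n_children})")

pairs = synth.simulate_gxe_pairs(5000, 5000, a0=2.01, e0=1.73,
                                 beta_a=0.08, beta_e=0.02, seed=7)
gxe = twin.fit_gxe(twin.regress_out_moderator(pairs), seed=7)
print(f"a={gxe.a:.2f} e={gxe.e:.2f} beta_a={gxe.beta_a:.3f} beta_e={gxe.beta_e:.3f}")
```

prints

```
adjusted male paternal-age effect: 0.305 (se 0.072, n=3958)
a=2.00 e=1.74 beta_a=0.075 beta_e=0.031
```

i.e. the clustered model recovers the generating male effect (0.28)
within half a standard error on a single 4,000-family draw, and the
moderation fit recovers the generating paths and slopes almost exactly
at 10,000 pairs: genetic variance grows with paternal age while the
environmental path barely moves.

`geekdex run --config paper_fit --out results/ --seed 7` executes the
whole chain (descriptives, crude/adjusted association tables, sex-split
mediation, twin correlation/AE/ADE/GxE fits, a variance-function table)
and writes deterministic TSV/JSON outputs plus a run manifest.

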