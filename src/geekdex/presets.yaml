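# Named SimConfig presets.
#
# paper_fit: generating parameters equal the fitted values reported for the
# real twin cohort — sex-specific paternal-age effects on GI of 0.28 (males)
# and 0.09 (females) GI units/yr on the adjusted scale, unstandardized latent
# paths a0=2.01 and e0=1.73 with moderation slopes beta_a=0.08, beta_e=0.02
# per standardized-paternal-age unit, GI->attainment coefficient 0.17 and a
# zero direct paternal-age effect on attainment (full mediation through GI;
# pooled mediated product ~= 0.185 * 0.17 ~= 0.03).  SES and maternal-age
# effects are non-zero so the "adjusted" models genuinely adjust.
paper_fit:
  n_families: 4000
  prop_mz: 0.36
  paternal_age_dist: [34.0, 6.0, 18.0, 60.0]
  maternal_paternal_age_corr: 0.7
  ses_paternal_age_corr: 0.2
  ses_effects: [2.0, 1.0]
  beta_maternal_gi: 0.05
  beta_pa_male: 0.28
  beta_pa_female: 0.09
  a0: 2.01
  d0: 0.0
  e0: 1.73
  beta_a: 0.08
  beta_e: 0.02
  b_gi_attain: 0.17
  direct_pa_attain: 0.0
  autism_prevalence: 0.004
  seed: 0

# A null cohort: no paternal-age, SES or attainment effects; useful for
# type-I-error and coverage experiments.
null_effects:
  n_families: 1000
  prop_mz: 0.36
  paternal_age_dist: [34.0, 6.0, 18.0, 60.0]
  maternal_paternal_age_corr: 0.7
  ses_paternal_age_corr: 0.0
  ses_effects: [0.0, 0.0]
  beta_pa_male: 0.0
  beta_pa_female: 0.0
  a0: 2.01
  d0: 0.0
  e0: 1.73
  b_gi_attain: 0.0
  direct_pa_attain: 0.0
  seed: 0
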