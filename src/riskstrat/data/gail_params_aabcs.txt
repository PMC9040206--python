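# Gail-model per-unit log relative risks and attributable-risk
# proportions for Asian-American women (AABCS recalibration of the Gail
# model; values as published for the Asian-American model, transcribed to
# 7 decimals).  The AABCS fit carries no age-at-first-birth x relatives
# interaction and no age-segment change in the biopsy coefficient, so the
# two segments share coefficients; the attributable risk differs by
# segment.  Swap this file to use another population's parameters.
format_version 1
population Asian.AABCS
coef.menarche.lt50 0.0749926
coef.biopsy.lt50 0.5526327
coef.first_birth.lt50 0.2763827
coef.relatives.lt50 0.7918563
coef.fb_rel_interaction.lt50 0.0
ar.lt50 0.5248019
coef.menarche.ge50 0.0749926
coef.biopsy.ge50 0.5526327
coef.first_birth.ge50 0.2763827
coef.relatives.ge50 0.7918563
coef.fb_rel_interaction.ge50 0.0
ar.ge50 0.4968360
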