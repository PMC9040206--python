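# riskstrat

Risk-stratified breast-cancer screening asks a simple question with several
competing answers: *which women should be flagged as high risk?* Four widely
used criteria — a positive first-degree family history, a 5-year absolute
risk ≥ 1.3% under the Gail (BCRAT-style) questionnaire model, a 5-year
absolute risk ≥ 1.3% under a 313-variant polygenic risk score (PRS), and
carriership of a protein-truncating variant (PTV) in nine breast-cancer
predisposition genes (*ATM, BRCA1, BRCA2, CHEK2, PALB2, BARD1, RAD51C,
RAD51D, TP53*) — select strikingly different sets of people. `riskstrat`
implements all four classifiers and the machinery to quantify their overlap
and agreement, exercised end-to-end on synthetic cohorts that emulate the
marginal structure of a large Asian breast-cancer case series.

It is aimed at statistical-genetics and cancer-epidemiology researchers who
want a tested, reusable implementation of:

* **PRS scoring** — plink `scoresum`-style weighted allele sums with
  orientation resolution and mean-imputation of missing dosages, then
  standardization against a control population: `z = (s − μ_ref)/σ_ref`.
* **PRS → absolute risk** — the iterative baseline-hazard calibration: per
  5-year age interval `[t, t+5)` solve `h₀(t)` from
  `h₀(t)·E_surv[exp(βz)] = λ(t)` (registry incidence), then deplete the
  survivor PRS distribution by the hazard `h₀(t)·exp(βz)`, so that
  higher-PRS women are removed faster as the cohort ages. The 5-year
  absolute risk at age *a* with relative risk *r* under competing
  mortality *m(t)* is the cause-specific cumulative incidence
  `∫ₐ^{a+5} r·h₀(t)·exp(−∫ₐᵗ [r·h₀(u)+m(u)]du) dt`,
  evaluated in closed form on piecewise-constant sub-intervals.
* **Gail model** — log-linear relative risks over menarche age, biopsy
  history, age at first live birth and first-degree relatives (with the
  age-50 segment split honoured *inside* the projection window), projected
  over attributable-risk-adjusted baseline hazards `λ(t)·(1−AR)`.
* **PTV carriership** — rule-based: nonsense SNVs, frameshift indels and
  splice-disrupting SNVs in the nine-gene panel, excluding last-exon
  variants (which are expected to escape nonsense-mediated decay).
* **Concordance** — pairwise Cohen's kappa, Spearman correlation and the
  Wilcoxon signed-rank test between the two absolute-risk scales, a full
  2⁴-region Venn decomposition, and incremental identification by 5-year
  age group as criteria are added (FH → Gail → PRS → PTV).

## Worked example

Run the whole pipeline on a simulated case series (a 20,000-strong source
population scored with the bundled synthetic 313-variant panel, from which
2,000 cases are drawn with probability ∝ exp(βz), β = log 1.61):

```sh
riskstrat report --config config.yaml
```

with `config.yaml`:

```yaml
outdir: demo_out
seed: 11
simulation: {n_population: 20000, n_cases: 2000}
```

Selected output (`demo_out/risk_comparison.tsv`, `kappa_matrix.tsv`,
`venn_all.tsv`):

```
spearman_rho          0.298
wilcoxon_p            1.8e-11
PRS  5-year risk %    median 0.9 (IQR 0.7-1.3)
Gail 5-year risk %    median 0.9 (IQR 0.6-1.2)
union of 4 criteria   918 of 2000 (46%)

criterion_a criterion_b     kappa    p_value
    fh_high   gail_high     0.644   2.8e-183
    fh_high    prs_high     0.014       0.50
  gail_high ptv_carrier    -0.010       0.57
   prs_high ptv_carrier     0.004       0.80
```

Reading it: the two absolute-risk scales rank women quite differently
(Spearman ρ ≈ 0.30) and their paired difference is systematically nonzero
(signed-rank p ≪ 0.001) even though both medians sit near 0.9%. The only
strongly concordant pair is the Gail model with family history (κ ≈ 0.64)
— unsurprising, since family history is itself a Gail input — while every
pair involving the genetic criteria (PRS, PTV) shows near-chance agreement
(|κ| < 0.05): the four criteria flag largely *different* women, which is
the substantive point of the analysis. `age_table.tsv` shows the
proportion identified rising monotonically as criteria are added within
each 5-year age group, and `venn_under50.tsv` repeats the overlap for
women below the usual screening entry age of 50.

Every table is reproducible bit-for-bit under the same `seed`. The other
subcommands (`simulate`, `score`, `calibrate`, `risk`, `classify`) expose
the individual stages on files; see `riskstrat --help`.

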