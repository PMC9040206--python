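# Methods

## Scope and model

`riskstrat` analyses a *case-only* cohort: every individual is a breast
cancer patient, and the question is which of four high-risk criteria —
family history (FH), Gail-model 5-year absolute risk, PRS 5-year absolute
risk, PTV carriership — would have flagged her, and how much the criteria
overlap. Absolute risks are evaluated at the age at diagnosis over a
5-year window.

### PRS scoring

The raw score is `s_i = Σ_j w_j d_ij` over a 313-variant panel, where
`d_ij` is the effect-allele dosage (sum semantics, matching plink's
`scoresum`; no averaging). Allele orientation is resolved per variant:
exact effect/other match, else the swapped orientation with the dosage
complemented (`d = 2 − d′`); variants matching neither orientation are
excluded with a logged count, and strand-ambiguous (A/T, C/G) variants
are matched as reported and flagged, since no strand information is
available in a plain dosage table. Missing dosages default to mean
imputation (`w_j · 2·freq_j` with `freq_j` estimated from non-missing
individuals — plink's default); an `omit` policy is available. Scores are
standardized against control-population statistics (sample SD, n−1
denominator); per-population references are supported with a pooled
fallback.

### Baseline-hazard calibration for the PRS

Registry incidence `λ_k` in interval `k` averages over the population PRS
distribution, so the hazard applicable at `z = 0` must satisfy
`h₀ₖ · E_k[e^{βz}] = λ_k`, where `E_k` is taken over women still
unaffected at the interval start. The survivor distribution is
represented on probabilists' Gauss–Hermite nodes (default 64; ≥ 64 nodes
agree with a 10⁵-point trapezoidal grid to better than 1e-8 relative on
`h₀`). Starting from the discretized standard normal, each interval
solves the fixed point above (converged to 1e-10 relative) and then
multiplies the node weights by `exp(−h₀ₖ e^{βz} Δt)` before
renormalizing. Competing mortality is PRS-independent and therefore
cancels from the normalized distribution. By construction the calibrated
hazards reproduce the input incidence exactly when re-averaged; the
package asserts this to 1e-6 relative at every interval. With β = 0 the
calibration returns the population incidence identically; the
first-interval closed form `h₀ = λ·e^{−β²/2}` follows from the lognormal
mean identity.

### Absolute risk under competing mortality

With piecewise-constant cause-specific hazard `h = r·h₀(t)` and
competing mortality `m(t)`, the 5-year cumulative incidence is summed in
closed form per sub-interval:
`Σ_j h_j/(h_j+m_j) · (1 − e^{−(h_j+m_j)Δt_j}) · S_j`, with `S_j` the
all-cause survival to the sub-interval start. Windows starting off a
5-year boundary are split at every rate-table edge; no rate interpolation
is performed (the tables are supplied, and treated, as piecewise-constant
5-year hazards). `h_j + m_j = 0` contributes zero risk. Results are
asserted to lie in [0, 1].

### Gail model

Relative risk is `exp(c_men·M + c_bio·B + c_fb·F + c_rel·R +
c_int·F·R)` with the standard BCRAT category scores (menarche ≥14/12–13/
<12 → 0/1/2; first birth <20/20–25/25–30 or nulliparous/≥30 → 0/1/2/3;
biopsy ever 0/1; first-degree relatives with breast cancer 0/1 — family
history is binary here). Unknown categories map to the reference
(lowest-risk) class, the convention of the BCRAT-style tools. The
coefficient set and attributable risk (AR) are segment-specific (<50 vs
≥50 attained age); the relative risk is re-evaluated on every
sub-interval so the segment change at 50 takes effect inside a
projection window. The baseline hazard is `λ(t)·(1 − AR)`. Bundled
parameters are the Asian-American (AABCS) recalibration, stored as a
plain key/value text file so another population's parameters can be
swapped in without code changes; the AABCS fit has no interaction terms,
so both segments share coefficients and differ only in AR.

The 1.3% screening threshold is the 5-year absolute risk of an *average*
50-year-old woman on US white-female reference rates — i.e. composite
incidence projected with relative risk 1 and AR = 0 (for the average
woman the factor `RR·(1−AR)` averages to one by the definition of AR).
On the bundled reference-rate fixture this evaluates to 1.23%, and the
threshold default is kept at the conventional 0.013 (configurable;
boundary inclusive, `risk ≥ threshold`, with a strict mode).

### PTV carriership

Purely rule-based on supplied annotations: consequence ∈ {nonsense SNV,
frameshift indel, splice-disrupting SNV}, gene in the nine-gene panel,
and not in the gene's last exon. The last-exon exclusion is applied to
all three truncating classes (variants escaping nonsense-mediated decay
are not expected to behave as loss-of-function). No pathogenicity
scoring is attempted.

### Concordance statistics

Cohen's kappa uses the standard 2×2 marginal chance correction with a
two-sided p-value from the large-sample null standard error (asymptotic
normal). Spearman's rho uses average ranks on ties. The Wilcoxon
signed-rank test drops zero differences, uses the exact null
distribution for n ≤ 25 without ties in |d| and the tie-corrected normal
approximation otherwise; the reported statistic is the positive-rank sum
W⁺. Constant raters with identical marginals, constant correlation
inputs and all-zero difference vectors return an explicit `degenerate`
status rather than a number. Venn regions are exhaustive disjoint counts
keyed by membership pattern. Incremental age-group proportions use bins
[30,35) … [70,75] (last bin closed at 75, matching a cohort diagnosed
between 30 and 75); out-of-range ages go to a warned overflow row. No
multiple-testing correction is applied across kappa pairs.

## Synthetic cohort generator

The generator emulates the marginal structure of a 7600-patient Asian
case series: category frequencies for menarche (29/52/11/8% incl.
unknown), first birth (4/19/30/24/17/5%), family history of breast
cancer (15%), ovarian cancer (2%), PTV carriership (5%), ethnicity
(75/15/8/1%) and case-type (59/41%); ever-biopsy is not reported in that
description, and its default (88/7/5%) is the package's own choice of a
plausible prevalence with an explicit unknown class. Ages at diagnosis
are truncated-normal, mean 52, SD 10.38 (matching median 52 and IQR
45–59), truncated to [30, 75]. Genotypes are Hardy–Weinberg draws (two
Bernoulli trials per variant) over a bundled synthetic 313-variant panel
(frequencies uniform on (0.05, 0.95), weights N(0, 0.06²), drawn once
and shipped as a labelled-synthetic fixture). Case sampling selects
`n_cases` without replacement with probability ∝ `exp(βz)` via the
Gumbel top-k construction (exactly sequential weighted sampling); in the
rare-sampling limit the selected `z` are N(β, 1), which the tests verify
at a 1% sampling fraction.

Deliberate simplifications: risk factors are mutually independent and
independent of the PRS (only marginals are targeted — no FH–PTV or
FH–Gail-input correlation beyond the structural one, so simulated
FH×Gail kappa is *higher* than in real data where the other Gail inputs
vary); the per-SD log odds ratio β defaults to log 1.61 ≈ 0.476, the
scale reported for 313-variant overall-breast-cancer scores; the
genotype-derived PRS is only approximately normal (313-term CLT), which
the calibration treats as exactly normal. Passing tests therefore
demonstrate correctness of the machinery under the stated generative
model, not the cohort-specific headline percentages of any real study,
which depend on restricted data.

Variant-annotation records are generated to be consistent with the
simulated carrier flags (one qualifying PTV per carrier, plus last-exon
and missense decoys), so the rule-based classifier is exercised
end-to-end rather than short-circuited.

## Bundled data files

* `prs_panel_synthetic.tsv` — synthetic 313-variant panel (see above).
* `singapore_rates_synthetic.csv` — hand-written approximations of
  Singapore female breast-cancer incidence (2013–2017 era) and non-breast
  mortality (2016 era), overall and per ethnic group, per 100,000
  person-years in 5-year intervals covering 30–80. Synthetic stand-ins,
  not registry extracts.
* `us_white_rates_synthetic.csv` — analogous approximations of SEER-era
  US white-female rates, used for the threshold identity.
* `gail_params_aabcs.txt` — AABCS Gail coefficients and ARs, transcribed
  from the published Asian-American model.

## Numerical and design choices

* Quadrature 64 nodes by default; configurable.
* Hazard unit convention: files carry rates per 100k person-years;
  everything internal is per person-year.
* Mortality column semantics: the tables carry a single competing
  (non-breast-cancer) mortality column; if only all-cause mortality is
  available the caller should subtract breast-cancer-specific mortality
  before writing the file.
* Reference-rate choice (overall vs ethnic-specific) is a config switch
  (`rates_population`), logged with the run.
* Pipeline determinism: one master seed, per-stage child seeds drawn
  below 2³¹; two runs with the same config produce byte-identical tables.
* Failure handling: any stage failure removes partial outputs and raises
  an error naming the stage.
* Problem sizes in the shipped tests (e.g. 10⁵-draw marginal checks,
  5×10⁶-population case-sampling recovery, a 7600-person end-to-end run)
  were chosen so each check's Monte-Carlo error is small relative to its
  tolerance while the full suite stays fast.

## Known limitations

No LD handling or genotype imputation (the panel is taken as given); no
lifetime or 10-year projections; no combined PRS×Gail model (the two are
deliberately analysed as separate classifiers); kappa p-values are
asymptotic only; the synthetic generator does not reproduce joint
risk-factor structure or real allele frequencies, and bundled rate
tables are approximations intended for testing and worked examples, not
for clinical use.
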