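# Methods

## Scope and design

`gxepi` implements the analysis pipeline of a frequency-matched
case–control study of gene–adiposity interaction in five layers:

1. **synthetic cohort** (`gxepi.simulate`, `gxepi.config`) — a generative
   population model plus outcome-dependent sampling;
2. **contingency statistics** (`gxepi.tables`) — crude ORs, χ², t,
   allele frequencies, Hardy–Weinberg testing, descriptives;
3. **logistic engine** (`gxepi.logistic`) — design building, a
   Newton–Raphson MLE, Wald inference, trend tests;
4. **interaction measures** (`gxepi.interaction`) — joint-indicator
   coding, RERI/AP/S/ROR with delta-method CIs, bootstrap oracle;
5. **orchestration** (`gxepi.pipeline`, `gxepi.cli`) — the full table
   bundle and a thin CLI.

The estimation layers follow the statsmodels idiom: a model object built
from data (`LogisticModel.from_dataframe`, `JointEffectModel`) whose
`fit()` returns a results object carrying estimates, covariance,
diagnostics and a `summary()`.

## The generative model and what it emulates

The generator draws a source population of women and only afterwards
samples cases and controls, because outcome-dependent sampling leaves odds
ratios invariant (only the logistic intercept shifts); this reproduces the
case–control design faithfully rather than simulating the analysed sample
directly.

* **Genotypes.** Each SNP draws two independent alleles at its configured
  minor-allele frequency, so genotype proportions are Hardy–Weinberg
  ((1−q)², 2q(1−q), q²). Defaults are the control-derived frequencies of
  the three study SNPs (0.2544, 0.2859, 0.3299). Genotypes are independent
  of adiposity by default; the study's causal picture does not require the
  obesity-associated variants to shift measured adiposity, and keeping
  them independent makes the configured exposure ORs exact. A dependence
  could be layered on via `disease_log_or`-style extensions, but is
  deliberately not a default.
* **Adiposity.** BMI, WC and WHR share a latent standard-normal score
  (correlation 0.7 between the latent and each index-specific score), and
  each index is an affine transform of its score with SD 3.3 kg/m²,
  9 cm and 0.06 respectively, located so that P(index ≥ binary cutoff)
  equals the configured prevalence (defaults 0.48/0.62/0.55, the control
  rates of the study population). Lower education and income tilt the
  latent score upward slightly (+0.15 SD for the lowest education band,
  −0.10 SD per log-income SD), so exposure–confounder correlation exists
  by default; the marginal prevalences remain approximately the configured
  values because the shifts are small.
* **Disease.** Logistic with the four joint-exposure cells of the
  configured SNP grouping and adiposity index:
  `logit p = logit(baseline_risk) + ln(or_geno)·1[G,¬E] + ln(or_env)·1[¬G,E]
  + ln(or_joint)·1[G,E]` plus optional covariate effects. By default
  `disease_log_or` is empty: the confounders correlate with exposure but
  not with disease, so the configured ORs are simultaneously the
  conditional and the marginal truth and no noncollapsibility bias enters
  the calibration experiments. Confounded scenarios (e.g. family-history
  log-OR 0.7) are opt-in and exercised in tests.
* **Matching.** All cases are kept (optionally thinned to a target count,
  default 818); controls are drawn without replacement within half-open
  age bands `[anchor + 5k, anchor + 5(k+1))` anchored at the minimum case
  age, allocated proportionally to case counts × `control_ratio` (default
  935/818) with largest-remainder rounding. Bands short of controls are
  refilled best-effort from the remaining pool, with a warning and a
  `SamplingReport` record.
* **Missingness.** Optional per-field independent masking emulates the
  per-variable incompleteness visible in real descriptive tables; `id`
  and `case_status` can never be masked.

What the generator does **not** emulate: genotyping error and call-rate
QC, recruitment-refusal mechanisms, measurement error in anthropometry,
secular or regional structure, and linkage between SNPs. Passing tests
therefore demonstrate the correctness and calibration of the *statistics*
under the study's design assumptions, not robustness to those data
pathologies.

## Numerical choices

* **MLE.** Newton–Raphson on the Bernoulli log-likelihood with
  step-halving whenever a full step would decrease it, so the likelihood
  path is non-decreasing by construction. Stop when max|score| < 1e−10
  (the tight stop makes the saturated-2×2 fit agree with the crude
  cross-product OR to better than 10 significant figures), cap 50
  iterations. Covariance is the inverse observed information at the
  optimum. Coefficients exceeding |β| > 15 are treated as diverging
  (complete or quasi-complete separation); the fit is flagged
  non-converged and the offending terms are named, never "fixed".
* **Complete-case handling** is per fitted model: rows missing any
  referenced field are dropped and counted, mirroring per-variable
  denominators in descriptive tables.
* **Adjustment presets.** `model1` = age (continuous), education, marital
  status, residence (categorical), income (continuous); `model2` adds
  hormone-drug use, family history (categorical) and moderate exercise.
  Exercise enters as a continuous 0–3 band score by default — the natural
  reading of an "hours/week" variable recorded in ordered bands — and can
  be recoded categorically through `Term`.
* **Trend tests** use the ordinal-score Wald z² (the exposure enters as a
  single 0,1,2,… score next to the adjustment set) rather than
  Cochran–Armitage; with covariate adjustment in play the model-based
  test is the coherent choice.
* **Crude OR CIs** are Woolf (log-scale) with z = 1.96, matching the Wald
  intervals used everywhere downstream; zero cells get the 0.5 continuity
  correction and a flag.
* **HWE** is the asymptotic 1-df χ² with the allele frequency estimated
  by counting, not an exact test. On one of the three sets of published
  control genotype counts (428/381/114) this test gives p ≈ 0.044,
  marginally below 0.05; the exact test or a different convention would be
  needed to reproduce a "conforms" verdict there, and the package
  documents rather than hides this sensitivity.
* **Delta method.** With β₁, β₂, β₃ the indicator coefficients and Σ
  their covariance block, each measure's variance is gᵀΣg at the MLE:
  RERI gradient (−OR₁₀, −OR₀₁, OR₁₁); AP gradient
  (−OR₁₀/OR₁₁, −OR₀₁/OR₁₁, (OR₁₀+OR₀₁−1)/OR₁₁); ln S gradient
  (−OR₁₀/D, −OR₀₁/D, OR₁₁/(OR₁₁−1)) with D = OR₁₀+OR₀₁−2. RERI and AP
  intervals sit on the natural scale, the S interval on the log scale
  (standard for ratio measures), ROR is a Wald interval on β₃−β₁−β₂. S is
  reported undefined (NaN, flag false) when D ≤ 0 or OR₁₁ ≤ 1.
* **Rounding** in rendered tables is half-up (ORs two decimals,
  percentages one); full precision is kept internally.
* **Determinism.** Every stochastic routine takes a seed or Generator;
  replicate experiments spawn independent child streams from a
  `SeedSequence`, and a fixed configuration reproduces byte-identical
  cohort CSVs and report bundles.

## Calibration experiments and problem sizes

The validation layer (`gxepi.validation`) fixes the study conditions for
the calibration checks: additive-null configuration with genotype-group
prevalence 0.3 (dominant coding at q = 1−√0.7), adiposity prevalence 0.4,
baseline risk 0.05 and ORs 1.5/2.0/2.5 (= 1.5+2.0−1).

* Null calibration: 200 replicates of a 200,000-woman population, each
  analysed as all cases (~15,000) plus equally many matched controls;
  mean RERI and mean S are required to sit within 3 Monte-Carlo SEs of 0
  and 1.
* Coverage: 500 replicates analysed at ~2,000 subjects (1,000 cases +
  1,000 controls); 95% delta RERI intervals must cover 0 in 93–97% of
  replicates.
* Delta vs bootstrap: one n = 5,000 sample, 2,000 stratified bootstrap
  refits; CI endpoints must agree within 15% of the CI width.
* Parameter recovery: 200 replicates at population 50,000; mean estimated
  log-ORs within 3 Monte-Carlo SEs of the configured values.

These sizes are the package's chosen balance between Monte-Carlo
resolution and a test suite that runs comfortably on a single CPU.

## Known limitations

* Wald/delta inference throughout; no likelihood-ratio or profile
  intervals, no Firth correction for separation, no exact HWE or Fisher
  tests, no conditional logistic regression, no multiple-imputation.
* No multiple-testing adjustment across SNP × index pairs, matching the
  analysed study's convention; interpret the nine interaction tables
  accordingly.
* Additive-scale measures computed from case–control ORs inherit the
  usual rare-disease interpretation; the package does not estimate
  risk-difference interaction from cohort data.
* The synergy index is numerically fragile when the single-exposure ORs
  are near 1 (denominator near 0); its log-scale CI can be extremely wide
  in moderate samples, which is faithful to the estimator rather than a
  defect.
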