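# Methods

## Model

The severity model is a linear structural equation model over nine
observed clinical-outcome scores `y` and three latent variables
`η = (Communication, Comorbidities, Global)`:

```
y = ν + Λ η + ε,   ε ~ N(0, Θ_ε) diagonal
η = B η + ζ,       ζ ~ N(0, Ψ)
```

Each observed variable reflects exactly one latent (Communication:
clinician communication domain, CSBS total; Comorbidities: insomnia,
daytime sleepiness, seizures, alertness; Global directly: motor, vision,
feeding).  In the default structure the two exogenous latents covary
freely and both feed Global through free structural coefficients; Global
carries a free disturbance variance.  Identification is by unit
first-loading: motor for Global, insomnia for Comorbidities, the clinician
communication domain for Communication.  This keeps loadings, factor
scores and derived weights on the indicators' (harmonized 0–100) scale.

The exact orientation of the severity construct is genuinely open — the
exogenous/endogenous labelling admits either two sub-latents driving a
global latent, or a second-order latent driving the sub-latents.  Both
structures parse and fit through the same reduced-form code path
(`V_η = (I−B)⁻¹ Ψ (I−B)⁻ᵀ`), and the alternative ships as
`second_order_model.yaml`; the default is the exogenous-pair structure and
neither is asserted as uniquely correct.

Free parameters (default structure): 6 loadings + 2 structural
coefficients + 4 disturbance (co)variances + 9 residual variances +
9 intercepts = 30; with 9 means + 45 covariances modelled, df = 24.

## Estimation

The observed-data (FIML) log-likelihood sums, over subjects, the
multivariate-normal log-density of each subject's observed subvector under
the correspondingly subset μ(θ), Σ(θ).  Rows are grouped by missingness
pattern and represented by sufficient statistics (count, mean, scatter),
which changes the cost, never the value; a property test asserts equality
with naive per-row evaluation to 1e-8.

Maximization uses L-BFGS-B with an analytic gradient (each free parameter
perturbs Σ through a rank-one or rank-two symmetric update).  Because raw
scores live on a 0–100 scale while loadings are O(1), the optimizer works
on internally standardized data: every variable is centred and scaled by
its available-case moments, latents are rescaled by their anchor-indicator
SDs so fixed unit loadings stay fixed, and estimates are mapped back to
raw units afterwards.  This is an exact reparameterization chosen purely
for conditioning.

Numerical choices:

- start values: free loadings 1, structural coefficients 0.5, residual
  variances half the available-case variances, latent variances half the
  anchor indicator's variance, intercepts at available-case means;
- convergence: projected-gradient tolerance 1e-6 and relative
  function tolerance 1e-13, iteration cap 500; the convergence flag,
  iteration count and optimizer message are recorded in every `FitResult`;
- admissibility: variance parameters are bounded below at 1e-8, so a
  negative-variance solution surfaces as a boundary estimate with a
  warning; a non-positive-definite implied pattern submatrix yields a
  -inf likelihood (penalized), not a crash;
- non-convergence is flagged in the result, never silent.

Reference models for fit indices:

- *saturated*: unstructured mean and covariance, maximized by an EM
  algorithm for the multivariate normal with missing data (closed form
  when data are complete), iterated to an absolute log-likelihood
  tolerance of 1e-10.  An oracle test checks EM against the closed-form
  factorized MLE for bivariate monotone missingness.
- *baseline*: independence model with free means and variances; under a
  diagonal covariance the FIML likelihood factorizes per variable, so its
  MLE is each variable's observed-data mean and ML variance.

Indices: χ² = 2(ℓ_sat − ℓ_model) (clipped at 0),
RMSEA = √(max(χ²−df,0)/(df·(n−1))), CFI = 1 − max(χ²−df,0)/max(χ²_b−df_b,
χ²−df, 0), TLI = ((χ²_b/df_b)−(χ²/df))/((χ²_b/df_b)−1), reported uncapped
and undefined (NaN with a warning) when χ²_b/df_b ≤ 1.  The RMSEA
denominator uses n−1 by default; software conventions differ and an `n`
option is provided (the difference is below 0.3% at n ≈ 200).

Standard errors for θ are not computed; the deliverables are point
estimates, fit indices and scores.

## Scores and weights

Factor scores are regression-method scores generalized to missingness
patterns: E[η | y_obs] = V_η Λ_oᵀ Σ_oo⁻¹ (y_o − μ_o).  Any subject with at
least one observed indicator gets a score; a subject with none gets NaN.
Each latent is sign-oriented so a larger score moves its anchor indicator
in the severity direction.  Global scores are standardized to mean 0 /
SD 1 (n−1 denominator) over the fitted cohort.

Harmonization maps every raw score linearly to 0–100 with higher = more
severe: `x' = 100(x−min)/(max−min)`, flipped for variables whose raw
direction is higher-is-better.  Directions and ranges are configuration;
the shipped defaults mark the clinician/caregiver assessments and the
sleep questionnaire as higher-is-better and the CSBS total (0–57) as
higher-is-more-severe, matching the study cohort's data dictionary rather
than the instruments' original manuals — published conventions for CSBS
and QoL differ between sources, which is exactly why the flags are
per-variable options.

Weights are the slopes of a complete-case OLS regression of the
standardized global factor score on the nine harmonized indicators,
rescaled by their sum (intercept discarded).  The weight regression is run
on harmonized variables by default (the unit-sum weighted average is only
meaningful when components share a scale); negative slopes are kept but
warned about.  The shipped published default weights sum to 0.999 as
printed (rounding); they are renormalized by their sum at load, preserving
the printed ratios.  Scoring a profile with missing components refuses by
default and names the absent components; an explicit `renormalize` policy
reweights the present ones, documented as an extrapolation beyond the
published procedure.

## Validation statistics

- Pearson correlations use pairwise-complete observations (each correlate
  reports its own n) with Fisher-z 95% intervals.
- The age-group comparison is a Welch two-sample t-test by default, with a
  pooled-variance option.
- Test–retest reliability is ICC(A,1): two-way mixed effects, absolute
  agreement, single measurement, computed from the two-way ANOVA mean
  squares, with the F-distribution 95% CI and bands poor < 0.5,
  moderate 0.5–0.75, good 0.75–0.9, excellent > 0.9.  The ICC form is not
  uniquely implied by the bands alone, so the chosen form is printed in
  every result; a one-way random-effects form is available as an option.
  Degenerate perfect-agreement tables return ICC = 1 with a (1, 1)
  interval.

## Synthetic cohort generator

The generator emulates the data structure the analysis assumes:

- latents: Communication and Comorbidities are bivariate normal (unit
  variances, covariance 0.45); Global = 0.65·Communication +
  0.45·Comorbidities + ζ with Var(ζ) set so Global has unit variance;
- indicators: loading × latent + residual, with loadings strong for motor
  and the communication pair and residuals largest for the sleep domains,
  so the derived-weight ordering (motor largest, sleep smallest) emerges
  from structure rather than from hard-coding;
- bounded scales: indicators are generated on the latent-linear scale and
  affinely mapped into their ranges (centre of range, three SDs to the
  nearest bound) then clipped; the clipping fraction is tracked and stays
  below 1% under the defaults.  `bounded=False` skips the mapping for
  parameter-recovery experiments where generating loadings must be
  directly comparable to fitted ones;
- missingness: instrument-block MCAR — all domains of a questionnaire are
  missing together — at the study's per-instrument rates (caregiver 4%,
  CSBS 20%, clinician 28%, QoL 30%, sleep 39%, EEG present for ~45/206);
- retest: each indicator's residual splits into a stable specific part
  plus occasion noise of SD `retest_noise_sd` (default 0.15 latent-linear
  units).  Cross-sectional moments are unchanged by the split, while
  test–retest reliability becomes 1 − σ_occ²/Var(indicator) — about
  0.95–0.99 per component under the defaults, emulating the high
  reliability of repeated COA administration.  Setting it to 0 reproduces
  baseline exactly (ICC = 1); `None` redraws the full residual.  The
  retest subgroup (18 of 206 by default) is drawn among complete-case
  subjects when possible, emulating complete test–retest assessment sets;
- external correlates are generated to hit target correlations with the
  latent Global (defaults: EEG alpha/delta 0.61, theta/delta 0.50, QoL
  0.68, behavior −0.21) on plausible raw scales; closed-form implied
  correlations (including the attenuated correlation of a weighted
  composite) are provided for oracle tests;
- age group (51.5% under 7) and sex (82% female) are decorative: unrelated
  to the latents, so the age t-test should be null — a type-I-error
  simulation in the tests confirms the rejection rate is near nominal.

What the generator does **not** emulate: floor/ceiling pile-ups beyond
mild clipping, non-normal latents or skewed score distributions,
informative (MAR/MNAR) missingness, age- or sex-dependent severity, and
item-level structure within instruments.  Passing tests therefore
demonstrate correctness of the estimation machinery under the model's own
assumptions, not robustness of the severity construct on real clinical
data.

## Inclusion rule

Subjects enter the fit with two or more reported scores.  Whether "two or
more" counts the nine variables or the distinct instruments is ambiguous
in prose descriptions of such rules; the default counts variables, and an
instrument-level option is provided.

## Problem sizes

The test suite exercises cohorts of 60–1000 subjects (50 replicates for
parameter-recovery and fit-index calibration at n = 1000) and up to
20,000 subjects for moment-recovery checks; the acceptance script runs the
full pipeline at the study scale of 206 subjects.  These sizes give Monte
Carlo error comfortably below the asserted tolerances while keeping a full
run to a few minutes on one CPU.

## Known limitations

- No standard errors, modification indices, robust estimators or
  bootstrap intervals.
- The FIML baseline/saturated references assume multivariate normality;
  indices inherit that assumption.
- The EM saturated fit can be slow in principle for pathological
  missingness patterns (many distinct patterns); instrument-block
  missingness keeps the pattern count small here.
- The weighted-average score is only a faithful stand-in for the factor
  score when all nine components are present; the renormalization policy
  for partial profiles is an undocumented extrapolation and flagged as
  such.
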