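# Methods

This note documents the statistical model behind `brainmetab`, the
numerical choices made where the design was genuinely open, what the
synthetic cohort generator does and does not emulate, and the known
limitations.

## Data model and preprocessing chain

The unit of analysis is an analyte (a measured metabolite or a calculated
indicator) in one brain region. Raw inputs are non-negative abundances
(area ratios or µM) over samples; samples carry group (CTRL, PD-CN,
PD-MCI, PD-D, or QC), region (cortex, putamen), plate, covariates and
optional progression scores. The preprocessing order is fixed:

1. **Quantification.** conc = ratio × expected QC concentration / median QC
   ratio, per analyte. Analytes without an expected concentration or with a
   zero QC median pass through as area ratios and are flagged. Blank
   signals are rescaled by the same factors so LODs stay comparable.
2. **LOD.** LOD = 2 × median blank signal. An analyte is removed only when
   strictly more than 50% of its values are below LOD in *every* subject
   group (QC excluded) — a compound detectable in any one group is kept.
   Retained sub-LOD values are not modified: they remain the best available
   estimates, and censoring-aware imputation would distort the medians the
   normalization depends on.
3. **Zeros.** Exact zeros become half the analyte's minimal non-zero value
   (an all-zero analyte is flagged and dropped); downstream transforms
   require positive values.
4. **Indicators.** Sum indicators add their member metabolites; ratio
   indicators divide numerator sum by denominator sum, with a zero
   denominator producing a missing value. Missing members propagate
   (no silent partial sums within a sample). By default indicators are
   computed from plate-raw values and then plate-normalized themselves;
   computing them from already-normalized metabolites is available via
   `PipelineConfig(indicators_from_normalized=True)` — the two differ only
   through the ratio of plate quotients, and the default keeps the
   indicator's own quotient estimable and reportable.
5. **Plate normalization.** See the README for the equations. Groups whose
   median is zero are excluded from the reference set; a plate with no
   finite reference keeps quotient 1. The map x → y is exactly
   scale-equivariant (x → c·x gives y → c·y). It is *not* exactly
   idempotent: re-running it on its own output moves the quotients slightly
   off 1 (zero for symmetric instances, typically below a few percent for
   balanced cohorts), because second-pass group medians mix plates.
6. **Box-Cox.** λ maximizes the profile log-likelihood over [−3, 3]
   (bounded scalar minimization, tolerance 1e-4; no shift parameter since
   inputs are positive by construction). λ is weakly identified when the
   coefficient of variation is small — harmless here, as near-affine
   transforms are near-equivalent after standardization. Constant vectors
   get λ = NaN and are flagged downstream.
7. **Tukey fencing** on the transformed scale with k = 3: values outside
   [Q1 − 3·IQR, Q3 + 3·IQR] are moved to the fence, never removed, bounding
   the influence of extremes without shrinking n or the variance the way
   removal would.
8. **Standardization** to the region's control mean and SD (z-scores).
   Analytes with fewer than 3 finite controls or zero control SD are
   flagged and excluded from modeling.

Quantiles (Tukey quartiles, the DOPA threshold) use linear interpolation
between order statistics (type 7), the numpy/R default.

**Covariate imputation.** Missing BMI and education are filled with the
(group, sex)-conditional mean, falling back to the group mean and then the
overall mean, each fallback logged. Nothing else is ever imputed.

**Acute levodopa state.** Per region, the threshold is the 95% quantile of
the controls' plate-normalized (pre-standardization) DOPA; a PD sample is
L+ iff its DOPA strictly exceeds it (ties → L−). Controls are never
flagged. Two consequences worth keeping in mind: by the quantile
construction, up to ⌈0.05·(n−1)⌉ controls sit above their own threshold
(2 of 36 = 5.6%); and since physiological-DOPA PD samples are drawn from
the control distribution, about 5% of them are unavoidably mislabeled L+,
which attenuates estimated levodopa interactions by roughly 5–8%.

## Regression models

**Differential model** (per analyte, per region): standardized value ~
group indicators (PD-CN, PD-MCI, PD-D against the control baseline, or one
all-PD indicator) + L+ × PD-ND + L+ × PD-D (the dementia interaction only
where demented subjects exist, i.e. cortex) + age + sex + education + BMI +
hyperlipidemia + diabetes + renal insufficiency + hypothyroidism +
log(post-mortem interval) + log(storage years). The log transforms let the
time covariates capture exponential decay. Betas read as control-SD
differences adjusted for covariates.

**Heteroscedasticity.** Residual variances differ by subject group.
Estimation is classical two-step feasible GLS: OLS, then per-group
variances σ̂²_g = RSS_g / (n_g − Σ_{i∈g} h_ii) with OLS leverages h_ii
(unbiased under homoscedasticity), then one weighted solve with weights
1/σ̂²_g. Iterating the weights to convergence is available
(`max_iter > 1`, variances floored at pooled/`max_variance_ratio`) but is
*not* the default: with p = 14 design columns and a 14-subject group, an
upweighted group can be interpolated by the fit, so iteration drives its
variance estimate toward zero and fabricates arbitrarily extreme
t-statistics. Monte-Carlo calibration of the two-step default at the
study's group sizes gives type-I error 0.047–0.054 at α = 0.05 for every
term family.

**Inference.** Per-coefficient Wald t with Welch–Satterthwaite effective
degrees of freedom assembled from the group-variance dfs (Var(β̂_j) =
Σ_g a_jg σ̂²_g with a_jg from the weighted projection). This matters for
contrasts carried by small groups, where n − p overstates the information;
`df_method` can be set to `"residual"` (n − p) or `"normal"`. With
`variance_groups=None` the fit is exactly OLS.

**Progression model**: covariates for all subjects, a PD-membership
indicator, and score regressors equal to (score − mean_PD)/SD_PD for PD
subjects and 0 for controls — controls sharpen the covariate estimates
without contributing to the score effect, and the score coefficient is
two-way standardized by construction (invariant to affine rescaling of the
raw score). PD subjects missing a score are dropped from that score's
models only. Several scores can be fitted jointly (`combined=True`) for
mutually adjusted effects.

**Cohort characteristics**: heteroscedastic one-way ANOVA (joint Wald test
on the group terms of the FGLS fit) for continuous variables; two-tailed
Fisher's exact test for binary ones (2×2 via scipy, 2×k by exact
Freeman–Halton enumeration over fixed margins). All-groups and
PD-groups-only variants. Welch's t-test is provided for L+/L− score
comparisons.

**Collinearity screen**: pairwise Pearson |r| over continuous regressors
and Fox–Monette generalized VIFs per term (the three group dummies form
one df = 3 term), adjusted as GVIF^(1/(2·df)), with limits 0.6 and 1.5.
The L+ × PD-D indicator is nested inside the PD-D dummy, so its adjusted
GVIF hovers around 1.5 by construction — the report shows it; it is not
evidence of a data problem.

## FDR control

Storey q-values: q_i = min_{p_j ≥ p_i} π̂₀ · m · p_j / rank(p_j), monotone
in p and order-invariant; with π̂₀ = 1 this is exactly Benjamini–Hochberg.
π̂₀ smooths π̂₀(λ) = #{p > λ}/(m(1−λ)) over λ = 0.05…0.95 with a cubic
least-squares fit evaluated at λ = 0.95, clipped into (0, 1]. Below 100
tests π̂₀ is fixed at 1: the tail count behind π̂₀(0.95) has sampling SD
≈ √(π₀/(0.05·m)) — about 0.8 at m = 30 — and an extrapolated smoother can
collapse a whole stratum's q-values toward zero on pure noise. Runs are
stratified per coefficient family and per (LC/FIA × measured/calculated);
mixed-method indicators sit in the FIA stratum (conservative choice, since
FIA is the noisier arm).

## Set enrichment

Member p-values from the covariate-adjusted models are tested against
Uniform(0,1) with D⁺ = max_i (i/n − p_(i)) (right-continuous ECDF for
ties). The tail is exact (Birnbaum–Tingey, `scipy.stats.ksone`) for
n ≤ 10 and asymptotic exp(−2nD⁺²) above; at n = 50 the two agree within
~15% near the null mode. Mapping is many-to-many (a measurement that may
be any of several isoforms joins every pathway of every isoform), a custom
microbial set can be appended, only sets with ≥ 4 mapped members are
tested, and members without a fitted p-value are excluded with the size
recounted. Set-level FDR uses the same q-value machinery. Enrichment is
computed per region.

## AUC analysis

Dementia label: PD-D = 1 versus PD-CN/PD-MCI = 0 (MCI counts as
non-demented). AUC is the Mann–Whitney probability with ties counted ½;
variance by DeLong's placement-value estimator; 95% CI = AUC ± 1.96·SE
clipped to [0, 1]; orientation corrected so AUC ≥ 0.5. Strata: all PD,
L+ only, L− only; a stratum needs ≥ 3 subjects per class. Ranking breaks
AUC ties by narrower CI, then analyte id.

## Synthetic cohort generator

The generator emulates the study structure: 36/14/19/32 cortex subjects
(CTRL/PD-CN/PD-MCI/PD-D) on two plates, 35/14/19/0 putamen subjects on
one plate, QC repeats on every plate, blanks; covariates and progression
scores drawn near the cohort's group-wise means/SDs, with realistic
missingness in UPDRS-M, MMSE, BMI and education. Abundances are
log-normal; on the log scale the mean is shifted by planted group,
levodopa (L+ subjects of the targeted class only) and score effects, all
expressed in control-SD units so that the near-log Box-Cox transform plus
control standardization makes regression coefficients recover them
directly. Residual SD scales per group; per-analyte plate factors are
log-normal (σ = 0.15); a DOPA analyte separates L+ from L− subjects by 4
control-log-SDs; L+ status is assigned independently of progression scores
(probability 0.5); blanks are written so that 2 × median(blank) equals the
analyte's empirical `lod_censor_quantile` (default 2%). A single seed
drives everything through spawned per-analyte RNG streams, making cohorts
bit-for-bit reproducible.

What it does *not* emulate: between-analyte correlation (independent by
default; an optional block-correlation knob exists but no claim is made
that it matches real covariance), within-plate drift, censoring mechanisms
other than the LOD mark, non-log-normal abundance shapes, and any relation
between levodopa dosage and DOPA level. Passing recovery tests therefore
demonstrates correctness of the statistical machinery under the stated
generative assumptions, not robustness to their violation.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` use desk-scale problem sizes:
FGLS calibration over 1000 null analytes at the cohort's design; recovery
of a planted 1.0 control-SD dementia effect over 200 six-analyte cohorts;
levodopa-interaction power and AUC ranking over 100 twelve-analyte cohorts
(DOPA + the planted analyte + 10 nulls); KS calibration over 10⁴ ten-member
null sets. For a lone planted signal the FDR detection burden grows with
the number of co-tested nulls (q ≤ 0.05 needs p ≲ 0.05/m), so the power
figures are specific to the twelve-analyte cohorts; real strata with many
true effects share that burden.

## Known limitations

- The levodopa state is estimated, not observed; its ~5% false-positive
  rate attenuates interaction estimates (see above) and no
  measurement-error correction is applied, matching the source procedure.
- Group-variance estimation is honest but noisy at n_g ≈ 14; the
  Satterthwaite df protects test size at the cost of some power.
- The plate normalization is a one-pass estimator; its quotients are
  consistent under a multiplicative batch model but the procedure has no
  exact fixed-point property.
- Regions are modeled independently; shared-subject correlation between
  cortex and putamen samples is not exploited (no mixed effects).
- π̂₀ estimation requires ≥ 100 tests per stratum; smaller strata get
  conservative BH behavior.
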