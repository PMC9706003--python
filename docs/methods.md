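# Methods

## Scope and data model

The package implements the full analysis pipeline for a pediatric
tacrolimus population-PK study: event-table I/O, the structural and
covariate model, FOCE-ELS estimation, stepwise covariate selection,
simulation-based qualification, and a machine-learning stage that
predicts individual clearance from the screened covariates. Because no
patient-level data are deposited, a synthetic-cohort generator defines
the study conditions; every calibration and recovery claim in the test
suite is made against data simulated by that generator.

Estimation datasets are NONMEM-dialect tables (`ID, TIME, AMT, DV,
EVID`, optional `MDV`) with subject-constant covariate columns. Doses
are in µg, times in hours since each subject's first dose, and
concentrations in µg/L of whole blood. Genotypes are stored as text
calls (`"*1/*3"`, `"GA"`); derived 0/1 indicators (`CYP3A5_33`,
`CTLA4_GA`, `CTLA4_AA`) are materialized on demand. Missing covariates
required by an active model raise; others pass through untouched.

## Structural model and parameterization

One-compartment, first-order absorption and elimination, all parameters
apparent (CL/F, V/F); Ka is fixed at 4.48 h⁻¹ and never estimated. The
closed-form biexponential is the production path; numerical integration
of the gut/central ODE system is used only as a test oracle (agreement
to 1e−6 relative). When |Ka − k| < 1e−8·Ka the code switches to the
continuous limit D·Ka·t·e^(−k·t)/V. Multiple dosing uses superposition;
the prediction engine compresses dosing histories into runs of equal
amount and uniform interval and evaluates the geometric-series partial
sums, so a 100-dose q12h history costs a handful of terms per
observation.

Continuous covariates enter as power functions normalized to the cohort
median (the median — age 5.3 y — is frozen into a fitted model rather
than recomputed at prediction time); categorical covariates as
exp(θ·indicator). Between-subject variability is log-normal on CL and V
with a diagonal Ω (the study reports no CL–V correlation). Residual
models: additive, proportional, combined, and exponential; the
exponential model is fitted by log-transforming both sides, and its
objective includes the Jacobian term 2·Σ log y so that −2LL and AIC are
comparable across residual models on the concentration scale.

## FOCE-ELS estimation

Per subject, an inner optimization finds the conditional mode η̂ of the
random effects, and the marginal −2LL contribution is

    Σ_j [log(2π R_ij) + (y_ij − f_ij(η̂))² / R_ij]
      + η̂ᵀΩ⁻¹η̂ + log|Ω| + log|JᵀR⁻¹J + Ω⁻¹|,

with J = ∂f/∂η at η̂ and R evaluated at the conditional prediction
(interaction). For models linear in η with additive error this is the
exact marginal −2LL (verified to machine precision); on small nonlinear
instances it agrees with adaptive Gauss–Hermite quadrature to the 1e−3
level.

Numerical choices that matter:

- The inner solve is a vectorized damped Newton across all subjects.
  Prediction derivatives with respect to η are analytic (for C = h(k)/V
  with k = CL/V, ∂C/∂η_V = −C − ∂C/∂η_CL, so one extra geometric sum
  yields the full Jacobian); the per-subject 2×2 Hessian is taken by
  central differences of that analytic gradient, which captures the
  ∂R/∂η terms that a Gauss–Newton Hessian misses — those dominate for
  subjects whose conditional predictions approach zero under
  proportional error.
- Convergence: per-subject gradient below 1e−8·max(1, |g|). Stragglers
  are polished individually by a full-Newton refinement; a subject whose
  warm-started mode ends worse than η = 0 is re-solved from zero (warm
  starts across outer iterations can otherwise strand a subject on the
  wrong side of a stiff region).
- The outer problem minimizes the summed OFV by L-BFGS-B on transformed
  coordinates (log for positive parameters, identity for covariate
  coefficients) with finite-difference gradients (step 1e−5). Because
  line searches on this stiff surface occasionally terminate early, the
  optimizer is restarted (fresh quasi-Newton memory) while the end-point
  gradient exceeds 1, up to twice by default.
- Standard errors come from the inverse finite-difference Hessian of the
  OFV at the optimum (covariance = 2·H⁻¹), delta-method-transformed to
  the natural scale; CV% = 100·SE/|estimate|.
- Default initial values are data-driven: CL₀ = median(dose/(12·C)) from
  the steady-state relation, V₀ = CL₀/0.06 h⁻¹ (≈12 h half-life),
  covariate coefficients 0, moderate generic variances.

η shrinkage is 100·(1 − SD(η̂)/ω). GOF quantities: PRED (prediction at
η=0), IPRED (at η̂), and CWRES — the FOCE-linearized decorrelated
residual L⁻¹(y − (f(η̂) − Jη̂)) with LLᵀ = JΩJᵀ + R.

## Covariate search

Forward inclusion accepts, per round, the candidate with the largest
OFV drop if it exceeds 3.84 (χ², df=1, p<0.05), repeated to exhaustion;
backward elimination then deletes, least-significant first, any term
whose removal raises the OFV by at most 6.63 (p<0.01), iterated to
stability. The forward and backward phases run once each (the study
protocol does not state iteration; a single alternation is the common
reading and is deterministic). Candidate order is fixed: clinical
covariates (age, weight, sex, albumin, hematocrit, Wuzhi) before SNPs in
panel order. Non-converged candidate fits count as "no improvement".
Within one search, fits are memoized by covariate-term set, so backward
eliminations of recently added terms replay the forward fits exactly.

Multi-level genotypes enter as indicator blocks against the
major-homozygote reference, added and removed jointly but judged by the
scalar df=1 thresholds (the fitted model keeps the CTLA4 GA and AA
indicators as a block even though the AA bootstrap interval spans
zero). CYP3A5 is coded as the field-standard expresser/non-expresser
binary. The univariate SNP pre-screen is a Kruskal–Wallis test of
per-subject dose-normalized trough means across genotype groups at
α = 0.1; monomorphic loci are excluded and logged.

In recovery experiments the candidate list excludes body weight: the
generator derives weight from age through a growth curve, so the two
are nearly collinear and either can absorb the maturation effect —
with both present, "age recovered" would be a coin flip against its own
proxy. Null-calibration experiments keep weight.

## Synthetic cohort

Defaults reproduce the study conditions: 139 subjects; ages log-normal
with median 5.3 y truncated to [1.1, 15.6] (σ_log = 0.55); weight
19.7·(age/5.3)^0.75 kg with 18% log-normal noise, clamped to
[9.5, 88] kg; 27% male; albumin log-normal median 18.3 g/L in
[7.6, 46.8]; hematocrit normal 41.2 ± 5%, clamped to [23.4, 55] (the
printed upper bound of 447.6% is treated as a typo); Wuzhi
co-medication Bernoulli at 6/139. Twelve SNPs are drawn independently
(no linkage) under Hardy–Weinberg proportions at the cohort's allele
frequencies.

Dosing is q12h starting at 25 µg/kg per dose rounded to 250 µg and
clamped to [500, 3000] µg. Monitoring visits fall on days 14, 28 and
56; after each visit's (noise-free, true-subject) trough the dose steps
±250 µg toward the 5–10 µg/L window — titration reacts to the virtual
patient's true state, as a TDM clinic reacts to the real one, so the
random effects drawn at generation time are reused when the cohort's
concentrations are simulated. Troughs are sampled 0.5 h before the
visit dose with probability 0.95 and peaks 0.5–3 h after it with
probability 0.084, giving ≈432 samples of which ≈35 peaks. Residual
error follows the model's form; the assay never reports non-positive
values (non-positive noisy draws are redrawn), and values below
0.5 µg/L are flagged (`BLQ=1`) but not modified.

What the generator does not emulate: growth-chart-faithful pediatric
anthropometry, linkage disequilibrium between loci, adherence lapses
and dropout, time-varying labs, and any relationship between disease
activity and PK. Passing recovery tests therefore show that the
estimator recovers the generating process under the study's design —
not that the published estimates are correct for real patients.

## Identifiability of the study design

With ω²_V = 1.13 (SD > 1 on log V) and almost all samples pre-dose
troughs, a subject's trough constrains only a one-dimensional curve in
(V, k); the population scale of CL/F is pinned essentially by the ~35
peak samples. The tvCL profile likelihood of a single simulated cohort
is consequently nearly flat over a wide range, and per-cohort MLEs
scatter roughly ±40% around the truth (multi-start and exact-likelihood
checks confirm these are genuine optima, not convergence failures). The
20-replicate recovery study checks the *median* estimate, which is
close to unbiased, but inherits visible sampling noise from this
flatness. Consistent with the weak individual-level information, the
fitted η shrinkages (≈30% for CL, ≈37–43% for V) match the study's
reported values closely.

A related consequence: the CYP3A5 *3/*3 effect of −0.25 yields expected
ΔOFV values of roughly 6–15 against the backward-elimination cutoff of
6.63, so its final-model retention rate under the generator is near
50–65% — age, with its wide covariate range, is retained in ≈95% of
replicates. These rates are properties of the stated effect sizes,
thresholds and sampling design.

## Diagnostics

All diagnostics simulate at the observed design (doses, times,
covariates) and are bit-reproducible given a seed. One subtlety of the
calibration experiments: dose titration couples a generated cohort's
doses to its subjects' true random effects, so data simulated with those
same effects are *not* exchangeable with fresh-eta replicates at the
fixed design — low-clearance subjects carry systematically lower doses
and the observed percentile spread narrows. Calibration checks of VPC
and NPDE therefore re-simulate the observed data with fresh random
effects at the fixed design, which is the null those diagnostics assume.
(On titration-coupled data the VPC's extreme percentiles sit inside the
bands less often — the same behavior real TDM datasets show.) VPC bins follow the
sampling design — peaks form one bin, troughs are binned by visit —
because uniform time bins degenerate on trough-heavy data; bins under 5
observations merge into a neighbor; bands are the 2.5–97.5% envelope of
each percentile across replicates. The bootstrap resamples subjects
with replacement to the original count, keeps the covariate-model
structure fixed, drops non-converged replicates (flagging the result if
convergence falls below 80%), and reports medians with 2.5/97.5
percentile intervals. NPDE decorrelates observed and simulated vectors
with the simulated mean and Cholesky factor (ridge-regularized if
needed), clamps the rank fraction to (1/(2n_sim), 1 − 1/(2n_sim)), and
tests mean 0 (t), variance 1 (χ²), and normality (Shapiro–Wilk and KS).

## Machine-learning stage

The regression target is the empirical-Bayes individual clearance of
the final fit, TV_CL(x_i)·e^{η̂_CL,i} — the only per-subject clearance
the PPK stage produces; features are the screened covariates (age plus
the Wuzhi, CYP3A5 and CTLA4 indicators, already 0/1-discretized). Six
families run under one protocol: regularized gradient tree boosting
(XGBoost), random forest, extremely randomized trees, gradient boosting,
AdaBoost, and L1-penalized linear regression, each with a small
config-exposed hyperparameter grid. Five outer repetitions of {fresh
random 70/30 train/test split; 5-fold cross-validated grid search on
the training 70%; refit; held-out scoring} are averaged. Metrics:
R², MSE, MAE, MedAE, RE and RMSE. RE is the mean relative error
mean(|y−ŷ|/y): the study table glosses RE as a root-mean-square
quantity, but its printed values are arithmetically inconsistent with
the MSE column under that reading, so both RE (relative) and RMSE are
reported and neither is a reproduction target. The published metric
table itself depends on the undeposited cohort and is out of scope; the
checkable quantity is that the linear model's R² approaches the
generator's analytic covariate-explained variance fraction,
e^{ω²}·Var(m)/(E[m²]e^{2ω²} − E[m]²e^{ω²}) with m the typical clearance
over the realized covariates, and that tree ensembles do not materially
exceed it.

## Problem sizes used by the automated studies

Parameter recovery: 20 cohorts of 139 subjects. Search calibration: 100
null replicates at 30 subjects with four clinical candidates (nominal
any-retention ≈ 1 − 0.99⁴ ≈ 4%); effect recovery: 10 study-size
replicates with five candidates. Diagnostics: six study-size cohorts
for NPDE/VPC calibration (400/300 simulation replicates), one
200-replicate bootstrap at 35 subjects. Replicate studies use a faster
fit profile (single restart, 60 outer iterations) whose estimates agree
with the thorough profile well within the decision tolerances.

## Known limitations

No lag time, transit absorption, two-compartment disposition,
inter-occasion variability, or Ω off-diagonals; no time-varying
covariates or infusion records; BLQ values are used as-is rather than
through a censored likelihood; the exact additive constants of the
objective are implementation-specific, so only OFV differences are
comparable across software.
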