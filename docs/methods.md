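# Methods

This note documents the models, algorithms, numerical choices and
limitations of `s1popk`. It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Structural model

Six linear states describe oral S-1 (5 mg/kg tegafur): a gut depot emptying
at rate K_a + K_a,Met (absorption of tegafur vs. presystemic routing to the
5-FU precursor, 5'-hydroxytegafur), two-compartment tegafur disposition
(CL_Teg, CLd_Teg, V_1,Teg, V_2,Teg), an amount-only precursor pool fed by
the gut route and by the fraction F_Met of central tegafur clearance and
drained at K_Conv, and two-compartment 5-FU disposition (CL_5FU, CLd_5FU,
V_1,5FU, V_2,5FU). IV 5-FU doses enter the 5-FU central compartment
directly. All clearances and volumes are apparent (per F); amounts are pure
mass bookkeeping with no molecular-weight correction between tegafur and
5-FU — the closed-form AUCs reproduce the reference noncompartmental means
only under that convention.

**Units.** Internally mg/kg, L/kg, h; concentrations cross the API boundary
in ng/mL (1 mg/L = 1000 ng/mL). The precursor pool has no volume and is
never observed.

**Propagation.** The system is linear and time-invariant, so states are
propagated exactly by eigendecomposition of the 6×6 rate matrix
(superposing dose events); if the eigenvector basis is ill-conditioned
(condition number > 1e10, e.g. a defective matrix at contrived parameter
ties) the code falls back to stepwise `scipy.linalg.expm`. Agreement with
an adaptive stiff solver (LSODA, rtol 1e-10) is asserted to 1e-6 relative
in the tests. Negative round-off is clipped at zero.

**Closed forms used as oracles.**
- AUC_Teg = f_a·D/CL_Teg and AUC_5FU = (f_m + f_a·F_Met)·D/CL_5FU with
  f_a = K_a/(K_a+K_a,Met), f_m = K_a,Met/(K_a+K_a,Met).
- Total 5-FU ever formed = D·(K_a,Met + K_a·F_Met)/(K_a+K_a,Met).
- The terminal slope of an analyte is the smallest positive decay rate among
  the eigenvalues of the subsystem feeding it; eigenvalues with zero residue
  (a decoupled peripheral compartment when CLd = 0) are dropped. At the
  reference values the slow tegafur disposition eigenvalue (0.351 /h) lies
  below the gut exit rate (0.418 /h), and both analytes share it — the
  flip-flop property: 5-FU's observed terminal phase reflects upstream
  input, not its own elimination (IV 5-FU t½ ≈ 14 min).
- Mass balance is checked on an augmented system with two
  cumulative-elimination states; the defect is < 1e-6 of dose by
  construction and measured at ~1e-14.

## Synthetic study generator

The generator emulates the reference experiment: two oral arms × 5 rats
(configurable), sampling at predose, 0.25, 0.5, 1, 1.5, 2, 3, 4, 8, 12,
24 h; optional IV 5-FU arm (10 mg/kg) with a denser early schedule (2 min –
2 h, chosen for a ~14 min terminal half-life; the source schedule for that
arm is not recorded); LLOQ censoring at 50/10/50 ng/mL for
tegafur/5-FU/gimeracil.

- Between-subject variability: independent log-normal η per parameter
  (F_Met on the logit scale so draws stay in (0,1)); no Ω off-diagonals, as
  no correlations are reported. The reference BSV column is interpreted as
  **variances** of log-parameters (the reporting convention of the
  estimation software used in the source analysis); `bsv_is_sd=True`
  switches to an SD reading. This ambiguity is inherent to the source table
  and is surfaced as a flag rather than silently resolved.
- Residual error: SD = √(σ_add² + (σ_prop·pred)²). Magnitudes are not
  reported in the source; defaults are σ_prop = 0.15 and σ_add = LLOQ/2 per
  analyte — typical bioanalytical noise, a synthetic choice.
- Predose samples are recorded as BLQ zeros (single-dose design); BLQ is
  flagged iff the noisy value is strictly below the LLOQ, never on
  noise-free values; negative noise draws are clipped at 0.
- Gimeracil is outside the structural model; a one-compartment oral
  (Bateman) generator with ka = 5.3 /h, CL/F = 2.81 L/h/kg, V/F = 2.84 L/kg
  reproduces the reference control summary (Cmax ≈ 348 ng/mL, t½ ≈ 0.7 h,
  AUC∞ ≈ 516 ng·h/mL at 1.45 mg/kg); the pretreated arm's reduced
  absorption is emulated by bioavailability ×0.47 and ka ×0.611
  (calibrated to Cmax ≈ 142 ng/mL and AUC ≈ 47%). Shared log-variance 0.03
  per parameter matches the ~12–17% CVs of the reference summary.
- Determinism: one `numpy` Generator seeded by the design seed, fixed
  draw order; identical inputs give byte-identical CSV.

What the generator does **not** emulate: dropout, actual (vs. nominal)
sampling times, assay batch effects, parameter correlations, nonlinear or
time-varying kinetics, and any direct gimeracil → CL_5FU coupling (the
pretreatment effect on CL_5FU is imposed as a covariate effect, not
mediated mechanistically). Passing tests therefore demonstrate correctness
of the algorithms under the stated statistical model, not robustness to
real-data pathologies.

## Noncompartmental analysis

λz: log-linear least squares over every contiguous terminal subset of
quantifiable post-Tmax points (Cmax excluded, ≥3 points), choosing the
subset with the largest adjusted R²; ties within 1e-9 resolve toward more
points; a non-negative best slope or too few points yields a flagged
not-estimable result, never an exception. AUC(0–tlast) uses the linear
trapezoid (the cited tool's default; a log-down variant is out of scope)
from t = 0, treating a leading predose BLQ as a zero anchor and discarding
later BLQ values. AUC∞ adds the **observed** Clast/λz. CL/F = Dose/AUC∞
(reported in mL/min/kg), Vz/F = CL/F/λz. Group comparison: two-sided
pooled-variance unpaired t-test at α = 0.05 (`welch=True` available);
zero-variance degenerate inputs give p = 1 (equal means) or p = 0.

Note the interaction of sparse late sampling with the trapezoid: on the
uncensored noise-free 5-FU profile the 8→12→24 h trapezoids overestimate
the exponential tail by ~6%; with the study LLOQ censoring those points the
NCA AUC∞ agrees with the closed form within 5%, which is how the reference
analysis itself was conditioned.

## Population estimation (importance-sampling MC-PEM)

Transformed parameters φ = log θ (logit for F_Met); subject model
φ_i = μ + β·g_i + η_i, η_i ~ N(0, diag(ω²)). Group effects β (control as
reference) sit on K_a, K_a,Met and CL_5FU by default; F_Met can be added.
Parameters listed in `bsv_params` carry estimated random effects and
updated typical values; parameters outside it are frozen at their initial
values, and `group_params ⊆ bsv_params` is enforced.

Each iteration, per subject:

1. **Mode.** BFGS minimization of the negative conditional log-posterior,
   warm-started from the previous iteration's mode (40 iterations first
   pass, 8 thereafter; finite-difference gradients).
2. **Proposal.** The BFGS inverse Hessian, symmetrized with eigenvalues
   clipped to [1e-8, 2·max ω²] and inflated ×1.2, as the covariance of a
   Gaussian proposal at the mode.
3. **Importance sampling.** K ≥ 100 draws; self-normalized weights from
   p(y|η)p(η)/q(η) give E[η|y], E[η²|y] and the subject's marginal
   log-likelihood (log-mean of the unnormalized ratios).

M-step: μ and β by group means of the conditional φ̂_i; ω² as the mean of
conditional variance plus squared recentred deviation, floored at 1e-4;
residual (σ_add, σ_prop) per analyte by Nelder-Mead maximization of the
weighted expected log-likelihood over the cached sample predictions,
floored at (1e-3 ng/mL, 1e-4). Residual error is shared across groups.

Other choices: BLQ observations are discarded (M1; simplest defensible
default — a refit of an uncensored replicate of one test dataset changed
the recovered clearance ratio by < 4%, so M1 is not the dominant error
source at these censoring fractions). Initial values are NCA-informed
(CL from dose/AUC, K_a from the median Tmax, volumes from Vz) unless
supplied. Convergence: relative change of the marginal log-likelihood
< 1e-4 over 10 consecutive iterations; non-convergence returns a flagged
result with the full trace. Seeding is per (run seed, subject id,
iteration), which makes estimates invariant to subject order;
`common_random_numbers=True` freezes the draws across iterations, under
which the trace is monotone up to the Monte-Carlo floor (the tests allow
dips of 2.5 log-likelihood units from mode re-location noise).

Empirical-Bayes estimates are MAP η at the final population parameters.
Shrinkage toward the typical grows with the **additive** residual SD; a
growing proportional SD does not flatten the likelihood (its variance is
prediction-dependent), so monotone-shrinkage statements are made, and
tested, for the additive component.

The IV 5-FU arm (untreated animals) is co-fitted with the oral arms by
default, sharing the 5-FU disposition parameters with the control group —
joint fitting mirrors the source analysis and anchors CL_5FU away from the
flip-flop confound.

## Diagnostics

**VPC.** n_sim ≥ 100 replicate studies at each subject's own design (new η
and residual noise per replicate); bands are the 10/25/50/75/90th
percentiles pooled per (group, analyte, nominal time). Bins follow the
nominal schedule (no adaptive binning); bands are plain prediction
intervals — with a single dose level per arm, prediction correction adds
nothing. Simulated values are not LLOQ-censored; observed BLQ points are
excluded from the overlay and coverage. Empty bins stay in the table with
`n_obs = 0`.

**NPDE.** n_sim ≥ 500 simulation vectors per subject; the observation
vector and the simulations are decorrelated by the inverse Cholesky factor
of the empirical simulation covariance (ridge-regularized with a warning if
singular); the componentwise rank, tie-broken by a seeded U(0,1)/n_sim
jitter and clamped away from {0,1}, maps through Φ⁻¹. Under the generating
model the sample is approximately N(0,1); normality is assessed by
Shapiro-Wilk (D'Agostino above 5000 values). The construction is invariant
to a common rescaling of concentration units applied to data, dose and
additive error.

## Problem sizes and tolerances

The packaged checks run at desk scale, chosen as the package's own
defaults: typical-subject AUCs on a 4001-point grid to 96 h (> 45 terminal
half-lives) plus an analytic tail; diagnostic calibration on 30 rats/arm
(~1050 quantifiable observations, NPDE mean within ±0.1, variance within
±0.15, interquartile VPC coverage within ±10 points of 50%); the recovery
experiment on 20 rats/arm plus 5 IV animals with K = 150 importance samples
and up to 60 EM iterations. The recovered CL_5FU group ratio is compared to
the generating 1.68 at ±15%; note that at this cohort size the realized
cohort ratio itself has ≈13% log-SD around 1.68 (ω² = 0.163), so this check
is a genuine statistical experiment whose outcome varies with the seed, and
the estimator is accurate to a few percent **relative to the realized
cohort** — the tests' fixed seed keeps the suite deterministic.

## Known limitations

- Linear kinetics only; no saturable conversion, enterohepatic recycling,
  or mechanistic gimeracil/oteracil modeling (gimeracil is NCA-only).
- BLQ handling is M1 (discard); likelihood-based censoring (M3) is not
  implemented.
- No Ω off-diagonals, inter-occasion variability, or Fisher-information
  standard errors (resampling utilities would sit above `mcpem_fit`).
- The importance-sampling E-step assumes a unimodal, roughly Gaussian
  conditional posterior; pathological posteriors would need more samples or
  a heavier-tailed proposal than the ×1.2-inflated Laplace.
- Adjusted-R² λz selection can pick short noisy tails on very sparse
  profiles — the flagged `n_lambda`/`adj_r_squared` fields exist so users
  can filter.
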