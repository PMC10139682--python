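# Methods

## The models

**Univariate latent change score (LCS).** For one instrument measured at
two waves the wave-2 score is defined as X1 = X0 + Δ with unit loadings, so
the free parameters are the baseline mean μ0 and variance σ²0, the change
mean μΔ, the change variance σ²Δ, and the baseline–change covariance σ1Δ.
The model is a reparameterization of the saturated bivariate normal: on
complete data the ML estimates are exactly the sample moments
(μΔ̂ = mean(x1−x0), σ̂²Δ = ML variance of the difference scores, σ̂1Δ = ML
baseline–difference covariance), which the test suite asserts to 1e-8.
σ1Δ is parameterized as a covariance, not a regression, because it is the
quantity the trial literature reports; a negative σ1Δ means participants
with worse baseline scores improve more (regression to the mean plus any
genuine baseline-targeting of the intervention).

**Multigroup testing.** The two arms are fitted jointly with shared or
free parameters per block. Following the reporting convention of these
trials, baseline means are always equated across arms (randomization makes
them equal in expectation) and baseline variances are always free. The
constrained model equates (μΔ, σ²Δ, σ1Δ); the unconstrained frees them;
their 3-df likelihood-ratio statistic tests whether change differs by arm.
df accounting: 2 groups × (2 means + 3 covariances) = 10 moments; 6
parameters constrained (df 4) vs 9 unconstrained (df 1).

**Two-wave five-variable LCS (2W-LCS).** Variable order is fixed as
(EPDS, HADS-A, DERS-SF, SCS-SF, CompACT); the first two are adjustment
outcomes, the last three psychological processes. The change factors obey
the structural system

    Δ = α + G·X0 + B·Δ + ζ,

where G carries own-baseline → own-change paths (diagonal) plus the 12
cross-lagged paths (3 process baselines → 2 outcome changes and 2 outcome
baselines → 3 process changes), and B carries the 6 change-to-change paths
(process changes → outcome changes). Because outcomes feed nothing, B is
nilpotent and (I−B)⁻¹ = I + B exactly. Residual covariances among the
change factors exist only between the three process pairs and the
EPDS–HADS-A pair, matching the correlation blocks such reports print;
own-baseline relations are directed paths so cross-lagged and
change-to-change coefficients are regression coefficients. The nested
sequence A (α, G-diagonal, residual block, cross-lagged and
change-to-change all group-equal) → B (change-to-change free) → C
(+ cross-lagged free) → D (all free) is compared with sequential Δχ²
tests. Full enumeration gives 130 moments and dfs 58/52/40/21 for A–D; the
published report prints 103/99/87/82, which no parameter counting
consistent with its text reproduces, so the computed dfs are reported and
the printed pairs are treated purely as inputs to the fit-index layer.

## Estimation

**FIML.** The observed-data likelihood sums, over records, the normal
log-density of each record's observed sub-vector; records are grouped by
missingness pattern so the likelihood reduces to pattern-level sufficient
statistics and is cheap inside the optimizer. Records with no observed
scores are dropped with a count (they carry no information in a
means-plus-covariances model). Optimization is BFGS on an unconstrained
working scale — log variances for the univariate model; Cholesky factors
for the baseline covariance and for the two residual blocks of the 2W-LCS
— which keeps every implied covariance positive definite without
constrained optimization. For the 2W-LCS the gradient uses the closed-form
derivative of the pattern likelihood with respect to the group means and
covariances, chained with a central-difference Jacobian of the (data-free)
implied-moment map; this makes a 109-parameter fit tractable on one CPU.
Starting values are moment-based (saturated estimates mapped through the
closed-form identities; for the nested sequence each model warm-starts
from the previous solution), so univariate starts are essentially exact.
Convergence requires the per-observation gradient below 1e-5 (scipy's BFGS
criterion at gtol 1e-7 for univariate models); non-convergence is flagged
on the result, never raised. Boundary variances (< 1e-8) are flagged.

**Saturated and baseline fits.** The saturated per-group means and
covariances come from EM over missingness patterns (relative log-likelihood
tolerance 1e-10, max 500 iterations; the tolerance is tight enough that EM
agrees with direct optimization to 1e-6 in log-likelihood, which is
tested). The CFI baseline model is per-group free means and variances with
zero covariances — closed form, since the likelihood then factorizes by
variable. χ²_M = 2(ll_sat − ll_M).

**Standard errors** come from the inverse observed information,
differentiated numerically in the natural (interpretable)
parameterization; standardized solutions use delta-method SEs with a
numerical Jacobian. Wald p-values use the normal reference. No sandwich or
bootstrap SEs are provided.

## Fit indices

RMSEA uses the multigroup convention RMSEA = √G · √(max(χ²−df, 0)/(df·N))
with N the total sample size — the convention, and the only one tried that
reproduces all twelve arithmetically consistent printed RMSEA values of
the reference report from its printed (χ², df) pairs to three decimals
(two further printed values round from the unrounded χ² and differ in the
third decimal; they are excluded from that check). The 90% CI inverts the
noncentral χ² cdf in the noncentrality parameter (Brent's method on
scipy's ncx2) and maps through the same scaling; the close-fit p-value is
P(χ²_df(λ0) ≥ χ²) with λ0 = N·df·0.05²/G. CFI is
1 − max(χ²_M−df_M, 0)/max(χ²_B−df_B, χ²_M−df_M, 0), clipped to [0, 1];
CFI values are reported but not checked against the report because the
baseline χ² is unprinted there. SRMR is the group-size-weighted root mean
square of standardized mean and covariance residuals against the saturated
moments.

## The synthetic-trial generator

The generator is the study-condition definition, not a tuning knob. Per
arm it draws (X0, Δ) jointly normal from the model-implied moments of that
arm's structural parameters and sets X1 = X0 + Δ, guaranteeing internal
consistency with the estimator, so parameter recovery is well posed. The
default parameter set transcribes the published trial: arm sizes 542/511;
per-arm baseline means and SDs and univariate change estimates
(e.g. intervention EPDS μ0=10.99, σ0=5.14, μΔ=−2.27, σ²Δ=20.11,
σ1Δ=−12.97); baseline correlations converted to covariances with the
baseline SDs; change-factor correlations to residual covariances; and
standardized cross-lagged / change-to-change coefficients to unstandardized
paths via the implied SDs. Own-baseline paths are then solved in closed
form so every instrument's implied σ1Δ matches its published value
exactly, and the residual blocks so every implied σ²Δ and change
correlation matches; the construction is verified positive definite.
Baseline means are arm-specific by default (the published tables report
them separately); `equalize_baseline_means` pools them for calibration
studies where the fitted models' equality constraint should hold exactly.

Wave-2 missingness regimes: `mcar_by_instrument` (independent per-cell
MCAR; the report publishes only the endpoint range 32.4%–40.2%, so the
five rates are linearly interpolated across the canonical instrument
order), `mcar_by_arm` (whole wave-2 vector missing per record at the
published completion imbalance, 50.7% intervention vs 12.9% control), or
`none`. Baseline covariates (age, parity, marital status, education,
employment, income, residence, infant age/sex, PDPI-R risk truncated at
the 5.5 eligibility cutoff) are generated at the published arm-level
distributions for exercising the descriptive layer; they do not feed the
outcome model.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: integer item-sum score distributions
(scores are continuous normals unless `discretize` rounds and clips them,
shifting large-sample means by well under half a scale point),
missingness that depends on observed or unobserved values (everything is
MCAR; FIML's MAR robustness is argued, not simulated), covariate-outcome
dependence, and any third wave.

## Descriptive layer conventions

Pooled-variance t tests (df = n1+n2−2) and Pearson χ² without continuity
correction reproduce the reference report's Table-style cells (its
residence cell prints 0.2 for a computed 0.17). Two printed cells are
internally inconsistent in the reference report (its parity counts give
χ²=4.11 where it prints 4.0; its infant-sex p does not match its printed
χ²/df); the package reports its own computed values. "Evaluative
respondents" (completed both assessments) is operationalized listwise
across all five instruments by default, with a per-model variant
(presence of that model's instrument at both waves) exposed, because
instrument-wise wave-2 ns and a single subgroup definition cannot both
hold. Little's MCAR test uses the EM grand moments; its statistic sums
pattern-level Mahalanobis distances of pattern means, df = Σ pⱼ − p.
Covariate flagging applies α = .05 two-sided per contrast (arm and
completer/dropout), with no multiplicity correction, matching the
reporting practice the package mirrors.

Covariate adjustment of the outcome models, when requested, partials
dummy-coded covariates out of every score column by OLS (effects pooled
across arms) before fitting — a covariate-conditional moment analysis.
It is off by default: the reference analysis states covariates were used
but not how, so the default replicates the fully specified uncovariated
model.

## Problem sizes

The default test suite runs the full univariate battery at 600/arm, the
2W-LCS sequence at 400/arm, Monte-Carlo moment checks at 1.2×10⁵ draws,
Little's-test calibration at 250 replicates of n=400, and the Δχ²
calibration at 200 replicates of 500/arm; the acceptance script runs
recovery at 5000/arm and the same calibration sizes. These sizes put
Monte-Carlo error well below the 3·SE tolerances used.

## Known limitations

- Two waves only; no latent variables with multiple indicators, no
  nonlinear change, no MNAR mechanisms, no mediation (a three-wave design
  would be needed).
- The observed information is differentiated numerically; for very flat
  likelihoods (tiny subgroups) SEs can be unstable, and the battery skips
  subgroups with fewer than 10 records per arm.
- The 2W-LCS df bookkeeping follows the enumerated parameter sets; it
  intentionally does not reproduce the reference report's printed dfs
  (see above).
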