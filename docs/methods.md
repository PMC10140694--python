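# Methods

`lifecap` implements a life-course inequality analysis of intrinsic
capacity — the composite of an older adult's physical and mental capacities
— and a synthetic cohort generator that reproduces the statistical
structure such an analysis assumes, so every stage can be exercised and
validated without access to restricted survey microdata.

## The capacity measurement model

Intrinsic capacity is modelled as a second-order factor: twelve observed
indicators (chair-stand, grip strength, balance, walking speed, episodic
memory, mental status, forced expiratory volume, haemoglobin, hearing,
vision, affective state, sleep) load on five subdomain factors
(locomotion, cognitive, vitality, sensory, psychological), which in turn
load on a single overall capacity factor:

    x       = Λ η_sub + e,        e ~ N(0, Θ) diagonal
    η_sub   = λ η + δ,            δ ~ N(0, Ψ) diagonal
    η       ~ N(0, φ)

Indicators are coded so that larger always means better before fitting.
Parameters are estimated by minimizing the maximum-likelihood discrepancy

    F(θ) = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − p,
    Σ(θ) = Λ (φ λλ′ + Ψ) Λ′ + Θ

with the first indicator of each subdomain as its marker (loading fixed at
1), the first subdomain as the marker of the overall factor, and the
overall factor variance free. Variances are optimized on the log scale
with an analytic gradient (L-BFGS-B, `ftol` 1e-14, `gtol` 1e-9) and a
three-point fixed-seed multi-start to guard against local minima.
Non-positive-definite sample covariance, zero-variance indicators and
non-convergence raise explicit errors; convergence is flagged on the
result, never assumed.

Participants are scored with regression (Thurstone) factor scores,
`Cov(f, x) Σ⁻¹ (x − x̄)`, then each score column is standardized to mean 0
and standard deviation 1 on the scored sample. The scoring rule is a
design choice: it is deterministic and closed-form given the fitted
parameters. Tests verify that scores are invariant (to 1e-6) under
positive rescaling of any indicator with refitting, monotone in each
indicator, and that the fitted optimum is no worse than an independent
RAM-parameterized Nelder-Mead fit started from the data-generating truth.

## Inequality measurement

Socioeconomic position is the continuous family-economic-status (wealth)
variable; ranks are weighted fractional ranks,
`r_i = (cumweight below + w_i/2) / Σw`, with tie groups receiving their
weighted average rank, so the weighted mean rank is exactly ½. The
concentration index is

    C = 2 cov_w(y, r) / μ_w(y).

Standardized capacity scores have mean 0, for which `C` is undefined. The
default variant therefore min-max rescales the score onto [0, 1] before
computing the index (`shifted_minmax`); `standard` (positive-mean outcomes
only) and an Erreygers-corrected variant (`4 μ̃ C̃` on the [0, 1] scale)
are selectable, and every output names its variant. Because a shift-based
index depends on the chosen support, magnitudes are comparable across
variants of this package but not necessarily with other modified indices;
this is flagged wherever indices are reported. Uncertainty is a
participant-level percentile bootstrap (default B = 1000) with ranks
rebuilt inside each resample; degenerate resamples are counted, not
silently dropped.

## Decomposition and mediation

For the linear model `y = Σ β_k x_k + ε` on dummy-coded determinants the
index decomposes exactly:

    C = Σ_k (β_k x̄_k / μ) C_k + GC_ε / μ

with `C_k` the determinant's own concentration index and `GC_ε` the
generalized concentration index of the residual. The additivity identity
is asserted internally to 1e-10 on every call. A categorical factor's
contribution is the sum over its dummy levels (reference-level choice
moves level terms around but not the category roll-ups, which is why
roll-ups over the four life-course categories — early-life, current
socioeconomic, demographic, lifestyle — are the primary report). Negative
shares are reported signed, never truncated.

Mediation is by model exclusion: the early-life category share under the
full model is the *direct* share; re-estimating without the four current
socioeconomic covariates gives the *total* share; indirect = total −
direct is the part of early-life inequality transmitted through adult
socioeconomic position. Confidence intervals come from a paired bootstrap
(one resample per replicate, both models re-run on it, so the two shares
stay correlated within replicate). This is a descriptive contrast of
decomposition shares, not a causal natural-effects estimand.

Regression tables carry heteroskedasticity-robust (HC1) standard errors,
raw two-sided p-values and Holm–Bonferroni step-down adjusted p-values
(`p_(i) → max_{j≤i} (m−j+1) p_(j)`, capped at 1, applied within each
outcome's coefficient table). For recovery experiments on the generator —
whose errors are homoskedastic by construction — the exact nonrobust
intervals are used (`cov_type="nonrobust"`).

## The synthetic cohort generator

The generator emulates a CHARLS-like ageing survey table: 11 early-life
factor groups (17 categorical covariates), 4 current socioeconomic
factors, 3 demographic and 3 lifestyle covariates, a continuous wealth
variable with quintiles, and the 12 capacity indicators. Its defaults are
the study conditions: `n = 21 783`, the published regression effects for
all six outcomes as planted coefficients, and published sample
compositions as marginals where available (early-life marginals, which no
table reports, were chosen once as plausible for a Chinese cohort born
1930–1965 and are documented in the shipped YAML).

Dependence is induced by a single latent childhood-advantage variable
`U ~ N(0,1)`: each covariate is assigned by ordered thresholds on
`loading·U + noise`. A single latent factor with per-covariate loadings
guarantees a positive-definite dependence structure with few parameters.
Levels are assigned by *empirical* quantiles (largest-remainder counts),
so configured marginals hold exactly and wealth quintiles contain n/5 ± 1
rows; the cost is a small negative dependence between counts that does not
affect conditional inference. Current-SES covariates add a mediation index
`M = Σ mediation_coefs · early-life dummies` to their threshold index —
the path through which early-life advantage becomes adult socioeconomic
advantage. Continuous wealth is `exp(9 + 0.8 z)` (yuan-like) with
`z = 0.5 U + M + noise`.

The latent overall capacity is `η = Xβ + ε`, `ε ~ N(0,1)`; each subdomain
latent is `η_d = Xβ_d + λ_d ε + δ_d`, and indicators follow the
measurement model above. Latent truths are carried in `latent_*` columns,
excluded from every analysis path, and exist only so recovery experiments
can compare estimates against known ground truth. `simulate_factor_data`
generates from the pure factor model (no covariate effects) for
measurement-model validation, where the generator's covariate structure
would otherwise leak into the disturbances.

Missingness is injected MCAR per column (the analysis assumes missing at
random; MCAR is the testable special case). Selection uses a probit
propensity, by default increasing in wealth and education and decreasing
in age, mirroring the documented profile of excluded participants.

What the generator does *not* emulate: multi-stage survey sampling and
weights calibration, household clustering, panel attrition dynamics,
measurement error in recalled early-life factors, and any nonlinearity or
interaction among determinants. Passing tests therefore demonstrate that
the estimators recover the structures they target, not that the synthetic
magnitudes equal those of any real cohort; published point estimates are
context, not targets, except where a planted-effect recovery experiment
makes a printed coefficient a legitimate stochastic target.

## Sensitivity machinery

*Selection.* A probit inclusion equation (probit, not logit, because the
inverse Mills correction is derived under normality) is fitted by ML on
the full cohort; `λ_i = φ(z_i γ)/Φ(z_i γ)` is appended to the outcome
regression for included rows. Perfect separation is flagged; when the
selection covariates add nothing beyond the outcome covariates the module
warns that identification rests on functional form alone rather than
inventing an exclusion restriction.

*Imputation.* Chained equations via predictive mean matching (statsmodels'
MICE engine behind the module surface), default m = 20 imputations and 10
chain iterations between retained datasets; imputed categorical cells
stay inside the observed level set by construction. Estimates pool by
Rubin's rules, `T = W̄ + (1 + 1/m) B`, with Barnard–Rubin small-sample
degrees of freedom when a complete-data df is available; `B = 0`
reproduces single-dataset inference exactly.

*Subgroups.* Pre-old (< 60 years) vs older, and a median split on the
cognitive subdomain score (the recall-bias check; the cut-point is a
package choice since none is published). Each side gets the full
fit/index/decomposition pipeline; the side-by-side coefficient table is
computed on the original outcome scale because the min-max support —
hence the scaled coefficients — differs between subgroups.

## Numerical choices and problem sizes

Tolerances: decomposition additivity 1e-10; rank mean ½ to 1e-12;
index scale-invariance 1e-12; CFA oracle gap 1e-4 in discrepancy and 0.02
in score-latent correlation; score scale-invariance 1e-6. Ties in ranking
variables are averaged; constant outcomes define C = 0 under every
variant; a non-positive mean under the standard variant raises an error
that names the bounded alternatives; constant columns in the Spearman
matrix yield flagged NaNs, never silent zeros.

Default problem sizes in the test suite were chosen to make Monte-Carlo
error small against each assertion's margin: recovery uses 250 replicates
at the full n = 21 783 (per-term CI-coverage standard error ≈ 1.4 points
against a 5-point margin); the mediation dual-route check runs on one
n = 200 000 cohort, where package and an all-numpy reimplementation must
agree to 1e-8; bootstrap coverage checks use 120 replicates at B = 300.
Pipeline defaults (B = 1000 bootstrap, B = 200 mediation replicates at
n = 21 783) run end to end in well under ten minutes on one core.

## Known limitations

The "modified" concentration index of the source analysis is not publicly
specified; the shift-based default here is well-defined and reproducible
but its magnitude need not match other modified indices on the same data.
The scoring rule (regression scores) is likewise a declared choice among
defensible alternatives. Survey weights are accepted everywhere but
default to 1, and the generator takes no stance on weighted estimation.
Decomposition shares for outcomes with near-zero total concentration
index are numerically unstable (shares are ratios); they are reported
with their totals so readers can judge, matching the known imprecision of
locomotion and psychological decompositions.
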