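# Methods

## The problem

Longitudinal studies of parenting and child adjustment routinely ask
whether maladaptive parenting (MP) drives later emotional (EP) and
behavioural problems (BP), or the reverse. Cross-lagged panel models
answer this with prospective paths `β(X_t → Y_{t+1})` conditional on
`Y_t`, but a plain CLPM confounds these paths with anything unobserved
that makes `X` and `Y` correlate. Two designs strengthen the causal
reading, and they do so *differently*:

* the **RI-CLPM** splits each person's trajectory into a stable random
  intercept and occasion-specific within-person deviations, so any
  *time-invariant* confounder (shared with a co-twin or not) is absorbed
  by the intercepts;
* the **MZD-CLPM** exploits monozygotic twin pairs: a latent familial
  factor per trait-occasion soaks up everything co-twins share —
  genetic influence and shared environment, whether stable *or*
  time-varying — leaving lagged structure only among the twin-specific
  (nonshared-environment) components.

The package implements both (plus the baseline CLPM and an explicit
difference-score variant) on one estimation engine, and a generator whose
confounding regimes make each design's control claim checkable by
simulation: a regime the design controls for should leave its focal
cross-lag unbiased at zero; a regime it does not control for should not.

## Models

All models are linear Gaussian structural models in RAM form: variables
`v` (observed and latent) satisfy `v = A v + m + e`, `e ~ N(0, S)`, so the
observed moments are `μ = F(I−A)^{-1} m` and
`Σ = F(I−A)^{-1} S (I−A)^{-T} F'`. Free entries of `(A, S, m)` carry
string labels; entries sharing a label are constrained equal, which is how
all cross-twin equality constraints are expressed.

With `K = 3` traits and `T = 3` occasions:

* **CLPM** (individual level, 9 observed variables, 54 moments): free
  means (9), full first-occasion covariance block (6), all lag-1 paths per
  transition (18), later-occasion residual variances (6) and
  within-occasion residual covariances (6) — 45 free parameters,
  **df = 9**. The only restrictions are the omitted lag-2 paths.
* **RI-CLPM** (pair level, 18 observed variables, 189 moments):
  `y_{v,t,j} = μ_{v,t} + RI_{v,j} + w_{v,t,j}` with unit loadings. Means,
  within-twin (co)variances and lagged paths are equated across twins;
  cross-twin covariance blocks of the random intercepts and of each
  occasion's residuals are fully free (`K×K = 9` entries each, not
  exchangeability-reduced to 6 — the fully-free block is the pattern
  consistent with the df fingerprint and is closed under twin
  relabelling). 87 free parameters, **df = 102**.
* **MZD-CLPM** (pair level): one familial factor `F_{v,t}` loads 1 on both
  twins' `y_{v,t}`; the 9 familial factors covary freely (45 parameters).
  Twin-specific components `u_{v,t,j}` carry the lag-1 paths (equated
  across twins), have equated within-twin (co)variances, and are *fixed
  uncorrelated between twins* — twin differences are twin-unique by
  construction. 90 free parameters, **df = 99**.
* **Difference-score CLPM**: the CLPM applied to `d_{v,t} = y_{v,t,1} −
  y_{v,t,2}`. The familial half cancels in the differencing, so its lagged
  paths estimate the same quantities as the latent MZD-CLPM's
  twin-specific paths; the two agree to well under 0.01 at 4000 pairs in
  the equivalence check.

The df values 9 / 99 / 102 are treated as fingerprints of the constraint
patterns: the figure-level descriptions under-determine the
parameterisation, and reproducing the printed df is the criterion by which
the patterns above were fixed. `ModelSpec.parameter_table()` lists every
entry, status and label for audit.

## Estimation

**FIML.** Rows are grouped by missingness pattern; each pattern
contributes `n_r [p_r log 2π + log|Σ_oo| + tr(Σ_oo^{-1} S_r) + d'Σ_oo^{-1}d]`
to the deviance via its pattern-level sufficient statistics (all-missing
rows contribute nothing). Gradients with respect to every free parameter
are analytic: writing `C = FB`, `V = FBSB'` with `B = (I−A)^{-1}`, the
derivative of Σ in a path entry `(i,j)` is the symmetrised outer product
`C_i V_j' + V_j C_i'`, so the whole gradient reduces to two small matrix
products (`C'GC`, `C'GV`) per evaluation. This is what makes the
1 200-model-fit bias experiment run in about a minute.

**Optimisation.** Free variances are optimised on the log scale and all
other parameters unconstrained (L-BFGS-B, `ftol 1e-12`, `gtol 1e-5`, max
5 000 iterations). A non-positive-definite Σ sub-block met during the
search returns a large finite penalty with an eigenvalue pushback
gradient, so the line search recovers. Start values: observed column
means for observed-variable means; builder-declared fractions of the mean
observed variance for latent/residual variances (e.g. RI 0.25, within
0.55); paths and covariances at 0. A fit is flagged non-converged when
the optimizer fails and the gradient norm is large; fit indices are then
withheld. If the within-pattern sample covariance is singular (e.g.
literally identical twins: the twin-specific process has no variance and
its paths are unidentified) the fit carries an explicit warning.

**Inference.** Naive SEs come from the observed information (numerical
Hessian of the analytic gradient at the optimum, natural scale); robust
SEs from the sandwich `H^{-1}(Σ_i s_i s_i')H^{-1}` with analytic per-unit
scores. Units are pairs in the pair-level models, so clustering by pair
is automatic; the individual-level CLPM treats individuals as units,
matching its df-9 specification. Two-sided p-values use the normal
reference with robust SEs (α = 0.05). The mean-and-variance-adjusted
*scaled* test statistic is deliberately not implemented: the reported χ²
is the plain likelihood-ratio statistic, and robustness to nonnormality
enters through the sandwich SEs used for inference on paths.

**Standardisation.** Paths are rescaled by `SD(source)/SD(target)` under
the model-implied covariance of *all* variables (so RI-CLPM and MZD-CLPM
betas are standardized with respect to the latent components they relate);
covariances become correlations. 95% CIs use the delta method on the
standardized scale with the robust parameter covariance.

**Fit indices.** χ² = 2(ℓ_sat − ℓ_model) with the saturated model fitted
by the same engine (closed form under complete data); the independence
baseline (free means and variances) likewise. CFI, TLI, RMSEA use their
conventional definitions with `n` = number of independent units; SRMR is
the covariance-metric residual in sample-SD units, diagonal included,
means excluded — under missing data SRMR is reported missing rather than
computed from a patched covariance. AIC = −2ℓ + 2k, BIC = −2ℓ + k log n.

## Synthetic twin panels

Per pair `i`, twin `j`, trait `v`, occasion `t`:

    y = μ_v + T^sh_{v,i} + T^ns_{v,i,j} + w_{v,t,i,j} + λ_v U + covariates

with stable shared `T^sh` (one draw per pair), stable nonshared `T^ns`
(per twin), and a lag-1 within process `w_t = B_t w_{t−1} + η_t` whose
innovations split into shared and nonshared parts. Cross-trait coupling
enters through correlation parameters on the stable and innovation
components. Missingness is completely at random per twin-wave (a skipped
questionnaire wave drops all three traits), which is the mechanism FIML
is valid under; the real panel's attrition is not characterised well
enough to emulate and selective attrition is out of scope. Sex is
pair-constant, ages are wave-nominal plus pair jitter, and configured age
and sex effects are added wave-centred so that residualisation
(individual-level OLS per trait-wave) closes the loop exactly.

### Study conditions (presets)

The confounder regimes share one base — stable shared variance 0.4 per
trait, innovation variances 0.2 (shared) + 0.3 (nonshared),
autoregressions 0.3, traits otherwise uncoupled — plus a unit-variance
confounder `U` loading 0.5 on BP (exposure) and MP (outcome):

| preset | U drawn | expected unbiased models |
|---|---|---|
| `shared_stable_confounder` | once per pair | RI-CLPM, MZD-CLPM |
| `shared_timevarying_confounder` | per occasion, shared in pair | MZD-CLPM only |
| `nonshared_stable_confounder` | once per twin | RI-CLPM only |

The magnitudes are illustrative (the confounding taxonomy itself carries
no effect sizes); they are set large enough that a biased cell separates
cleanly from Monte-Carlo noise at 100 replicates of 1000 pairs. Under
`shared_timevarying`, the CLPM/RI-CLPM bias is *negative* — conditioning
on the confounded `Y_t` induces an adjustment bias rather than a positive
spurious path — the ledger claims concern bias vs no bias, not sign.

`true_crosslag` sets `B[mp←bp] = 0.3` with stable shared variance reduced
to 0.05 and no stable nonshared variance: a large stable trait component
would attenuate the individual-level CLPM's cross-lag below any sensible
recovery band *by design* (that attenuation is precisely the CLPM critique
the other two models answer), so the "no confounding" recovery condition
is defined with a small stable component, under which all three models
recover 0.30 within ±0.05.

`teds_like`, the end-to-end default, adds cross-trait correlations
(stable 0.45, innovations 0.25), a mild true BP→MP effect (0.08), wave
missingness (5/12/25%), and age/sex effects, producing contemporaneous
cross-trait correlations in the 0.1–0.4 band and stabilities around
0.15–0.40, in line with the published descriptive tables.

What passing these simulations does *not* show: the instruments behind
the real data are short ordinal sum scores with modest reliability; the
generator is Gaussian and error-free. Measurement error in difference
scores attenuates MZD estimates in real data in a way these simulations
do not exhibit, and non-random attrition could bias FIML estimates.
Conclusions transfer to the *designs*, not to any particular dataset.

## Model comparison

The RI-CLPM and MZD-CLPM are not nested, so agreement between their
coefficient vectors is summarised by Spearman's ρ (Pearson correlation of
average ranks, ties averaged) and R² (squared Pearson correlation of the
values), computed for both the 12-path cross-lagged subset and the
18-path regression set, on both standardized and raw scales — which scale
and subset produced a published summary is not always stated, so all four
are reported side by side. A per-path classification (significant in
both / one / neither, with sign agreement) uses robust p-values at
α = 0.05.

## Problem sizes and runtime

The bias experiment runs 4 regimes × 3 models × 100 replicates × 1000
pairs (≈ 1 200 fits, about a minute on one CPU); equivalence and SE checks
use single panels of 4000 pairs. These sizes put Monte-Carlo standard
errors of regime means near 0.003, an order of magnitude below the
injected biases (0.05–0.22).

## Known limitations

* Plain LR χ² only; no scaled test statistics or scaled difference tests.
* SRMR unavailable under missing data (no patched sample covariance).
* No ordinal estimation; sum scores are treated as continuous, as in the
  normal-theory-with-robust-correction tradition.
* One MZ zygosity group; no DZ twins, ACE decomposition, multiple-group
  moderation, or random slopes (which would need ≥ 4 waves).
* The RI-CLPM pair form assumes twin exchangeability in its equated
  parameters; systematic birth-order effects would violate it.
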