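# Methods

`cloneirt` implements a complete calibration-study workflow for
clone-structured item banks: a bank of puzzle *templates*, each realized as
six *clones* (three shape sets crossed with two distractor-construction
strategies), administered to a large sample under planned missingness, and
analyzed with hierarchical ("additive multilevel item structure", AMIS)
3PL item response models.  This note records the model, the generator, the
numerical choices, and the known limitations.

## The measurement model

The probability that person *i* answers clone *k* of template *j* correctly
is a three-parameter logistic (3PL) model,

    P(y_ijk = 1) = γ + (1 − γ) · logistic(α_jk · θ_i − β_jk),

with the guessing parameter fixed at the nominal rate for four response
options, γ = 0.25 (free guessing parameters are poorly identified at
ordinary sample sizes).  Difficulty and discrimination follow an additive
two-level structure:

    β_jk = μ_β + Σ_n Q_jn δ_βn + ε_βj + Σ_m R_km δ_βm + ε_βk
    α_jk = μ_α + Σ_n Q_jn δ_αn + ε_αj + Σ_m R_km δ_αm + ε_αk

Template-level attributes Q are element number (1–4) and rule number (1–6);
clone-level attributes R are distractor type and the clone's mean log
response time, orthogonalized against the other three attributes so its
coefficient reflects residual dwell-time structure only.  Discrimination is
restricted to [0, 5].  Six nested models arise by switching residual terms
on: models 1–3 fix α = 1 and grow the difficulty structure (fixed effects
only; + template residuals; + both residual levels); models 4–6 keep the
full difficulty structure and grow the discrimination structure the same
way.

Ability is explanatory: θ_i = Σ_p X_ip ρ_p + ε_i with standardized person
covariates (age, gender coded −0.5/+0.5, mean response time, and the
response-time slowing slope on harder items) and residual variance fixed at
1 − Σρ², which identifies the latent scale (marginal ability variance ≈ 1;
exactly 1 up to the gender coding, whose ±0.5 codes have variance 0.25, a
deliberate fidelity choice that keeps Var(θ) within 2% of one).

### Coding conventions

Element and rule number enter mean-centered, and distractor type is coded
MD = +0.5, PD = −0.5, so μ_β keeps its reading as the average difficulty
across items and a one-unit attribute contrast is symmetric about the
average item.  The marginal effect of an attribute on accuracy is reported
as 100·[p(θ=0, β=μ−δ/2) − p(θ=0, β=μ+δ/2)] — the percentage-point accuracy
reduction for an average-ability respondent.

## The synthetic-data generator

The generator is the package's study-conditions oracle: every downstream
stage is exercised on data whose truth is known.  Defaults reproduce the
calibration design: 64 templates × 6 clones, 1501 persons (desk default:
16 templates, 300 persons), 16 difficulty-stratified sets with one template
answered per set, and clone assignment counterbalanced by cycling a random
permutation per template, which keeps per-clone administration counts
near-uniform (~62 at full scale, ~375 per template).

Structure coefficients default to the calibrated posterior means
(μ_β = 0.177, μ_α = 1.298, δ_β = (0.579, 0.514, 1.105, 0.541),
δ_α = (−0.015, 0.020, −0.029, −0.010), σ_β,clone = 0.620,
σ_α,template = 0.221, ρ = (−0.299, 0.128, 0.427, 0.368)); the template-level
difficulty scale is solved analytically so the marginal sd of difficulty is
1.431 under the generator's attribute distributions.  Element and rule
number are drawn independently (their association in the real bank is
negligible).  Discrimination residuals that would leave [0, 5] are redrawn
(logged; rare at defaults).  The clone-level dwell-time attribute is drawn
as an exogenous offset (sd 0.15 log-seconds), orthogonalized for the item
structure, and fed into the response-time simulation so a refit can recover
it from data.

Response times are log-normal: intercept log(15) s, person-intercept sd
0.25, residual sd 0.35 (≈ 16 s mean, ≈ 7 s sd), plus the seven
accuracy × rest-score × difficulty fixed effects of the mixed model
(0.039, 0.167, 0.073, −0.064, 0.097, 0.032, 0.012) applied to centered
accuracy and standardized rest score / empirical difficulty.  Trials whose
latent time overruns the 30-s deadline are mostly (75%) answered just
before the buzzer — per the task instructions to guess when time runs out —
with accuracy still given by the 3PL; the remainder time out, are censored
at 30 s, flagged, and coded incorrect (≈ 1.8% of trials).  Optional
artifact injection adds rapid-guessing persons (≥ 4 trials with uniform
0.3–3 s times and chance accuracy) and non-responders (≥ 4 timeouts),
matching the exclusion definitions exactly.

What the generator does **not** emulate: item-position and fatigue effects,
person-level heterogeneity in guessing or speed–accuracy strategy beyond
the modeled covariates, perceptual idiosyncrasies beyond i.i.d. clone
residuals, and any dependence between the person RT covariates and the
person RT random intercept.  Passing tests therefore certify the pipeline's
statistical machinery under the modeled data-generating process, not the
behavior of any particular human sample.

## Estimation

Models are fit by full-Bayes posterior sampling in a non-centered
parameterization (all residuals as unit normals scaled by their σ; the
covariate coefficients ρ mapped to the open unit ball by u ↦ u/√(1+‖u‖²),
which enforces Σρ² < 1 smoothly).  Priors: Normal(0, 2.5) on intercepts and
attribute effects, half-Normal(0, 1) on residual scales, Normal(0, 0.5) on
ρ, and a smooth quadratic barrier keeping discrimination inside [0, 5]
(hard clipping creates zero-gradient regions that trap samplers and
optimizers).

The default backend is an in-package Hamiltonian Monte Carlo sampler:
jittered fixed-length trajectories (12 leapfrog steps ± 20%, step size
jittered ± 20%), dual-averaging step-size adaptation to a 0.75 acceptance
target, and a diagonal mass matrix re-estimated from the middle of warmup.
The full protocol is 4 chains × 7500 iterations with 5000 discarded
(10,000 retained); the desk protocol scales this to 2 chains × 2500 with
500 discarded, thinned to 1500 draws.  A fit is flagged unconverged unless
every split R-hat is below 1.01 and no post-warmup divergences occurred
(divergence: energy error > 1000 or non-finite density).  Two further
backends share the contract: `emcee` (affine-invariant ensemble; an
independent cross-check on small models) and `laplace` (joint posterior
mode + Gaussian approximation; deterministic and fast, but the joint mode
of a hierarchical posterior systematically overstates residual scales, so
it is reserved for smoke testing).

Weakly-identified variance components (e.g. a clone-level discrimination
scale fitted to data that has none) concentrate near zero but retain prior
mass; at desk scale their posterior means sit near 0.15–0.25 rather than 0.

## Model comparison

Models are compared by leave-one-cluster-out (LOCO) cross-validated
expected log predictive density, approximated by Pareto-smoothed importance
sampling over clusters.  The cluster is the item template by default —
the comparison asks how well a model generalizes to *new item families*
— with clone-level clustering available.  Crucially, the predictive density
of a held-out cluster integrates that cluster's own residual effects over
their priors (a new template's residuals cannot be conditioned on); the
integration uses nested Gauss–Hermite quadrature (clone residuals inside,
template residuals outside; 11 nodes per dimension by default).  Because the
template-level integrand is sharply peaked away from zero for large
clusters, that dimension is integrated adaptively: a coarse pass locates
each draw's conditional mode and curvature and the rule is re-centered and
re-scaled there with an importance correction.  The integrals agree with
brute-force Monte Carlo to ~0.005 in log density and with exact
drop-one-cluster refitting well within its standard error.  Person abilities remain conditioned at their posterior draws
(the "conditional" LOCO reading).  Tables are reported in deviance scale
(−2·elpd), with the difference to the best model, the paired standard error
of that difference, a weak-preference flag when the difference is within
two standard errors, and the count of clusters whose Pareto shape exceeds
0.7 (importance weights unreliable; with few large clusters this is common
and the flagged count should temper interpretation).

## Model checking

Two discrepancy statistics drive posterior predictive p (PPP) values, each
computed per retained draw on the observed data (realized) and on data
replicated from that draw; PPP is the share of draws with replicated ≥
realized, and PPP ≤ 0.05 flags misfit.

* **Score-distribution χ²**: observed vs expected proportions of persons at
  each total-score level, Σ n(o_s − e_s)²/e_s over levels ≥ 2 (scores of 0
  and 1 are ignored); the expected distribution is the mean over persons of
  each person's Poisson-binomial score distribution, computed exactly by
  dynamic programming.
* **SGDDM**: the overlap-weighted mean absolute standardized conditional
  covariance of item residuals over item pairs.  Items are paired at the
  template level — under the planned-missingness design two specific clones
  share almost no respondents (about one at full scale), while two
  templates share ~90 — with a minimum-overlap filter (default 10).

The validation-study check takes *new* responses and *fixed* item
parameters, computes each person's ability posterior under a Normal(0, 1)
prior by dense grid quadrature (81 points on [−4, 4]; exact to plotting
accuracy, no sampling required), draws abilities, and applies the χ² PPP to
total scores.

The parameter-recovery harness generates studies at a configurable scale
(desk default 10 replicates × 300 persons × 96 clones; the full design is
100 × 1500 × 384), refits, and reports bias, RMSE, truth-estimate
correlation and central-interval coverage.  Replicated datasets reuse the
observed assignment pattern.  Recovery fits use the generative person
covariates; the pipeline instead recomputes the RT covariates from data,
as an analysis of a real study must.

## Response-time analysis

The mixed model is `log(RT) ~ accuracy * score * difficulty + (1 | person)`
fit by REML (statsmodels), with accuracy centered, rest score (total
correct on all other items) and empirical difficulty (one minus proportion
correct) standardized; timeout trials are excluded here but retained (as
incorrect) for the item response models.  Person-level covariates come from
per-person regressions of log RT on centered difficulty: intercept → mean
RT, slope → difficulty-slowing; both standardized across persons, with
persons having fewer than three valid times flagged and imputed at zero.

Deadline censoring attenuates the RT coefficients slightly (slow trials are
clamped at the buzzer or excluded), so estimator-recovery experiments
generate uncensored data; the attenuation at the default 30-s deadline is
visible but small and affects a real administration equally.

## Optimal test assembly

Form assembly is a mixed integer program (HiGHS via
`scipy.optimize.milp`): binary selection variables per clone × form;
objective = the minimum test information over the ability grid
(−1, −0.5, 0, 0.5, 1) minus a weighted penalty on pairwise inter-form TIF
gaps (gap variables also hard-capped at a tolerance, default 0.5); hard
constraints for form length, at most one clone per template per form,
optional identical template sets across forms (short-form mode), clone
uniqueness across forms (default on — parallel forms share no physical
item), and per-form distractor homogeneity (default on; the alternative
reading, only per-template uniqueness, remains enforced regardless).  Ties
are broken lexicographically by clone id through an epsilon cost.  A 60-s
default solver cap returns the incumbent with its bound gap when proving
optimality is slow; on enumerable banks the solver is exact.

Marginal reliability is Var_θ[TCC]/(Var_θ[TCC] + E_θ[Σ p(1−p)]) under
θ ~ Normal(0, 1) by 61-node Gauss–Hermite quadrature; expected scores are
reported both at θ = 0 and averaged over the population, since either
convention is defensible.

## Numerical choices and degenerate inputs

Likelihood terms use `log(1−p) = log(1−γ) + log_expit(−η)` to avoid
catastrophe at extreme abilities; exp(log σ) is clipped at e⁸ so divergent
leapfrog excursions cannot overflow; the score-distribution DP is exact;
HDI intervals are narrowest-window estimates on sorted draws.  Empty item
sets, single clusters, single items, rank-deficient covariates, unknown
clones and invalid model numbers all raise explicit errors rather than
degrade.

## Problem sizes used by the test suite

The suite runs the desk-scale protocols described above: recovery at
10 × 300 × 96 with 2 × 2500-iteration chains; comparison direction and PPC
calibration on twenty 100-person, 32-template wave-1 studies; RT recovery on
three 1501-person studies; assembly oracles on enumerable banks.  These
sizes are the package's desk defaults; full-protocol runs scale the same
code paths up.

## Known limitations

* The HMC backend uses fixed-length jittered trajectories, not dynamic
  (NUTS-style) ones; very weakly identified scale parameters mix more
  slowly and small studies occasionally flag R-hat just above 1.01 or a
  handful of divergences.
* The Laplace backend is a mode-based approximation unsuitable for
  hierarchical scale inference (documented above) — it exists for speed.
* PSIS-LOCO with few, large clusters routinely yields high Pareto shapes;
  the exact-refit oracle shows the elpd estimates remain accurate at small
  scale, but the flagged-cluster count should be consulted.
* Priors are the package's defaults, not a published specification;
  sensitivity can be probed through `PriorConfig`.
* The generator's deadline-guessing share (75% of overruns) is a design
  choice matched to the observed ~1.8% timeout rate, not a measured
  quantity.
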