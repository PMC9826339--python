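# Methods

This note records the statistical model implemented in `stratwin`, the
conventions the implementation fixes where the mathematics leaves slack, and
what the synthetic-data experiments do and do not demonstrate.

## Model and estimation

A composite endpoint records, per subject, a survival time D, nonfatal event
times (a single type; the first one, T, is what the prioritized rule uses),
independent censoring C, follow-up X = D ∧ C, and covariates Z.  A *win
rule* 𝒲 compares two outcome histories up to a horizon t and declares at
most one winner.  All rules here satisfy three axioms: the comparison uses
only data observed by t; it is antisymmetric (δ_ij + δ_ji ∈ {0,1}); and the
status freezes once both subjects' times are exhausted, so death as a
competing risk needs no special handling.

The regression model states that, within each stratum, the ratio of
conditional win fractions equals exp{β′(Z_i − Z_j)} at every horizon — a
proportionality assumption on within-stratum win fractions only.
Between-strata comparisons are never formed, so between-strata differences
in outcome law are unrestricted; this is the win-ratio analogue of
stratifying a Cox model, and it extends the matched two-sample win ratio to
regression (a matched pair is a stratum of two).

Estimation solves the pairwise estimating equation shown in the README.
With the recommended stratum-size weight h_l = n_l/n (the Mantel–Haenszel
convention; constant in time) and the time-constant pairwise win fraction
μ, the time integral of the residual process collapses, so the fitter only
needs each pair's status at the analysis horizon τ (default: the largest
observed follow-up).  Time-varying weights would require the full residual
process; they are out of scope.

### Observed-data horizon convention

Evaluated on observed data, the pair horizon h = X_i ∧ X_j ∧ t is almost
always *one of the subjects' own event or censoring times*, so the horizon
comparison cannot be strict: an event occurring exactly at h is observed
and counts.  The implementation therefore uses inclusive comparisons
against the horizon (d ≤ h, T ≤ h) and strict comparisons between subjects
(d_j < d_i), which keeps antisymmetry exact and makes ties at identical
event times (measure-zero under continuous models) indeterminate.  The same
convention resolves censoring at exactly an event time: the event counts.

A consequence worth knowing: under the prioritized rule a pair decided by
first nonfatal events can later be *overturned* when the interim winner
dies before the pair horizon — death outranks nonfatal history.  The pair
status is therefore not monotone in the horizon (decisions by death are
absorbing; decisions by nonfatal events are provisional).  The score
process construction tracks both phases of such pairs exactly.

### Newton–Raphson settings

Start at β = 0; stop when the score sup-norm falls below 1e-9; at most 50
iterations; halve the step while the score norm would increase.  The
curvature matrix is a weighted sum of μ(1−μ)-weighted outer products of
pair differences — logistic-like and positive semi-definite — so
convergence is fast (3–6 steps in the experiments here).  A singular
curvature matrix (collinear pair differences) raises an error naming the
offending covariates.  Strata with fewer than two subjects or with no
determinate pair contribute nothing and are dropped with a log message.

## Variance estimation

Both estimators are sandwiches around the same bread (inverse of the summed
per-stratum Jacobian blocks Â_l); they differ in the middle matrix:

* **Finite strata** — each stratum's U-statistic is linearized via its
  Hoeffding projection κ̂_l(O_li) (the average of a subject's weighted pair
  residual contributions); the middle matrix is 4 Σ_l n_l^{-2} Σ_i κ̂⊗².
  Requires every informative stratum to have n_l ≥ 2 and, implicitly,
  enough subjects per stratum for the linearization to be trustworthy.
* **Diverging strata** — the middle matrix is the sum of squared stratum
  scores; valid when the number of strata grows, including matched pairs.
  At stratum size 2 the two formulas are algebraically linked (the finite
  middle matrix is then exactly twice the diverging one), which is why the
  projection formula overestimates by ≈ √2 in matched-pair designs.

The `auto` policy picks the diverging regime when the median stratum size
is ≤ 5 or the number of strata exceeds √n; both regimes are always
available explicitly.  With very few strata the stratum-sum middle matrix
is rank-deficient (the stratum scores sum to zero at the solution), so the
diverging estimator should not be used for, say, L = 2 — this is a design
constraint, not a numerical accident.

Wald confidence intervals are symmetric on the log-win-ratio scale and
exponentiated for win ratios; p-values are two-sided normal with no
multiplicity adjustment.

## Proportionality diagnostics

The partial score U(t; β̂) accumulates pair residuals up to horizon t with
the same weights as the estimating function, so U(τ; β̂) = 0 by
construction.  Each component is standardized by the square root of the
corresponding diagonal of the middle ("meat") matrix — the variance
estimate of the estimating function itself, a byproduct of whichever
variance regime is in use.  Under the model the standardized process
behaves like a time-rescaled Brownian bridge; the implementation flags a
covariate when its path leaves [−2, 2] (the conventional rule of thumb; no
formal sup-norm test is attempted).  The default evaluation grid is the
exact set of pair-status jump times; the process is piecewise constant in
between, and a uniform grid is available for plotting export.

## Synthetic-data generators

The generators emulate semi-competing-risks composite outcomes via the
Gumbel–Hougaard joint survival model with exponential margins (rates
λ_D e^{−β′Z}, λ_H e^{−β′Z}) and dependence parameter κ (Kendall's τ = 1 −
1/κ).  Sampling uses the positive-stable frailty representation (Kanter's
sampler with stable index 1/κ; exact, no numerical copula inversion).  The
model implies the proportional win-fractions regression exactly under the
prioritized rule, so parameter recovery is a sharp correctness check.

Three designs:

1. **Three strata** (shares 20/30/50%): λ_Hl = 2 + μ_H(l−1),
   λ_Dl = 0.2 + μ_D(l−1), κ_l = 2 + (l−1) (τ = 50/67/75%); covariates
   Z2 ~ N(0,1) and Z1 | Z2, l ~ Bernoulli(expit(−0.2 + 0.5 Z2 + 0.2 l)),
   so Z1 is confounded with the stratum.  Heterogeneity scenarios are
   labelled by triplets (μ_H, μ_D, μ_A) = (0.3,0.1,0.3), (0.5,0.2,0.5),
   (1.0,0.5,0.5); the dependence schedule is fixed by κ_l, so the third
   entry is a scenario label rather than a formula input.
2. **Gamma-frailty small strata**: L = n/n_l equal strata; per stratum
   λ_Hl ~ Gamma(2, rate 2), λ_Dl ~ 0.5·Gamma(3, rate 3), κ = 2; covariates
   Z1 | Z2 ~ Bernoulli(expit(γ Z2)).  Used with n_l = 2 or 4.  The
   matched-pair experiments here use γ = 0 (the neutral choice; the
   covariate model's γ is not otherwise pinned down for this design).
3. **Confounded exposure with propensity matching**: Z2, Z3 ~ N(0,1),
   exposure Z1 | Z2 ~ Bernoulli(expit(γ Z2)), outcomes from the model
   above with λ_H = 2, λ_D = 0.2, κ = 2, β = (β1, −0.5, 1.2).  A logistic
   propensity P(Z1=1 | Z2) is fit, and exposed subjects are greedily
   1:1-matched without replacement to the nearest control on the logit
   propensity, processed in random order, within a caliper of 0.2 SD of
   the logit propensity.  The caliper is essential, not cosmetic: with
   comparable group sizes, caliper-free 1:1 matching pairs *everyone*, and
   the mean within-pair imbalance then equals the marginal imbalance — no
   deconfounding occurs.  With the caliper, ~20% of exposed subjects go
   unmatched under strong confounding and the within-pair confounder gap
   collapses to a small fraction of the unmatched gap (asserted in the
   test suite at γ = 0.5).

### Censoring calibration

Censoring is independent Uniform(0, c).  The scale c = 2.0998 was fixed
once by bisection (n = 100 000 draws of the base three-strata design,
β = (−0.5, 0.5)) so that 35% of subjects have an observed death — the
stated death rate for this design — with the complementary 65% ending
follow-up without one.  A caveat recorded deliberately: no independent
censoring law can make only 65% of *nonfatal* events observed while 35% of
the much slower deaths are (nonfatal events at rates ≥ 2 are observed for
>80% of subjects whenever a third of deaths are), so the 35/65 split is
implemented as deaths vs non-death terminal states.  The same c is reused
in all three designs.

### What the experiments show — and what they do not

The Monte Carlo harness (`run_table`) reproduces four kinds of operating
characteristics: estimation (bias/SE/SEE/coverage of stratified vs naive
fits under stratum confounding), testing (level and power), variance-regime
behavior on matched pairs, and two-sample comparators under exposure
confounding.  Replicate counts default to 500 (the experiments are exact
replicas at reduced Monte Carlo size; at 500 replicates binomial error on a
coverage probability is about ±2 percentage points).  Seeds: one master
seed per experiment, replicate streams spawned deterministically, so every
table is bit-reproducible.

The generators share the structure of real composite-endpoint trials
(prioritized outcomes, dependent death/nonfatal times, stratum
heterogeneity, covariate confounding, independent censoring), but not their
messiness: no ties (continuous times), no covariate-dependent or informative
censoring, a single nonfatal event type, proportional effects by
construction, and modest dimensions.  Passing tests therefore certify the
estimating-equation machinery and its calibration under the model, not
robustness to violations the model excludes (IPCW-style censoring
adjustment, time-varying covariates and left truncation are explicit
non-goals).

## Known limitations

* One nonfatal event type (K = 1).  The prioritized and first-event rules
  only need the first nonfatal time; the recurrent rule is restricted to a
  single type by construction.
* The recurrent-event win rule implements the verbal hierarchy (death
  first; fewer events wins; tied counts broken by the later latest
  occurrence losing) as a documented reconstruction; unlike the other two
  rules its pair status can oscillate while both subjects are alive.
* No unified variance estimator for the intermediate regime (moderately
  many moderately sized strata); choose a regime explicitly or accept the
  `auto` heuristic.
* Weights other than n_l/n are not implemented; they would change
  efficiency, not the estimand.
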