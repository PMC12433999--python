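# Methods

## The estimation problem

`clustprev` estimates the prevalence of a rare, self-reported condition from a
two-stage census-style survey in which individuals are nested in households,
each household is screened by exactly one interviewer, and interviewers work
in exactly one of a small number of sites.  Ignoring this structure leaves the
point estimate roughly unchanged but understates its standard error, because
responses within a household (shared environment), within an interviewer's
workload (how questions are asked), and within a site are positively
correlated.

The outcome model is an intercept-only ("empty") logistic regression with
nested Gaussian random intercepts.  For individual *k* in household *h*,
screened by interviewer *j* of site *i*:

    Y_ijk ~ Bernoulli(pi_ijk)
    logit(pi_ijk) = beta0 + u_i + v_ij + w_h
    u_i ~ N(0, sigma_u^2),  v_ij ~ N(0, sigma_v^2),  w_h ~ N(0, sigma_w^2)

all effects independent.  Any ordered subset of the three levels can be
fitted.  There are no covariates: the empty model is the estimand-defining
model, and the prevalence is a transform of `beta0` and the variance
components.

**Estimands.** The package reports a *population-averaged* prevalence by
default: `1000 * E[logit^{-1}(beta0 + Z)]` with `Z ~ N(0, sigma_u^2 +
sigma_v^2 + sigma_w^2)`, computed by Gauss–Hermite quadrature.  This is the
rate a census of the population would show, and it is the quantity the crude
estimator targets.  A *cluster-conditional* variant, `1000 *
logit^{-1}(beta0)` (the rate in a cluster whose effects are exactly average),
is exposed and labelled; for a rare outcome it is noticeably smaller because
averaging over clusters on the logit scale lifts the mean.  All outputs carry
an `estimand` label so the two are never mixed.

## Intraclass correlation convention

For a binary outcome modelled on the logistic scale the individual-level
residual has no free variance; the latent-threshold convention fixes it at
`pi^2/3` (the variance of the standard logistic distribution).  The ICC of a
level is

    ICC_level = sigma_level^2 / (sum of included sigma^2 + pi^2/3)

and the *cumulative* ICC of a model is the sum of its cluster variances over
the same total.  The cumulative ICC is monotone non-decreasing in the set of
included levels, which is how a site+interviewer model's ~0.10 rises to ~0.41
when the household level enters.  Levels with ICC above 0.1 are flagged as
substantially clustered.

## Likelihood evaluation

The marginal likelihood integrates the random effects out level by level,
innermost first, exploiting conditional independence: household integrals
given interviewer and site effects, interviewer integrals given site effects,
site integrals last.  Because the model is intercept-only, every household
enters the likelihood only through its size and event count; households with
the same parent cluster and the same (size, events) pair are collapsed into
multiplicity-weighted groups, which is what makes a fit on ~56,000 records
run in about a second.

Three evaluation schemes are available (`ModelSpec.estimation` /
`agq_scope`):

* **Joint Laplace** (`laplace`, the `ModelSpec` default).  The joint mode of
  all random effects is found by damped Newton iterations; the Hessian is
  tree-structured (each cluster couples only to its ancestors, with equal
  coupling to every ancestor), so the log-determinant and the Newton solves
  use an exact innermost-first elimination that runs in linear time in the
  number of clusters.
* **Adaptive Gauss–Hermite on the innermost level, Laplace outside**
  (`agq`, scope `innermost`, Q = 9 by default).  The innermost level is where
  clusters are small — households of 1–15 members, typically 2–4 — and where
  the Laplace approximation for binary data is known to fail badly: with a
  ~1% outcome and three observations per cluster, the Laplace objective is so
  biased at large household variance that the apparent maximum runs away to
  absurd values (we observe fitted household variances above 100 on preset
  data).  One-dimensional adaptive quadrature per household group (nodes
  centred and scaled at each group's conditional mode) removes this at
  negligible cost.  The outer levels hold hundreds to tens of thousands of
  observations per cluster, where Laplace is accurate.  This scheme is what
  the experiment grid and the shipped analyses use.
* **Dense tensor-product Gauss–Hermite** (`agq`, scope `all`).  Exact in the
  limit of large Q; cost grows as Q^levels, so it is reserved for small
  fixtures.  The test suite checks it against an independent, deliberately
  naive recursive quadrature oracle (`loglik_oracle`) to 1e-8 on fixtures and
  requires 1e-4 agreement at fitted optima.

**Optimisation.**  Parameters are `beta0` and one log-SD per level (log-SD
keeps variances non-negative; a fitted log-SD below −6 is reported as a zero
variance).  Starting values: `beta0` from the closed-form intercept-only fit,
all SDs at 0.3.  A bounded L-BFGS-B leg with finite-difference gradients
makes fast global progress and a Nelder–Mead polish finishes, because the
quadrature objective has a small (~1e-4) noise floor that finite differences
cannot resolve near the optimum.  Likelihood evaluations are stateless (all
inner modes restart from zero) so the objective is a deterministic function
of the parameters; inner Newton loops stop on the Newton decrement or when a
step no longer improves the objective.  Fits are bit-reproducible.

**Standard errors.**  `se(beta0)` comes from the observed information — a
central-difference Hessian over the free parameters at the optimum —
inverted jointly, so the uncertainty of the variance components propagates
into it.  Coordinates whose variance sits at the zero boundary carry no
curvature and are held fixed.  The full parameter covariance is kept on the
`FitResult`.

**Adjusted-prevalence intervals.**  The default 95% interval for the
population-averaged prevalence is a delta-method Wald interval over
`(beta0, log-SDs)` using that covariance.  The simpler construction — push
`beta0 ± 1.96 se` through the averaging transform at plugged-in variances —
is also available (`ci_method="transform"`), but it systematically
over-covers: `beta0`-hat and the fitted variances are strongly negatively
correlated (a larger variance forces a lower intercept for the same marginal
rate), and ignoring that correlation overstates the prevalence-scale
variance.  In a pilot of 300 clustered replicates the transform interval
covered 100% while the delta interval covered 95.7%.

**Crude intervals** are binomial Wald on the proportion scale times 1,000,
with 1.96 for every interval and no truncation of negative lower bounds —
the convention that reproduces the published tables' arithmetic, including
the negative lower bound for the rarest interviewer stratum.

**Likelihood-ratio tests** report the naive chi-square upper tail.  When the
null pins a variance component at zero the true null distribution is a
mixture of chi-squares and the naive p-value is conservative; the result
carries a `boundary` flag instead of a correction.

## The synthetic generator

`epina_like_config()` builds populations with the structure of the two-site
Nairobi informal-settlement census the package emulates: 2 sites; 12 and 8
villages; 18 and 12 interviewers, each working whole villages within one
site (villages host one or two interviewers when interviewers outnumber
villages, and their households are split); ~1,150 and ~665 households per
village; household sizes 1–15 from truncated-geometric distributions with
site means 2.5 and 4.0 (the first site is the industrial-area settlement
with small, mobile households); ~56,000 individuals in total.  The preset
*solves* its parameters rather than hard-coding estimates: the three SDs
from the target latent ICCs (0.397 household, 0.101 interviewer, 0.070
site) under the `pi^2/3` convention, and `beta0` from the target marginal
rate of 9.4/1,000 by root-finding on the quadrature integral.

All randomness flows from one integer seed through named
`numpy.random.SeedSequence` spawn keys (structure, sizes, effects, outcomes,
sex, attrition, imputation, replicates), so every stage is independently
reproducible and replicate streams never collide.

What the generator does **not** emulate: covariate effects (X·beta is fixed
at zero), the two-stage screen/confirm cascade and its error processes,
interviewer-sex effects on the outcome (sex is generated but inert by
default), spatial layout, and household sizes correlated with risk.  Passing
tests therefore show that the estimators recover the parameters of *this*
data-generating model at realistic scale — not that the real survey's
numbers are correct.

Realized populations vary a lot across seeds: with only two sites and thirty
interviewers, the realized crude rate of a single population can sit far
from 9.4/1,000 even though the average over seeds converges to it.  That is
a property of the design being emulated, not a generator defect.

## Attrition and imputation

**MAR attrition.**  Dropout affects the outcome only; cluster labels and
covariates stay observed.  The dropout logit is linear in observed fields —
an indicator for a reference site, centred household size, interviewer sex —
and its intercept is calibrated by bisection so the mean dropout probability
hits the target rate (10% / 20% in the shipped analyses) to 1e-6.  Because
the probability never touches the outcome, the mechanism is MAR by
construction, and the suite verifies empirically that missingness is
independent of the held-out outcome within covariate strata.

The experiment grid aims the site coefficient at whichever site shows the
higher *observed* prevalence (an observed-data rule, so still MAR).  The
grid's acceptance analyses use a site coefficient of 1.5 — a strongly
prevalence-correlated dropout regime in which complete-case analysis is
visibly biased low, matching the qualitative behaviour the emulated study
reported; the library default is a milder 0.4.

**Sequential KNN imputation.**  Missing outcomes are filled from the k = 15
nearest donors under a Gower-style weighted distance over household size and
interviewer sex plus co-membership indicators weighted household 3,
interviewer 1, village 1, site 0.5 (a mismatch adds the weight).  Household
co-membership dominates by construction: in an empty model the cluster
structure is the only signal available, and household donors always sort
first.  Records are processed in decreasing order of observed household
members (ties by record id) so the best-informed cells are imputed first;
previously imputed records then join the donor pool.

The neighbourhood size matters more than is obvious.  With a very small k
(say 5) the donor share is a one-or-two-donor estimate of the local event
rate, and stochastic imputation from such noisy cell-level rates inflates
the between-household variance of the completed data — the classic
small-cell hot-deck effect.  On preset data at 20% dropout, k = 5 inflates
the fitted household ICC by ≈ +0.14, while a plain majority vote keeps the
ICC but collapses the event rate (completed-data prevalence ≈ 2 per 1,000
below truth).  k = 15 with the probability-matching vote preserves both: ICC
shift ≈ +0.02 (below the replicate Monte-Carlo SD) and completed-data
prevalence closer to the full-data value than complete-case analysis.

The default vote is *probability matching*: impute 1 with probability equal
to the donors' share of 1s, from a seeded stream.  A plain majority vote is
implemented but not the default, for an arithmetic reason: with a marginal
rate of ~9 per 1,000 the conditional probability of a case given any
neighbourhood almost never exceeds one half, so the mode is almost surely 0
and majority imputation deflates the completed-data rate to roughly
(1 − dropout) times the complete-case rate — *farther* from the full-data
value than complete-case analysis itself.  Probability matching preserves
local rates and, because donors are household-first, preserves the
household-level clustering; both properties are tested.  The two rules agree
for unanimous donors and for k = 1.

## The experiment grid

`run_grid` crosses attrition rates (0, 10%, 20%) with seven clustering
structures (none; each single level; site+interviewer; household+site; the
full three-level model) and two handlings (complete-case, sKNN-imputed),
over any number of replicates, recording prevalence, interval, variance
components, ICCs, AIC/BIC and convergence per cell; failures become
non-converged rows rather than disappearing.  `compare_models` ranks one
cell's structures by AIC with BIC as tie-break.

## Simulation sizes used by the shipped tests and acceptance script

Chosen to give adequate Monte-Carlo precision at single-CPU scale:

* ICC recovery / model selection: 100 preset replicates (~56k individuals
  each), three-level fits; Monte-Carlo SE of the mean household ICC ≈ 0.005.
* Interval coverage: 1,000 replicates of a compact two-site survey
  (~4,000 individuals, 1,000 households, household-only clustering with
  sigma_w = 2 and a 6% marginal rate, so that events are plentiful enough
  for small-sample Wald behaviour not to dominate).
* Attrition/imputation: 40 replicates for the bias comparison, 12 for the
  ICC-stability check at 20% dropout.
* The acceptance script re-runs the single-census grid once at the given
  seed and a 30-replicate ICC recovery.

## Known limitations

* **Two sites.**  A maximum-likelihood variance estimated from two clusters
  with a free intercept is biased down by roughly a factor of two
  (`sigma_u^2`-hat is essentially the half squared difference of two site
  effects after centring).  Mean recovered site ICCs therefore sit near
  0.03–0.05 against a generating value of 0.070 — an honest property of the
  emulated design, reported as such rather than patched.  Site-level
  inference from two sites should not be taken at face value in the real
  survey either.
* Pure Laplace estimation is unreliable for the household level of this
  preset (rare outcome, tiny clusters); use the default-for-analyses
  adaptive-quadrature scheme.  REML-style bias correction for the
  variance components is not implemented.
* Intervals are Wald-type throughout; no profile-likelihood or bootstrap
  intervals, no ICC confidence intervals, no design-weighted estimators.
* Single imputation only: the completed-data analysis does not propagate
  imputation uncertainty (no multiple-imputation pooling).
* The LRT boundary issue is flagged, not corrected.
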