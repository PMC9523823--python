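# Methods

## Estimands

All effects are survival-probability ratios indexed by time since exposure.
Writing `S_{A(a),M(a*)}(t)` for the probability of surviving past `t` had
the exposure been set to `a` on every pathway except the mediator process,
which takes the values it would have under `a*`:

    TE(t) = S_{(1,1)}(t) / S_{(0,0)}(t)
    DE(t) = S_{(1,0)}(t) / S_{(0,0)}(t)
    IE(t) = S_{(1,1)}(t) / S_{(1,0)}(t)

so `TE = DE * IE` holds by construction.  The indirect effect bundles every
pathway on which the exposure acts on the mediator first; pathways through
time-varying confounders that only later reach the mediator count as direct.
Ratios are undefined before the first mediator measurement; both estimators
report `IE(t) = 1` there, and the analysis population is restricted to
individuals surviving to the first visit.

## Dynamic path analysis (additive hazards)

Assumptions: additive hazard in `(A, Z0, M_0, M_current)` with arbitrary
time-varying coefficients; a linear event-time mediator model marginal over
the mediator's past; only the most recent mediator value affects the hazard;
all confounding controlled by baseline covariates.  At each distinct event
time the increment of the cumulative coefficient vector is
`(X'X)^{-1} X' dN` over the risk set; tied event times are processed once
with a multi-event counting-process jump.  Covariates are carried forward
from the latest visit (no interpolation), matching the hazard model's
"current value" assumption.  Numerical choices:

* Rank-deficient `X'X` (relative singular value below 1e-8): Moore-Penrose
  pseudoinverse with a logged warning by default; a strict mode truncates
  accumulation at the last full-rank time, and a raising mode is available.
  Continuous simulated covariates make this rare; categorical registry data
  may not.
* Mediator regressions with fewer at-risk rows than parameters carry the
  nearest preceding defined coefficients forward (logged); leading undefined
  times fall back to the first defined fit.

## Sequential-regression g-formula

The nested-counterfactual survival is an iterated integral over visit-wise
mediator and confounder densities with the exposure argument set per path.
Estimation works backwards from `K`, the last visit strictly before `t`
(survival to an integer time is governed by the hazard on the preceding
interval, so `K(t) = ceil(t) - 1`):

1. terminal factor: `P(T > t | T > K, history, A = a)` from a hazard model
   fitted once on the full follow-up with visit-updated covariates —
   additive by default (correct under the generator), Cox proportional
   hazards optional for applications;
2. M-step at visit `k`: regress the running pseudo-outcome on
   `(A, Z0, M_0, L_0, M_1..M_{k-1}, L_1..L_k)` and predict with `A = a*`;
3. L-step at visit `k`: extend to those at risk at `k-1`, set 0 for deaths
   in `(k-1, k]` (the at-risk indicator is a component of the visit-`k`
   confounder block), regress on the history excluding `L_k`, predict with
   `A = a`;
4. average the final predictions over the analysis population.

Pseudo-outcome regressions use a fractional-logit family: a logit-link
Bernoulli quasi-likelihood, well defined for responses in `(0,1)`; the
dispersion parameter affects no point estimate.  A linear family and fully
saturated designs are available; with them the recursion provably equals the
brute-force enumeration of the identification formula on discrete data (the
test suite verifies this to 1e-6 on a two-visit binary toy).  All
pseudo-outcomes and predictions are clipped to `[1e-6, 1 - 1e-6]` (logit
domain); terminal additive-hazard predictions outside `[0,1]` are clipped
and counted.  The exact covariate list per step is not uniquely pinned down
by the method's published sketch; the choice above (full measured history,
main effects) is isolated behind `GFormulaSpec` so alternatives can be
tested.  The terminal model is fitted once, not per target time: the
estimand's terminal factor is a single conditional-survival model, and
per-time refitting would multiply cost without changing the estimand.

The two estimators are algebraically equivalent when there is no `L`
process, both models are additive/linear, and everyone survives to the first
visit; the suite checks that their IE/DE curves coincide within joint Monte
Carlo tolerance at n = 2000, and the equivalence test uses the default
fractional-logit family (agreement holds at the same tolerance with the
linear family).

## Synthetic data generator

The generator emulates a four-year cohort: exposure `A ~ Bernoulli(0.5)`;
baseline confounder `Z0 ~ Bernoulli(0.6 or 0.4 | A)` (marginally 0.5 —
equivalent to the confounder affecting the exposure); mediator trajectories
with bivariate-normal random intercept/slope (mean `[2.9, 0]`, covariance
`[[0.25, -0.015], [-0.015, 0.010]]`), visit effects of `Z0`, `A`, and
optionally a time-varying confounder `L` with its own random
intercept/slope, unit residual SDs throughout; event times drawn wave by
wave from a piecewise-constant additive hazard evaluated at the wave-start
mediator (and confounder) values, waves as long as the measurement interval;
administrative censoring at `tau = 4`.  One master seed spawns a substream
per 4096-individual block, so enlarging `n` never reshuffles earlier
individuals, and counterfactual arms reuse the same raw draws (common random
numbers), which roughly halves the Monte Carlo SE of truth ratios.

Twelve scenario presets cover: constant / increasing / immediate / delayed
mediator effects on the hazard (baseline, R1-R3); mediator generation every
0.25 years with analysis restricted to annual visits and exposure-mediator
effects of +2 / -2 (F1/F2); and six time-varying-confounder mechanisms
(L1-L6), of which L6 lets the exposure raise `L` while `L` lowers the
mediator and raises the hazard — the qualitative structure of an
infection-burden confounder, and the configuration that a baseline-only
adjustment provably cannot handle.  Each preset has three sub-scenarios:
both effects present, no direct effect (`alpha_A = 0`, `psi_A = 0`), no
indirect effect (`beta_A = 0`).

Published constraints fix the exposure/confounder prevalences, the mediator
random-effect distribution, the residual SDs, the F1/F2 exposure effects,
the censoring time and per-scenario event-fraction ranges (78-92% depending
on scenario).  The remaining hazard and confounder coefficients are not
publicly documented; they were reconstructed once to satisfy all of the
above plus strict hazard positivity (validated empirically at ~1e6 draws per
scenario) and, for L6, to reproduce the published true effect triple
(TE, DE, IE) = (0.82, 0.93, 0.88) at the median event time, and then frozen.
Consequences worth knowing: percentile event times and the magnitude (not
direction) of the coarse-measurement biases in F1/F2 differ somewhat from
the published ones, because they depend on the undocumented coefficients;
the L4/L5 confounder effects are deliberately small so that hazards stay
positive under slope SDs of 5 and 10, which makes those two scenarios nearly
unconfounded here.  What passing tests show is therefore the estimators'
structural behaviour (unbiasedness where assumptions hold, the direction and
growth of coarse-measurement bias, the asymmetric effect of exposure-induced
confounding), not a digit-for-digit replication of any table.

The generator draws Gaussian mediators with death depending on the current
value only; real registry biomarkers are bounded, measured with error, missing
not-at-random, and affect hazards with memory — none of which is emulated.

## Truth computation

True curves come from simulating the four cross-world arms
`(a, a*) in {(1,1), (0,0), (1,0), (0,1)}` at large `n` with the exposure
unconfounded (`Z0` at its marginal probability) and taking ratios of the
at-risk proportions (valid because censoring is administrative only).
Individuals with events before the first visit are removed arm by arm; a
shared-index variant is available (the two differ only through Monte Carlo
noise in the populations kept).  Default `n_truth = 500,000` puts binomial
SEs below 0.0007 per curve; block-jackknife SEs of the ratio curves are
computed alongside and feed every bias comparison.  Ratios with denominator
survival below 1e-6 are reported missing rather than raised.

## Performance evaluation

Per scenario x method x estimand x time cell: `bias = mean - truth`,
`empSE = SD`, `MCSE = empSE / sqrt(nsim)` (deviations from the replicate
mean, so the identity `MCSE * sqrt(nsim) = empSE` is exact).  Percent bias
is `100 * bias / truth` on the ratio scale.  Evaluation times are the
20/50/80% quantiles of observed event times in the analysis population
(quantiles among events, so they exist even when fewer than 80% of the
population ever fails; a population-proportion variant is available).
Replicate seeds are spawned from a master seed, failures are logged and
counted, and more than 1% of failures aborts a cell.  The percentile
bootstrap resamples whole individuals so stacked landmark rows move
together; resample failures are redrawn up to a retry cap.  The
required-replicate calculator is `ceil(Var / MCSE_target^2)`.

Desk-scale problem sizes used by the shipped tests and acceptance script:
n = 2000 observations per replicate; 60-400 replicates depending on the
check; truth at 300,000-500,000 per arm.  Bias checks accept a cell when the
bias is within twice the combined Monte Carlo error (replication MCSE plus
truth jackknife SE in quadrature) or within 2% of the true ratio — the
operational definition of approximate unbiasedness for these estimands; the
2% floor also absorbs the genuine O(1/n) convexity bias (about +0.004 at the
80% event time at n = 2000) that the exp(-cumulative) transform induces.

## Landmark datasets

For each landmark age in a configurable window, individuals at risk at that
age enter as exposed (first diagnosed at exactly that age — prevalent cases
are excluded upstream) or as never-yet-diagnosed, with time reset to zero
and administrative censoring at a configurable horizon (default 4 years).
Baseline covariates come from the review before exposure assessment, the
first mediator measurement from the review after it; individual-ages lacking
the prior review are dropped and counted.  Unexposed rows of individuals
diagnosed later are kept (not censored at diagnosis, which would be
informative censoring); their later exposure change is ignored, a known
limitation.  IV-antibiotic days are binned as 0, 1-7, 8-14, 15-21, 22-28,
>28: week-long courses motivate the bins, and the boundary day 21 belongs to
the three-week bin.  The synthetic registry used in tests is labelled
synthetic and mimics structure only (staggered entry, absorbing incident
diagnosis, declining mediator, annual reviews), not any real registry's
content.

## Known limitations

* The scenario registry is a reconstruction (see above); magnitudes tied to
  undocumented coefficients are reproduced qualitatively, not numerically.
* The additive terminal model can predict conditional survival outside
  [0,1]; predictions are clipped and counted rather than remodelled.
* No informative censoring, competing risks, or discrete-time generation.
* The g-formula's per-step covariate lists are a documented reconstruction;
  alternative histories plug into `GFormulaSpec`.
* Proportion mediated is computable as `log(IE)/log(TE)` by users but is
  deliberately not a first-class performance metric: it is unstable when the
  total effect is near null.
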