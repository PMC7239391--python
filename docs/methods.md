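# Methods

## The model and its assumptions

Registration counts are modelled per cell of a five-year age band x
calendar year x gender x region grid. The count in a cell is Poisson with
mean `theta * E`, where `E` is the mid-year population (person-years) and
`theta` the underlying incidence rate; `theta` is lognormal around a
log-linear regression surface `mu = X beta` with a single variance
`sigma^2` shared by all cells. The lognormal layer is what distinguishes
the model from a Poisson GLM: registry counts from large heterogeneous
populations are overdispersed, and the layer gives every cell a latent
rate whose posterior uncertainty propagates into every downstream summary.
Assumptions worth keeping in mind: cell-level random effects are
independent (no spatial or temporal correlation beyond what the regression
surface carries), the overdispersion variance is homogeneous across cells,
and exposures are treated as known constants.

Age enters as the band midpoint (open band 85+ mapped to 90), standardised
to zero mean and unit variance, with polynomial powers taken after
standardisation; for the all-cancer grouping age is categorical with 15
levels (midpoints 17, 22, ..., 82, 90) coded with sum-to-zero contrasts.
Year is likewise standardised. Gender and region use sum-to-zero
contrasts, so every categorical effect reads as a deviation from the
average level and the "average regional effect" is exactly zero on the log
scale — which is what makes the per-region proportional differentials
well defined. Modelling starts at midpoint 17 for all-cancer and breast
and at midpoint 47 for lung, bowel and prostate; younger bands are dropped
rather than pooled. Each cancer type has a catalogued set of maximal age
and year powers and pairwise interactions; interactions use the linear
standardised terms by default (configurable power).

Break points enter the design as a step indicator `I(v >= threshold)` plus
a hinge `(v - threshold) I(v >= threshold)` in standardised units: a level
shift plus a trend change, continuous at the threshold unless the step
coefficient is nonzero. The catalogue carries year breaks at 2006 (bowel;
bowel screening) and 1989 (breast; the national breast-screening rollout)
and an age break at 50 for breast cancer. With age as band midpoints the
age-50 indicator first switches on at midpoint 52. Priors are vague:
`beta_j ~ N(0, 1e4)` and `sigma^2 ~ Inverse-Gamma(shape 1, scale 0.001)`
(density proportional to `x^-2 exp(-0.001/x)`; equivalently the precision
is Gamma(1, rate 0.001)).

## Sampler

Metropolis-within-Gibbs over `(beta, sigma^2, log theta)`:

* `beta` — exact draw from its Gaussian full conditional (ridge regression
  of `log theta` on `X` with precision `X'X/sigma^2 + I/1e4`);
* `sigma^2` — exact draw from `IG(1 + n/2, 0.001 + RSS/2)`;
* `log theta` — the conditional factorises over cells, so a single
  vectorised random-walk Metropolis step updates every cell at once.

Per-cell step sizes adapt by Robbins-Monro towards a 0.44 acceptance rate
(the scalar-target optimum) during burn-in only; retained draws therefore
come from a fixed kernel. Initialisation regresses `log((C+0.5)/E)` on `X`
(the +0.5 avoids `-inf` at zero counts), starts the latent rates at the
observed values and `sigma^2` at 0.1. Defaults: 2 chains, 4,000
iterations, half burn-in, thinning 2, mandatory seed; chains derive
independent streams from one `SeedSequence`, so runs are reproducible
bit-for-bit. Split-Rhat and bulk ESS (via ArviZ) are reported for every
coefficient and `sigma^2`, with a warning above Rhat 1.05; a single chain
is split in half so the diagnostic still exists.

Correctness is tested three ways rather than by a Geweke
successive-conditional chain (which under these vague priors
forward-simulates astronomically overdispersed counts): closed-form
moment and KS tests of both conjugate conditionals, a quadrature KS test
of the Metropolis kernel's single-cell marginal (KS < 0.05), and
20-replicate calibration of the joint sampler (95% intervals cover ~95%
of true coefficients; observed 94-96% across the packaged experiments).

## DIC, Bayes factors and forward selection

The selection-relevant likelihood is `f(D | beta, sigma^2)` with the
latent rates integrated out; the reported criterion is

    DIC = -4 E[log f(D|beta,sigma^2)] + 2 log f(D|beta_hat, sigma2_hat)

with the expectation over retained draws and posterior means plugged in.
The one-dimensional integrals are computed by *adaptive* Gauss-Hermite
quadrature (21 nodes), each cell's grid centred at the mode of its
integrand with the Laplace width. This matters: a grid centred at `mu`
with width `sigma` under-resolves the Poisson factor in high-count cells
(its width is about `C^-1/2`, much narrower than `sigma`), and the
resulting per-cell errors distort between-model DIC differences by enough
to flip selections. The adaptive rule agrees with dense numeric
integration to ~1e-11 across count regimes. A theta-conditional DIC
(Poisson deviance evaluated at the theta draws) is computed alongside for
diagnostics; it is insensitive to the regression structure and is not used
for selection.

Forward selection adds, greedily, the eligible term with the best DIC,
accepting only improvements of at least 5 — the conventional smallest DIC
difference worth attention. The margin is what rejects chance-aligned
noise covariates: with an accurately computed DIC a null term still lowers
it by a couple of units about a quarter of the time, so a bare
any-decrease rule over-selects. Interactions become eligible only once
their main effects are included. Bayes factors are available as a
secondary criterion (accept if BF > 3) via a Laplace approximation of the
marginal likelihood at the posterior mode of `(beta, log sigma^2)` with a
finite-difference Hessian.

## Changepoint detection

Annual rate series are segmented under a Gaussian cost in which both the
segment mean and variance are free; the segment cost is twice the negative
maximised log likelihood, with an optional modified-BIC `log(length)` term
per segment that discourages spuriously short segments. The penalised
optimum is found by the pruned exact dynamic program (PELT); an unpruned
O(n^2) dynamic program with identical cost and tie-breaking is kept in the
package as the reference, and a randomised 1000-series battery asserts the
two return identical segmentations. Two details make the pruned version
exact here: with a minimum segment length m, a candidate failing the
pruning inequality at time t may still be needed until t + m (its
dominating replacement is not yet feasible), so removal is delayed; and
the MBIC length term violates cost subadditivity by up to log(n/2), so the
pruning constant is −log(n/2) when that term is on.

Defaults, chosen by calibration on null (no-break) series of annual length
(n = 36) while keeping full power for screening-sized shifts: penalty
5 log n per changepoint with the MBIC correction, minimum segment length 2.
BIC counting for mean, variance and location gives (3+1) log n; the extra
log n unit compensates the short-series optimism of the free-variance
cost. At these defaults ~95% of null series yield no changepoint, a 5-sd
mean shift is located within +-1 point essentially always, and an injected
2006 level shift of x1.3 in generated national series is recovered at +-1
year in 20/20 replicates. Which series to segment (crude or standardised,
national or regional) is the caller's choice; the pipeline segments the
observed national ESP-standardised series, genders pooled.

## Age-standardisation and inequality metrics

Age-standardised rates are direct: the weighted mean of age-specific rates
under the European Standard Population 2013 weights (embedded as
constants; the open 85+ band pools ESP's 85-89, 90-94 and 95+ groups),
restricted to the modelled age range and renormalised to sum to one, and
scaled to per 100,000. AD, RD and RC are computed per posterior draw — so
the identity of the extreme regions may change across draws — and
summarised by the posterior mean (median also reported) with equal-tailed
2.5/97.5 percentile intervals. A consequence worth knowing: the per-draw
mean of max-minus-min is never smaller than the max-minus-min of the
per-region summaries, and on the bundled published 2016 regional rates the
two conventions differ by one rounding unit in one of the eight
type-gender combinations (female lung). Reported rounding follows
convention: rates to 1 decimal, AD to integers, RD and RC to 2 decimals,
half away from zero.

## Synthetic registry generator

The generator draws from exactly the model hierarchy above on a 9-region x
36-year x bands x genders grid. Exposures are smooth and plausible:
regional scales follow the real mid-2010s population ranking (2.6M to
9.0M), an age pyramid tapering after 70, 0.4%/year growth and 2% lognormal
jitter, giving 2e4-3e5 person-years per cell within documented bounds.
The default truth is lung-like: quadratic age, linear year, an age:year
interaction, a +0.22 male effect, fixed region effects between -0.10 and
+0.18 on the log scale (the ninth implied by sum-to-zero), intercept
log(150 per 100k) and sigma^2 = 0.02 — values chosen once so standardised
rates land in the 100-300 per 100,000 range typical of site-specific
incidence. Break injection adds step/hinge coefficients to the truth, so a
x1.3 level shift at 2006 is a documented generator fact that detection and
fitting must recover.

What the generator does not emulate — and hence what green tests do not
establish about real registries: ICD coding-change artefacts, late
registration incompleteness, spatially correlated random effects,
non-constant overdispersion, and exposure estimation error.

## Problem sizes and numerical choices

Validation experiments are sized for desk-scale runs: parameter recovery
uses 20 replicates of the full default grid (5,832 cells) at 2 chains x
1,200 iterations; forward selection uses 20 replicates of an 18-year grid
(2,916 cells) at 1,500 iterations with 500-draw DIC estimates (run-to-run
DIC sd ~0.2); the segmentation battery uses 1,000 series of length <= 50.
The full test suite runs in about six minutes on one CPU, the acceptance
script in about five. Other numerics: all latent-rate computation on the
log scale; a large-negative finite guard instead of -inf when a zero
Poisson mean meets a positive count; variance floor 1e-8 (with warning)
for degenerate segments; Cholesky solves for the beta conditional with a
clear error when the precision is singular; rounding half away from zero.

## Known limitations

Real registry extracts are needed to reproduce published posterior point
estimates; the package validates the machinery, not those numbers. The
Laplace Bayes factor inherits the usual asymptotic caveats and vague-prior
sensitivity (marginal likelihoods under `N(0, 1e4)` priors penalise
dimension heavily), which is why DIC is the primary selection criterion.
DIC run-to-run noise means term decisions within ~1 unit of the margin are
not reproducible across seeds. The changepoint stage assumes approximately
Gaussian annual series; heavy-tailed series would need a different cost.
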