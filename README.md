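# canmorb

Bayesian modelling of cancer registration counts by age, calendar year,
gender and region, for epidemiologists and biostatisticians studying
morbidity trends and regional health inequality. The package fits a
hierarchical Poisson-lognormal model to registry tables by MCMC, detects
temporal break points (e.g. screening-programme introductions) with an
exact penalised segmentation algorithm, converts fitted cell-level rates
into ESP-2013 age-standardised rates, and summarises regional inequality
with credible intervals. A synthetic registry generator with recorded
ground truth makes every stage testable without access to confidential
registry extracts.

## Model

For a cell indexed by age band `a` (entering as the band midpoint), year
`t`, gender `g` and region `r`, with registration count `C` and person-years
exposure `E`:

    C_{a,t,g,r} ~ Poisson(theta_{a,t,g,r} * E_{a,t,g,r})
    theta_{a,t,g,r} ~ Lognormal(mu_{a,t,g,r}, sigma^2)
    mu = X beta

The lognormal layer absorbs the overdispersion that a plain Poisson GLM
cannot. The design `X` holds polynomial terms in standardised age and year
(or 14 sum-to-zero age contrasts when age is categorical), sum-to-zero
gender/region contrasts, the catalogued pairwise interactions per cancer
type, and step + hinge terms at detected change years (1989, 2006) or at
age 50 for breast cancer. Priors are vague: `beta_j ~ N(0, 1e4)`,
`sigma^2 ~ Inverse-Gamma(1, 0.001)`.

Inference is Metropolis-within-Gibbs: exact Gaussian and Inverse-Gamma
draws for `beta` and `sigma^2`, and one vectorised adaptive random-walk
Metropolis update per cell for `log theta`. Model comparison uses the DIC
with the latent rates integrated out by adaptive Gauss-Hermite quadrature,
plus optional Laplace-approximation Bayes factors.

Inequality statistics, computed per posterior draw: the absolute and
relative gaps between the highest- and lowest-incidence regions in year t,

    AD_t = HR_t - LR_t          RD_t = (HR_t - LR_t) / LR_t

and the percentage change per region between the first and last year,
`RC_r = 100 (R_{2016,r} - R_{1981,r}) / R_{1981,r}`, all on ESP-2013
age-standardised rates per 100,000.

## Worked example

Reconstruct the 2016 male lung-cancer regional gap from published regional
age-standardised rates:

```python
import canmorb as cm

pub = cm.published_rates_2016()
lung_m = pub[(pub.cancer_type == "lung") & (pub.gender == "male")]
series = cm.StandardisedRateSeries.from_point_rates(lung_m.assign(year=2016))
ad = cm.absolute_difference(series, 2016, "male")
rd = cm.relative_difference(series, 2016, "male")
print(cm.round_half_away(ad.point), cm.round_half_away(rd.point, 2))
```

prints

```
89.0 0.55
```

i.e. in 2016 the highest-incidence region (North East, 250.5 per 100,000)
exceeded the lowest (South East, 161.7) by 89 per 100,000, a 55% relative
gap. A full synthetic pipeline — generate a registry, detect breaks, fit,
standardise and summarise — runs from one config:

```bash
canmorb run --config config.yaml --out-dir out/
```

```yaml
# config.yaml
seed: 11
cancer_type: lung
stages: [simulate, changepoints, fit, metrics]
sampler: {n_chains: 2, n_iterations: 2000, burn_in: 1000}
```

which writes the simulated table, detected break years, posterior draws,
standardised-rate series and AD/RD/RC tables, plus a manifest with seeds
and content digests sufficient to reproduce the run bit-for-bit.

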