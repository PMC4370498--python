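# raptorcount

Detection-corrected occupancy and abundance models for raptor point-count
surveys along gradients of human construction.

Repeated point counts never see every bird that is present, so raw counts
confound *how many birds are there* with *how likely you are to see one*.
`raptorcount` implements the two standard hierarchical corrections for
surveys of a raptor community in a steppe landscape crossed by roads,
fences, settlements and a city, where each site's covariates are distances
(km) to the nearest instance of five classes of human construction:

**Multi-species occupancy model** (Bayesian, for species richness).
True occurrence of species *k* at site *i* is latent:

    z_ik ~ Bernoulli(ψ_ik)                      logit(ψ_ik) = a_k + Σ_c β_ck x_ic
    y_ijk | z_ik ~ Bernoulli(p_k · z_ik)        logit(p_k)  = b_k

Species-level parameters are draws from community hyper-distributions —
slopes β_ck ~ N(μ_βc, σ_βc), and the intercept pair (a_k, b_k) bivariate
normal with correlation ρ, because widespread species also tend to be easy
to detect. Site richness is the derived quantity N_i = Σ_k z_ik computed
from posterior draws of z, and community-level effects of each feature
class are read off the hyper-means μ_βc. Inference is Metropolis-within-
Gibbs MCMC (exact Gibbs for z, adaptive random walks frozen after burn-in
for everything else) with Gelman–Rubin R̂ convergence checks.

**Negative-binomial N-mixture model** (maximum likelihood, for abundance).
Latent site abundance is marginalized out of repeated counts:

    N_i ~ NegBin(λ_i, α)       log(λ_i) = α_0 + Σ_c β_c x_ic
    y_ij ~ Binomial(N_i, p)    p = inv-logit(η)

with the ecological NB parameterization Var(N) = λ + λ²/α. The likelihood
truncates the infinite sum over N at a bound K chosen so the neglected tail
is below 1e-8, fits by multi-start quasi-Newton, and reports Wald z, p and
significance stars (\*p≤0.1, \*\*p≤0.05, \*\*\*p≤0.01) per coefficient, a
logit-scale interval for p, and the most influential covariate (largest
|standardized estimate| among those with p ≤ 0.1).

Because all covariates are *distances*, a **negative** coefficient means the
response **increases with proximity** to that feature class.

A synthetic-data generator reproduces the field design — 22 transects
perpendicular to a primary road, four sites per transect at 1/2/3/5 km,
subsampled to 77 sites, each surveyed 2–12 times — with every latent
quantity returned, so both inference engines are validated by parameter
recovery against known truth.

## Worked example

```python
import numpy as np
from raptorcount import (DesignConfig, NMixtureParams, NMixtureConfig,
                         generate_design, simulate_counts, fit_nmixture,
                         detection_probability_ci, most_influential_effect)

design = generate_design(DesignConfig(n_sites_target=77), seed=1)
truth = NMixtureParams(alpha0=2.5, beta=np.array([-0.5, 0, 0.3, 0, -0.4]),
                       alpha_disp=1.0, eta=float(np.log(0.1 / 0.9)))
counts, _ = simulate_counts(truth, design, seed=2)
fit = fit_nmixture(counts, design.covariates, NMixtureConfig(seed=0))
print(fit.coefficient_table().round(3))
print("p =", detection_probability_ci(fit))
print("most influential:", most_influential_effect(fit))
```

prints

```
        parameter  estimate     se      z      p stars
0          alpha0     1.990  0.373  5.332  0.000   ***
1    primary_road    -0.219  0.117 -1.870  0.061     *
2  secondary_road     0.013  0.133  0.099  0.921
3           fence     0.391  0.108  3.631  0.000   ***
4      settlement     0.068  0.135  0.504  0.614
5            city    -0.248  0.121 -2.051  0.040    **
6  log_alpha_disp     0.511  0.259  1.974  0.048    **
7             eta    -1.691  0.428 -3.954  0.000   ***
p = (0.15568716301975805, 0.07386690762848276, 0.29888859396554573)
most influential: fence
```

The fit recovers the simulated signs: abundance rises toward primary roads
and the city (negative distance coefficients) and falls toward fences
(positive), with the fence effect the strongest standardized coefficient
that clears the p ≤ 0.1 gate. The detection estimate (0.156 against a true
0.10) shows the λ–p trade-off typical of N-mixture fits on one realization;
across 100 replicates the coefficient estimator is unbiased (see below).

The same workflow runs from the shell:

```bash
raptorcount simulate --seed 1 --model counts --out sim/
raptorcount fit-nmixture --counts sim/counts.csv --covariates sim/covariates.csv --out fit.csv
raptorcount fit-occupancy --counts sim/counts.csv --covariates sim/covariates.csv --out run/
raptorcount diagnose --draws run/hyper_draws.csv --out rhat.csv
raptorcount report --run-dir run/
```

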