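# Methods

## The two models

### Multi-species occupancy

Each of the K species in the surveyed community occupies site *i* with
probability ψ_ik, and is detected on any one survey of an occupied site
with probability p_k:

    z_ik ~ Bernoulli(ψ_ik)
    y_ijk | z_ik ~ Bernoulli(p_k z_ik),   j = 1..J_i surveyed replicates

    logit(ψ_ik) = a_k + β_1k x_i1 + ... + β_5k x_i5
    logit(p_k)  = b_k

The x_ic are standardized distances (mean 0, SD 1, divisor n−1) to five
classes of human construction: primary roads, secondary roads, fences,
settlements, cities. Species-level parameters are exchangeable draws from
community hyper-distributions: β_ck ~ N(μ_βc, σ_βc) independently per
covariate, and the intercept pair (a_k, b_k) jointly bivariate normal with
correlation ρ. The correlation is placed on the *intercepts* deliberately:
the ecological motivation — locally abundant species are both more
prevalent and easier to detect — is a statement about baseline occurrence
and baseline detectability, not about covariate responses.

Detection is constant within species (p_k): no site- or visit-level
detection covariates are modeled. The community is assumed closed over the
survey period, and only observed species are modeled — there is no
data-augmentation for never-detected species.

Site richness is never a parameter; it is the derived posterior quantity
N_i = Σ_k z_ik, computed per MCMC draw of the occurrence matrix, so its
posterior mean equals the mean of the draws exactly (this identity is
asserted in the tests). Community-level effects on richness are read off
the hyper-means μ_βc; because covariates are distances, a negative μ_βc
means richness rises with proximity to that feature class, and an effect
is called significant when the central 95 % credible interval excludes 0.

**Priors.** Weakly informative, configurable: hyper-means ~ N(0, 10²),
hyper-SDs ~ Uniform(0, 10), ρ ~ Uniform(−1, 1). On the logit scale an SD of
10 is far flatter than any plausible effect, while remaining proper.

**Sampler.** Metropolis-within-Gibbs. The latent z_ik are updated by exact
Gibbs draws from the closed-form full conditional — occupancy is certain
after any detection; otherwise P(z=1 | ·) = ψ(1−p)^J / (ψ(1−p)^J + 1−ψ).
All continuous parameters use Gaussian random-walk Metropolis, vectorized
over the K species within each parameter block (species are conditionally
independent given the hypers, so the accept/reject decisions are made per
species in parallel). Step sizes adapt every 50 sweeps during burn-in
toward a 0.35 acceptance rate and are frozen afterwards, so the post-burn-in
kernel satisfies detailed balance. Default schedule: 3 chains × 20,000
sweeps, first half discarded, thinned to 2,000 kept draws per chain.
σ- and ρ-proposals falling outside their supports are rejected outright.

Hierarchical logit models develop a *funnel*: if a hyper-SD drifts toward
zero, all species effects are pinned to the hyper-mean and neither the SD
nor the effects can escape by individual random walks — a chain can sit in
the funnel neck long enough to fail R̂. Each sweep therefore also performs
one *group move* per hierarchical block (each covariate's slopes, the
occupancy intercepts, the detection intercepts): propose σ′ = σe^s,
μ′ = μ + t, θ′_k = μ′ + (θ_k − μ)e^s jointly. The Gaussian prior ratio
contributes −Ks and the (K+1)-dimensional scaling Jacobian +(K+1)s, so the
acceptance log-ratio reduces to the likelihood change plus s plus the
hyper-mean prior change. These moves travel along the funnel axis and in
practice remove the stuck-chain failures entirely.

All chains are advanced together in one vectorized state (a leading chain
axis on every array); chains share no information — they only share numpy
calls — and are distinguished by independent random initial values and
proposal noise from a single seeded generator.

**Diagnostics.** The classic Gelman–Rubin potential scale reduction factor
(between- vs within-chain variance of the kept draws), computed per
monitored hyper-parameter; R̂ < 1.1 is the working convergence criterion
and any violation raises a warning, never a silent pass. With identical
constant chains the statistic is undefined and reported as NaN. The
implementation is deliberately the classic (non-split, non-rank-normalized)
form; a test cross-checks it against arviz's rank-normalized split-R̂ on
well-behaved chains.

### Negative-binomial N-mixture

For a single species (or the counts summed over species, for total
abundance), latent site abundance follows

    N_i ~ NegBin(λ_i, α),   log(λ_i) = α_0 + Σ_c β_c x_ic
    y_ij ~ Binomial(N_i, p),  p = inv-logit(η)

NB convention: mean λ, overdispersion α, Var = λ + λ²/α, i.e. scipy's
`nbinom(size=α, prob=α/(α+λ))`. Conventions differ between packages —
here **larger α always means less overdispersion**, with the Poisson
recovered as α → ∞.

The marginal likelihood sums N from max_j(y_ij) to a truncation bound K,
evaluated in log space. K is chosen so the NB upper-tail mass beyond K at
the largest fitted site mean is below 1e-8 (and never below the maximum
observed count); after each fit the bound is enlarged and the fit repeated
until the log-likelihood is stable to 1e-6. A hard cap (K = 3000 by
default) guards against the known N-mixture pathology where the likelihood
is maximized along the ridge λ → ∞, p → 0; generous box constraints on the
optimizer serve the same purpose, and any fit touching the cap or a bound
is flagged `boundary` with its SEs marked unreliable rather than silently
reported.

Optimization is L-BFGS-B over (α_0, β_1..5, log α, η) — the log/logit
scales keep α > 0 and p ∈ (0,1) — with 5 starts (two detection-probability
heuristics plus seeded random perturbations), keeping the best likelihood,
because the (λ, p) profile can be multimodal. Standard errors come from the
inverse of a central-finite-difference observed information matrix at the
optimum; per-coefficient inference is a two-sided normal Wald test with
stars at p ≤ 0.1 / 0.05 / 0.01, and the detection interval is Wald on the
logit scale, back-transformed.

**Most influential covariate.** Among distance coefficients with Wald
p ≤ 0.1, the one with the largest absolute standardized estimate; none if
no coefficient passes the gate. The p-gate matters: a larger raw
coefficient that fails it is passed over (the tests include exactly such a
case). This rule is this package's operationalization of "most influential"
for standardized-coefficient tables.

## Synthetic data generator

The generator emulates the field design the models were built for:

- 22 transects, 1 km apart, perpendicular to a primary road (the line
  x = 0), alternating road sides; 4 point-count sites per transect at 1, 2,
  3 and 5 km from the road (88 candidate sites), optionally subsampled
  uniformly at random to a target (77 reproduces the realized field
  effort; which sites are dropped is random because the field reasons —
  access, weather — are not modeled).
- A city placed on the road axis 6 km before the first transect, so
  distance-to-city varies smoothly along the road rather than duplicating
  distance-to-road.
- Secondary roads, fences and settlements as homogeneous Poisson point
  processes; a site's covariate is the distance to the nearest feature.
  Intensities (0.10, 0.60, 0.05 features/km²) were fixed once so that
  nearest-feature distances fall at steppe-realistic scales (fences within
  a kilometre or so, settlements a few kilometres) and give the five
  covariates distinct, non-collinear spatial structure.
- Replicate surveys per site drawn uniform-integer on [2, 12], with no
  seasonal or diurnal structure (the field protocol controlled for both by
  design).

Simulated detection histories and counts come from exactly the generative
models above, with all latent quantities (z, N, species effects, ψ, p)
returned, and are bit-reproducible under a fixed seed.

What the generator does **not** emulate: spatial autocorrelation in
occupancy beyond what the shared covariates induce, open-population
dynamics, observer effects, double counts, or site-varying detection. A
passing recovery test therefore shows the estimators work when the model is
true at the field design's scale — not that the model is true of any field
system.

## Study-condition truths for the recovery experiments

- N-mixture: α_0 = 2.5 (λ ≈ 12 birds in range at an average site),
  β = (−0.5, 0, 0.3, 0, −0.4), α = 1 (strong overdispersion), p = 0.1
  (low per-survey detection); 100 replicate datasets of 77 sites. Checks:
  mean β̂_1 within 2 Monte-Carlo SEs of −0.5, and 95 % Wald coverage in
  [0.90, 0.99].
- Community occupancy: 11 species, 77 sites; one real community effect
  (μ_β,city = −1.5, occupancy rising toward the city) and four null
  effects, σ_β = 0.5 for all slopes, μ_a = −0.5 / σ_a = 1.0,
  μ_b = −1.0 / σ_b = 0.7, ρ = 0.5; 20 replicate communities. Checks: the
  city effect flagged in ≥ 90 % of fits, null effects in ≤ 15 %, and
  R̂ < 1.1 throughout.
- Replicated MCMC fits use 3 chains × 12,000 sweeps (half burn-in, 1,000
  kept per chain after thinning) — enough for R̂ comfortably under 1.1 on
  this posterior; the library default remains 3 × 20,000 and heavier
  schedules are a config field away.

## Numerical choices and edge cases

- Bernoulli/logit likelihoods use the softplus identities
  log σ(t) = −log(1+e^(−t)) and z·log σ + (1−z)·log σ(−t) = z·t + log σ(−t);
  the NB-binomial marginal is summed with `logsumexp`.
- Standardization uses the n−1 divisor; a constant covariate column is an
  error naming the column, and the centering constants are stored so raw
  and standardized scales round-trip to 1e-10.
- Unsurveyed replicates are represented by an explicit mask, never by
  zeros: a zero inside the mask is a real "no birds seen" observation and
  enters both likelihoods; cells outside the mask are zeroed on ingestion
  and touched by nothing.
- Species with zero detections are retained in community data structures;
  the N-mixture fitter refuses them (the model is unidentifiable without a
  single count).
- Degenerate hyper-SDs of exactly 0 are treated as point masses (the
  corresponding species parameter is pinned to the hyper-mean), which is
  what makes small fixed-hyper-structure test problems exactly comparable
  to grid-posterior oracles.
- Wald p-values use the normal reference distribution, not t.

## Known limitations

- The occupancy sampler is single-site-process: no spatial random effects,
  no multi-season dynamics, no model selection.
- N-mixture SEs are asymptotic (observed information); they are flagged,
  not fixed, near boundaries. On sparse data (few sites × few replicates ×
  low p) the λ–p ridge can make the abundance intercept effectively
  unidentified even when the covariate coefficients are fine.
- ML coefficient estimates in the N-mixture model, like most nonlinear
  MLEs, are not exactly unbiased in finite samples: at the 77-site design
  under low detection the recovery study (the mean estimate reported by
  the reproduction script) can sit a few hundredths below the truth even
  though interval coverage is nominal; the effect disappears as the number
  of sites grows.
- The classic R̂ is insensitive to some pathologies the rank-normalized
  split version catches; for the short, well-mixing chains used here the
  two agree to ~0.02.
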