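# Methods

## The model

`wpindex` estimates how a community of ground-dwelling vertebrates changes
over time from camera-trap detection histories, correcting for the fact
that a species present at a sampling point is often not photographed.

For one species, the data are ternary sites × periods matrices per annual
season: 1 (photographed), 0 (sampled, not photographed), NA (camera not
active). The multi-season occupancy model has two layers:

* **Ecological process.** Site *j* carries a latent occupancy state
  Z<sub>jt</sub> per year. In year 1, Z<sub>j1</sub> ~ Bernoulli(ψ<sub>j1</sub>)
  with logit(ψ<sub>j1</sub>) = βx<sub>j</sub> (site covariates: elevation,
  canopy height, distance to edge, ...). Between years, an occupied site
  stays occupied with apparent survival φ<sub>t</sub> (local extinction
  1−φ<sub>t</sub>) and an empty site is colonized with probability
  γ<sub>t</sub>, giving the recursion
  ψ<sub>t+1</sub> = ψ<sub>t</sub>φ<sub>t</sub> + (1−ψ<sub>t</sub>)γ<sub>t</sub>.
* **Observation process.** Within a year the state is closed; each sampled
  period yields a detection y ~ Bernoulli(Z·p<sub>t</sub>). Detections are
  impossible at unoccupied sites, so non-detection at an occupied site is a
  false negative that the model accounts for.

The marginal likelihood of a site's multi-year history sums over the latent
chain with a scaled two-state forward recursion (exact, linear in years);
sites are independent, so the dataset log-likelihood is the sum over sites.

Six candidate structures are fitted per species: a fully constant
null model; year-specific φ/γ with constant or year-specific p; and
year-1 occupancy driven by elevation, elevation+canopy or elevation+edge
(additive, logit scale). Species with fewer than 15 site-detections in
every year are restricted to the null-type structures. Maximum-likelihood
fits (L-BFGS-B on the unconstrained scale, 5 seeded starts, objective
tolerance 1e-10, SEs from the inverse observed information) are compared by
AIC (ties break toward fewer parameters); the selected structure is refitted
by MCMC, and DIC is reported alongside.

## The sampler

The Gibbs/Metropolis sampler exploits conjugacy wherever the model allows:

* Z<sub>jt</sub> is drawn from its exact full conditional given the
  neighbouring years, the year's detection history and the current
  parameters (sites vectorized, years scanned in order). A year with a
  detection forces Z = 1.
* φ, γ, p have Beta(1,1) priors and Beta full conditionals given the latent
  transition/detection counts (pooled across years when constant).
* β has a Normal(0, sd 10) prior on the logit scale and a random-walk
  Metropolis update whose proposal scale adapts only during burn-in
  (target acceptance ≈ 0.35), keeping the post-burn-in chain valid.

Defaults mirror a full survey-scale analysis — 5 chains × 30,000
iterations, burn-in 20,000, thinning 3 — while the pipeline default is a
desk-scale 3 × 6,000 / 4,000 / 2 configuration (`DESK_MCMC`); the survey
configuration is available via `mcmc: survey` in the pipeline config.
Convergence is monitored with the classical Gelman–Rubin potential scale
reduction per scalar parameter; any R̂ > 1.1 attaches a warning (never
fatal). All chains derive from a single integer seed through spawned
`SeedSequence` streams, so runs are bit-reproducible.

Each retained draw stores two derived annual occupancy series: the
*finite-sample* occupancy (mean of Z across sites) and the *expected*
occupancy (recursion applied to that draw's parameters, with ψ₁ averaged
across sites for covariate models).

### Which occupancy feeds the community indices

The WPI and λ ratios consume the **expected** series by default
(`psi_kind="expected"`), with the finite-sample series available as an
option. The reason is a degeneracy of the finite-sample version under
high cumulative detection: with p = 0.4 per period and 15 periods, the
chance of missing an occupied site-year entirely is (1−0.4)¹⁵ ≈ 5·10⁻⁴, so
the data pin Z almost exactly, the finite-sample draws collapse to the
realized occupancy, and index intervals degenerate to points that reflect
binomial realization noise rather than parameter uncertainty. The expected
series propagates the posterior uncertainty of (β, φ, γ) and behaves
correctly in both low- and high-detectability regimes.

## Goodness of fit

The chi-square Bayesian posterior predictive check compares, at each
retained draw, the observed annual aggregated detection counts O_t with the
draw-conditional expectation E_t = p_t × (sampled periods at sites occupied
under that draw's Z), via Σ_t (O_t − E_t)²/(E_t + c) with stabilizer
c = 0.5 (rare species make small expected counts routine; c bounds the
ratio). A replicate dataset is then simulated from the same draw with the
observed NA pattern — aggregated per year, so the check is invariant to
site ordering — and the Bayesian p-value is the fraction of draws whose
replicate discrepancy exceeds the observed one. Values near 0 or 1 signal
misfit; posterior predictive p-values are conservative, so well-specified
data concentrate near 0.5 rather than being uniform. The replicate is
compared against the same E_t as the observed data (the alternative — a
freshly drawn expectation per replicate — is a coherent variant but is not
what the per-iteration discrepancy idiom computes).

## Community indicators

* **WPI.** For a species set S, each posterior draw m gives
  WPI<sub>t,m</sub> = (∏<sub>i∈S</sub> ψ<sub>i,t,m</sub>/ψ<sub>i,1,m</sub>)<sup>1/|S|</sup>.
  Species are fitted independently; draws are paired by retained-draw
  index. The baseline year is identically 1. The per-year point estimate is
  min(median, half-sample mode) — occupancy posteriors of rare species are
  right-skewed, and the lower of the two central-tendency measures is the
  conservative summary. Zero baseline draws are floored at 10⁻⁶ and the
  species flagged.
* **λ ratios.** For every ordered year pair, λ = ψ(t+n)/ψ(t) per draw;
  a decline is declared when the 95% HPDI of λ lies entirely below 1, an
  increase when entirely above, otherwise no change. The same rule applies
  to WPI ratios, and the WPI can be disaggregated by hunted status,
  functional guild (herbivores split at 20 kg body mass) or IUCN status
  (least-concern vs the rest).
* **HPDI.** Shortest contiguous window over the sorted draws containing
  ⌈level·n⌉ of them. The point-estimate mode is the half-sample mode
  (recursive shortest-half), chosen over kernel density for determinism;
  its sampling noise is larger than a KDE argmax (sd ≈ 0.08 at n = 10⁵ for
  a standard normal), which the tests account for.
* **Richness.** Relative richness ψ_S is the probability that a species
  from a known regional pool (40 species by convention for the emulated
  site) is present in a year. The same dynamic-occupancy machinery is
  transposed: rows are pool species (never-detected members enter as
  all-zero rows — informative under the model), within-year replicates are
  sampling points, and detection is logit-linear in standardized log body
  mass, trophic group (herbivore/carnivore/omnivore/insectivore; the two
  herbivore guilds merge) and year. Scaled richness is ψ_S × pool size;
  uncertainty comes from a nonparametric bootstrap over sampling points
  (500 iterations by default; both the percentile interval and the
  bootstrap SE are reported, since a "± k species" summary can mean
  either).

## The synthetic-data generator

The generator draws from exactly the model above, so every downstream stage
can be validated against known truth. Defaults mirror the emulated study
design: 60 points, 5 annual seasons, 15 periods, a 13-species assemblage
with realistic guild/mass/hunted attributes, per-period detection 0.4, and
site covariates along a 30–3000 m elevational gradient (canopy height and
edge distance Gaussian-copula correlated with elevation, defaults −0.4 and
0.3). Two presets define the calibration conditions:

* `stable`: every species at its stationary occupancy
  (γ = ψ(1−φ)/(1−ψ), φ = 0.8), so the true WPI is 1 in every year;
* `hunted-decline`: hunted small herbivores get φ = 0.72 and γ = 0.01, so
  their expected occupancy falls by more than half over three transitions
  (the magnitude of decline the index is meant to flag); all other species
  stay stationary.

Missing effort is independent Bernoulli NA per cell by default, with a
"tail" mode (camera dies, all later periods NA) mimicking real failures.
The generator intentionally omits spatial autocorrelation, animal movement,
within-year state changes and observation covariates on p — passing tests
therefore demonstrate correctness of the estimators under the model's own
assumptions, not robustness to violations of them.

## Numerical choices and problem sizes

* Likelihood underflow is avoided by per-year renormalization of the
  forward pass; impossible histories return log-likelihood −∞ and are
  rejected with the offending site.
* Unconstrained optimization caps |logit| at 15 (probabilities within
  ~3·10⁻⁷ of the boundary); boundary estimates are flagged.
* Covariates are standardized (mean 0, sd 1, ddof = 1) before entering any
  design matrix; categorical covariates are one-hot with the alphabetically
  first level as reference.
* Period collapse splits days into contiguous near-equal blocks, remainder
  days front-loaded; a block is NA only when all its days are NA.
* Validation studies in the test-suite use 20 replicates of 200 sites × 5
  years × 15 periods with reduced chains (2 × 2500, burn-in 500, thin 2)
  for parameter recovery, 2 × 1500 chains for DIC comparison, and
  20-replicate calibration runs at the 60-point design for the WPI, BPPC
  and richness checks; these sizes were chosen so the full suite runs on a
  single CPU in minutes while keeping Monte-Carlo error well below the
  effect sizes being verified.

## Known limitations

* p carries no within-year observation covariates, and there are no
  spatial random effects or abundance (N-mixture) variants.
* The exploratory naive-occupancy step-wise screening sometimes used to
  motivate candidate sets is not implemented; the candidate set is fitted
  directly.
* DIC uses the marginal deviance (latent states integrated out); DIC
  variants computed on the conditional deviance are not comparable.
* The WPI draw-pairing across independently fitted species is a
  convention; any pairing yields the same marginal WPI distribution but
  joint statements across species inherit the independence assumption.
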