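# wpindex

Dynamic occupancy models and the Wildlife Picture Index (WPI) from
camera-trap data.

## The problem

Long-running camera-trap grids are one of the few standardized,
replicable ways to monitor ground-dwelling tropical-forest mammals and
birds. The raw signal — whether a species was photographed at a sampling
point during a period — confounds two things: whether the species was
*there*, and whether it was *seen*. `wpindex` separates them with
multi-season (dynamic) occupancy models and derives community-level
indicators from the fitted posteriors, so that trend statements are
corrected for imperfect detection. It is written for ecologists and
biostatisticians running or evaluating such monitoring programs.

## The model

Per species, sites × periods detection histories per annual season feed a
hierarchical model:

```
Z_j1 ~ Bernoulli(ψ_j1),        logit(ψ_j1) = β·x_j          (year 1)
Z_j,t+1 | Z_jt = 1 ~ Bernoulli(φ_t)                          (survival)
Z_j,t+1 | Z_jt = 0 ~ Bernoulli(γ_t)                          (colonization)
y_jtk ~ Bernoulli(Z_jt · p_t)                                (detection)
```

with closure within years. The marginal likelihood sums over the latent
chain by an exact two-state forward recursion. Six candidate structures
(constant vs year-specific φ/γ/p; elevation, elevation+canopy or
elevation+edge on year-1 occupancy) are fitted by maximum likelihood and
ranked by AIC; the winner is refitted with a self-contained
Gibbs/Metropolis sampler (Beta(1,1) priors on probabilities,
Normal(0, 10) on logit coefficients), checked with Gelman–Rubin R̂, a
chi-square Bayesian posterior predictive check, and DIC.

From the per-species occupancy posteriors the package derives:

* **WPI** — per draw, the geometric mean across species of occupancy
  relative to the baseline year (1 = no community change), with 95% HPDIs,
  optionally disaggregated by hunted status, functional guild or IUCN
  status;
* **λ ratios** — ψ(t+n)/ψ(t) per draw; HPDI entirely below/above 1
  classifies decline/increase;
* **detection-corrected species richness** — the same occupancy machinery
  transposed to species-by-point matrices against a known regional pool,
  with detection modelled on body mass, trophic group and year, and
  bootstrap CIs over sampling points.

A seeded synthetic-community generator (60 points × 5 seasons × 15
periods, a 13-species assemblage, stable and hunted-decline presets)
provides known truth for every stage. See `docs/methods.md` for the full
account.

## Worked example

`examples/03_wpi_community.py` simulates the hunted-decline community,
fits all 13 species and prints the disaggregated WPI (abridged):

```
year   WPI(all)        WPI(hunted)     WPI(not hunted)
   1   1.00 [1.00,1.00]  1.00 [1.00,1.00]  1.00 [1.00,1.00]
   2   0.94 [0.92,1.01]  0.81 [0.75,0.87]  1.01 [0.95,1.07]
   3   0.91 [0.85,1.00]  0.65 [0.57,0.74]  0.99 [0.91,1.11]
   4   0.86 [0.79,0.97]  0.52 [0.45,0.64]  0.99 [0.88,1.13]
   5   0.83 [0.75,0.95]  0.44 [0.37,0.56]  0.98 [0.87,1.15]

hunted-group WPI year1->4: decline (HPDI [0.45, 0.64])
```

The hunted group's index falls to about half of baseline and its λ HPDI
lies entirely below 1 — the declared decline — while the not-hunted
group stays statistically indistinguishable from 1. The other examples
cover ingest round trips (`01`), single-species fitting and λ
classification (`02`), and richness correction (`04`).

The same analysis runs from a shell via the thin CLI:

```
wpindex simulate --scenario hunted-decline --seed 7 --outdir sim/
wpindex run --config config.yaml        # or: fit / assess / wpi / richness / report
```

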