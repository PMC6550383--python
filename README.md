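# lurepoint

Census analysis for **point transects with lures**, built around the survey
method used to count golden lion tamarins (*Leontopithecus rosalia*) across
their fragmented Atlantic Forest range: observers broadcast recorded
long-calls at fixed points and record whether a group responds. The package
turns playback-trial and survey tables into detection functions, effective
detection areas, Horvitz–Thompson densities with bootstrap confidence
intervals and per-management-unit population sizes, and evaluates
demographic/genetic conservation goals with a small individual-based
population-viability simulator.

## The method

**Detection function.** The probability that a group at distance *r* from
the lure point is detected is modelled by logistic regression on the binary
outcomes of playback trials (lures presented to known, habituated groups at
30, 60, 90 and 120 m):

    g(r) = logit⁻¹(β₀ + β_d r + β_s·1{small fragment})

Candidate covariate sets (distance, fragment-size class, group size) are
compared by AIC with Akaike weights wᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2).

**Effective detection area.** With a truncation distance *w* = 200 m beyond
which detection probability is taken as zero, each lure point samples an
effective area

    ν = ∫₀ʷ g(r)·2πr dr .

**Density and abundance.** A stratum with *m* detections over *k* surveyed
points has group density D̂ = m/(kν). Abundance over a stratum of area *A*
is the Horvitz–Thompson estimate N̂ = Σ 1/π with inclusion probability
π = kν/A (identically D̂·A under this equal-probability design).
Uncertainty comes from a percentile bootstrap that resamples **quadrats**
(the survey's cluster: two transects, points every 200 m, surveying stops
at the quadrat's first detection) with replacement, 3,999 resamples by
default. Per management unit, population size = group density × mean
observed group size × forest area.

**Viability.** An annual-cycle individual-based simulator (monogamous
pairing, configurable litter distribution and age/sex mortality, carrying
capacity) with a classic gene drop — two unique founder alleles per
individual at one neutral locus — reports extinction probability and gene
diversity (expected heterozygosity, 1 − Σpᵢ²) retained after 100 years,
against the goal of 0% extinction and ≥ 98% retention.

A synthetic-data module generates playback experiments and whole
quadrat-grid surveys over Poisson landscapes with known ground truth, so
every stage is testable without field data.

## Worked example

```python
import lurepoint as lp

params = lp.TrueDetectionParams()                      # simulation truth
trials = lp.simulate_trials(params, n_groups=400, seed=42)
comp = lp.compare_models(trials, [("distance",),
                                  ("distance", "fragment_class")])
best = comp.best
print(lp.effective_area(best, "large"), lp.effective_area(best, "small"))
# 0.0457 km2 and 0.0295 km2 — the area sampled per lure point by stratum

agg = lp.aggregate(lp.load_reference_estimates())      # packaged 2014 table
print(agg["total_population"], agg["total_forest_ha"])
# 3706 individuals in 41411 ha of forest
```

Running `python examples/03_population_viability.py` simulates the seven
management-unit populations for a century under the placeholder vital
rates and prints, e.g.:

```
population              N0  P(ext)  N extant    GD %  goal
Pirineus              1303    0.00    1303.0   98.59  pass
Gavioes-Lavras         142    0.00     142.0   87.53  gene diversity retention 87.53% below 98.00%
Total metapop         3706    0.00    3706.0   99.49  pass
```

No population goes extinct, but only the largest unit — and the pooled
metapopulation — keeps ≥ 98% of its gene diversity; the smaller isolates
drift below the genetic goal.

The `lurepoint` command exposes the same stages as subcommands
(`simulate`, `fit-detection`, `estimate`, `pva`, `report`); see
`lurepoint --help`.

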