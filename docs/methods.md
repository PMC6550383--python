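# Methods

This note documents the models implemented in `lurepoint`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## Detection function

Playback trials are Bernoulli outcomes y ∈ {0,1} for a lure presented to a
known group at distance r. The detection function is a fixed-effects
logistic regression fitted by maximum likelihood (statsmodels `Logit`):

    logit g = β₀ + β_d·r + β_s·1{small fragment} [+ β_g·group size]

AIC = 2k − 2ℓ ranks candidate covariate sets; ties go to the model with
fewer parameters; Akaike weights are normalized over the candidates that
fitted, and any candidate that fails (separation, singular design) is
excluded with a warning rather than aborting the comparison. Complete or
quasi-complete separation raises an explicit `ConvergenceError`; a fit
whose coefficients exceed 50 in absolute value on the log-odds scale is
treated as separated rather than reported.

Repeated presentations to the same group are not independent. A
group-level random-intercept refit (`fit_detection_random_intercept`,
variational Bayes via `BinomialBayesMixedGLM`) is exposed as a robustness
check; its marginal, population-averaged curve is obtained by
Gauss–Hermite integration over the random effect. The fixed-effects fit
drives model selection and everything downstream: with only 40 trials from
10 groups the random-effect variance is weakly identified, and the best
model in practice carries 3 fixed parameters.

The fragment-size covariate is a binary label carried with the data. The
threshold that assigns it is configurable (`size_class_threshold_km2`,
default 10 km², matching the rule that also selects the quadrat size);
experiment fixtures may label fragments directly.

## Effective detection area

With truncation distance w (default 200 m; g is defined as 0 beyond w),
each lure point samples

    ν = ∫₀ʷ g(r)·2πr dr,

evaluated by adaptive quadrature (`scipy.integrate.quad`, absolute
tolerance 1e−8 on the m² integrand, relative 1e−10), then converted to
km². ν is monotone in w and in any coefficient that raises g pointwise,
which the tests exercise; a 10⁶-dart rejection sample over the disc serves
as an independent oracle.

## Density, Horvitz–Thompson abundance, bootstrap

Group density is D̂ = m/(kν): detections over total area sampled, where k
counts only points actually surveyed (points skipped after a quadrat's
first detection never enter the denominator — the only accounting
consistent with "area sampled"). Abundance over a stratum of area A is the
Horvitz–Thompson sum N̂ = Σ_detections 1/π with π = kν/A; under this
equal-probability design it equals D̂·A exactly, but the HT form is kept so
per-point effective areas (unequal probabilities) can slot in later. π > 1
raises an error pointing at the area units.

Confidence intervals are percentile bootstrap (2.5%, 97.5%) over resamples
of quadrats with replacement within a stratum, 3,999 resamples by default.
The quadrat is the resampling unit because its points share the stop rule
and spatial proximity; resampling points would pretend they are
independent. Percentile (rather than BCa or normal) intervals are the
simplest choice that produces the asymmetric intervals this kind of sparse
count data shows. A single quadrat has no resampling variance and is an
error.

Per management unit: individual density = D̂ × group-size statistic (mean
by default; median is configurable because field reports sometimes
tabulate medians), population = individual density × forest area (ha/100),
rounded half-up to whole animals, with the density CI scaled by the same
factors. MUs with no detections report population 0 with a (0, upper)
interval and a warning. Aggregation sums populations and forest exactly
and partitions the total by management origin (wild / reintroduced /
translocated); the integer type sums always partition the total.

### Known approximation: overlapping discs

Points 200 m apart have strongly overlapping 200-m detection discs. The
per-point accounting ν-per-point is the lure-point method's own
convention, and it ignores two things: (i) at most one detection is
recorded per point, so the expected count per point is 1 − exp(−λν) rather
than λν (relative shortfall ≈ λν/2); (ii) surveying points sequentially
conditions later points on earlier non-detections over the shared disc
area, thinning the apparent density where discs overlap. Both effects bias
densities low. Measured on the simulator at the default (study-strength)
detection function and 2.25 groups/km², the combined bias is roughly
−10…−15%; with a weak lure (λν ≲ 0.01–0.03 and small g everywhere) it
falls below 1–2%, inside Monte-Carlo noise. The calibration tests
(unbiasedness, recovery, interval coverage) therefore run in the
weak-lure regime where the method's own accounting is valid; the
strong-lure bias is a property of the field method as published, not of
this implementation. Exhaustive (100%) quadrat coverage maximizes the
overlap conditioning and is the worst case.

## Synthetic data generator

The generator emulates the published field design:

- **Trials**: one presentation per group × distance {30, 60, 90, 120} m,
  default 10 groups, half in large and half in small fragments; detection
  is Bernoulli(g(r, class)).
- **Landscape**: each MU is a planar rectangle (metres, origin at its SW
  corner; no geodesy); groups are a homogeneous Poisson process of the
  configured intensity, default 2.25 groups/km² (the long-term reserve
  average used as the reference density); group sizes are
  2 + Poisson(mean − 2) with mean 5.16 — groups are social units, so a
  minimum of 2 is imposed.
- **Survey**: a quadrat grid from the SW corner (48 ha ⇒ 600×800 m with 6
  points; 120 ha ⇒ 1200×1000 m with 10 points; two north–south transects
  200 m apart, points every 200 m, serpentine visiting order), partial
  edge quadrats dropped (not clipped), 10% of quadrats sampled (at least
  one). At a surveyed point every group of that MU within w is an
  independent Bernoulli(g); the point records a detection if any group
  responds, with the nearest responding group's size; the quadrat stops at
  its first detection.
- **Ground truth** (per-MU realized group counts and densities) is
  returned beside the survey.

Default detection coefficients are β₀ = 2.6, β_d = −0.025 /m,
β_s = −0.75, chosen so the implied effective areas are ≈ 0.045 km² (large)
and ≈ 0.030 km² (small) — the values back-computed from the published
stratum densities and counts — with plausible response probabilities at
the trial distances.

`make_landscape(edge_buffer_m=...)` optionally extends the Poisson process
into a strip around each rectangle so that near-edge points do not face
artificially empty discs; buffer groups are flagged and excluded from true
counts. Calibration simulations use a buffer equal to w so their estimand
is the Poisson intensity itself.

Not emulated: group movement and territorial spacing, acoustic
propagation, double-counting of one group by adjacent points, observer
heterogeneity, and real fragment geometry (rectangles only — the
estimators only ever see distances). Passing tests therefore validate the
estimators under the design's own assumptions, not the behavioural
realism of tamarin responses.

## Population viability simulator

Each iteration follows individuals through an annual cycle: (1) monogamous
pairs drawn anew each year from adults at or above the age of first
breeding, a configurable fraction of paired females producing a litter
drawn from the configured distribution, offspring sex Bernoulli;
(2) age- and sex-specific annual mortality (newborns face age-0 mortality
in their birth year), death at the maximum age; (3) truncation to carrying
capacity by uniform random removal. Founders start at ages drawn from the
survivorship-proportional distribution (or all at age 0 if configured) and
carry two unique alleles at one neutral locus; offspring inherit one
allele from each parent uniformly at random. At the horizon the simulator
reports the fraction of iterations extinct (extinction = nobody left;
"single remaining sex" is a configurable stricter definition), the mean
extant size, and gene diversity 1 − Σpᵢ² as a percentage of the founders'
1 − 1/(2N₀), averaged over extant iterations, with its SD.

The default vital rates are a **placeholder** parameterization — plausible
for a small twinning callitrichid (first breeding at 2 y, modal litter of
twins {1: 0.2, 2: 0.7, 3: 0.1}, mortality 0.40 in year 1, 0.15 in year 2,
0.105 for adults, maximum age 15, 75% of paired females breeding per
year, even birth sex ratio) — not a published life table. Under these
rates populations grow to carrying capacity and persist, and the
qualitative range-wide pattern emerges: no extinctions, ≥ 98% gene
diversity retention after 100 years only for populations around a thousand
or more, and a pooled metapopulation that beats every isolate.

A `wright_fisher_mode` replaces the annual cycle with discrete
generations: 2N allele copies resample uniformly from the previous
generation (random union of gametes, selfing allowed), for which expected
heterozygosity decays exactly as H₀(1 − 1/2N)^t. It exists to give the
genetics a closed-form oracle and for quick Ne-style reasoning.

`simulate_metapopulation(pooled=True)` models "managed as a
metapopulation" as full panmixia: one run with summed initial sizes and
capacities. Isolated mode runs each population separately. Dispersal-rate
dynamics between partially connected units, inbreeding depression,
catastrophes and harvest/supplementation are out of scope; the annual
cycle is the place such hooks would attach.

The goal check is a threshold comparison: pass iff P(extinction) ≤ 0 and
gene-diversity retention ≥ 98% (both configurable), with reasons listed
per failed criterion. `required_area(target, density)` is the goal
arithmetic target/density, e.g. 2,000 animals at 0.08/ha → 25,000 ha.

## Numerical and I/O conventions

- Tables are comma-separated UTF-8 with headers and decimal points;
  boolean detection columns accept yes/no/1/0 variants. Parse errors name
  the row (counting the header as line 1); schema errors name the column.
- A survey row recording activity after a quadrat's first detection is a
  stop-rule violation: warning by default so messy field data still load,
  error if configured.
- Report tables round densities to 1–2 decimals and populations to whole
  individuals (half-up); totals of forest and population are exact sums
  computed before rounding, and totals-row densities are recomputed
  area-weighted rather than transcribed.
- All simulations take explicit integer seeds (`numpy.random.default_rng`);
  fixing the seed fixes every simulated table bit-for-bit.

## Problem sizes used in the shipped checks

The test suite and acceptance script scale the published design down to
keep runs quick while leaving every statistical check meaningful: trial
experiments of 400–1,250 groups where coefficient stability matters,
single-MU survey replicates of 100–500 for unbiasedness and coverage,
bootstrap intervals of 999 resamples inside replicated checks (3,999 for
single analyses, matching the default), and viability runs of 60–1,000
iterations depending on the precision the check needs. These sizes are the
package's own choices and are recorded in the tests themselves.
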