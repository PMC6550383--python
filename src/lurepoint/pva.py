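"""Individual-based population viability analysis with gene drop.

A deliberately small VORTEX-style simulator: each iteration follows every
individual through an annual cycle — monogamous pairing of eligible adults,
litters drawn from a configurable distribution, sex- and age-specific
mortality, truncation to carrying capacity by uniform random removal. Each
founder carries two unique alleles at one neutral locus and offspring
inherit one allele from each parent uniformly at random (a classic gene
drop), so genetic drift falls out of the pedigree rather than a diffusion
approximation. At the horizon the simulator reports the proportion of
iterations extinct, the mean extant population size, and gene diversity
(expected heterozygosity 1 - sum p_i^2) as a percentage of the founders'
gene diversity, averaged over extant iterations.

The default vital rates are a PLACEHOLDER parameterization: plausible values
for a small twinning callitrichid (first breeding at 2 y, modal litter of
twins, high infant mortality, maximum age 15 y). They are not a published
life table; analyses of real populations should supply their own config.

A non-overlapping-generations Wright-Fisher mode (constant population,
random union of gametes) exists so that simulated gene-diversity decay can
be checked against the closed form E[H_t] = H_0 (1 - 1/2N)^t.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import SchemaError


def _default_litter_distribution() -> dict[int, float]:
    return {1: 0.2, 2: 0.7, 3: 0.1}


def _default_mortality() -> dict:
    # annual death probabilities by age; "adult" covers every older age
    return {0: 0.40, 1: 0.15, "adult": 0.105}


@dataclass
class PVAConfig:
    """Demographic and run parameters for one simulated population.

    initial_n / carrying_capacity are individuals; the horizon is in years.
    ``sex_ratio_at_birth`` is the probability an offspring is male.
    ``percent_females_breeding`` is the annual probability a paired adult
    female produces a litter. ``mortality_by_age_sex`` maps an integer age
    (or the key "adult") to an annual death probability; values may be a
    single number (both sexes) or a {"female": q, "male": q} pair.
    ``wright_fisher_mode`` replaces the annual cycle with discrete
    Wright-Fisher generations at constant size (oracle/testing use).
    """

    initial_n: int
    carrying_capacity: int
    horizon_years: int = 100
    iterations: int = 500
    sex_ratio_at_birth: float = 0.5
    age_of_first_breeding: int = 2
    max_age: int = 15
    percent_females_breeding: float = 0.75
    litter_size_distribution: dict[int, float] = field(
        default_factory=_default_litter_distribution
    )
    mortality_by_age_sex: dict = field(default_factory=_default_mortality)
    rng_seed: int = 0
    extinction_definition: str = "all_gone"  # or "single_sex"
    initial_ages: str = "stable"  # or "zero": every founder starts at age 0
    wright_fisher_mode: bool = False

    def __post_init__(self) -> None:
        if self.initial_n < 0 or self.carrying_capacity < 0:
            raise SchemaError("population sizes must be >= 0")
        if self.horizon_years < 1 or self.iterations < 1:
            raise SchemaError("horizon_years and iterations must be >= 1")
        for p in (self.sex_ratio_at_birth, self.percent_females_breeding):
            if not 0.0 <= p <= 1.0:
                raise SchemaError("probabilities must lie in [0, 1]")
        if self.age_of_first_breeding > self.max_age:
            raise SchemaError("age_of_first_breeding exceeds max_age")
        probs = np.array(list(self.litter_size_distribution.values()), float)
        if probs.min() < 0 or not np.isclose(probs.sum(), 1.0):
            raise SchemaError("litter_size_distribution must be a probability mass")
        if self.extinction_definition not in ("all_gone", "single_sex"):
            raise SchemaError("extinction_definition must be all_gone or single_sex")
        if self.initial_ages not in ("stable", "zero"):
            raise SchemaError("initial_ages must be 'stable' or 'zero'")
        for q in self.mortality_by_age_sex.values():
            vals = q.values() if isinstance(q, dict) else (q,)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise SchemaError("mortality probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class PVAResult:
    prob_extinct: float
    mean_extant_n: float
    gene_diversity_pct: float
    sd_gene_diversity: float
    n_iterations: int

    def __post_init__(self) -> None:
        assert 0.0 <= self.prob_extinct <= 1.0


@dataclass(frozen=True)
class ViabilityCriteria:
    """Goal thresholds: extinction probability and % gene diversity retained."""

    max_prob_extinct: float = 0.0
    min_gene_diversity_pct: float = 98.0


def _mortality_lookup(config: PVAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-age mortality as dense arrays (female, male) for vectorized lookup."""
    table = config.mortality_by_age_sex
    adult = table.get("adult", 0.0)
    qf = np.empty(config.max_age + 1)
    qm = np.empty(config.max_age + 1)
    for a in range(config.max_age + 1):
        entry = table.get(a, adult)
        if isinstance(entry, dict):
            qf[a], qm[a] = entry["female"], entry["male"]
        else:
            qf[a] = qm[a] = entry
    return qf, qm


def _stable_age_distribution(qf: np.ndarray) -> np.ndarray:
    """Survivorship-proportional starting ages (keeps early years realistic)."""
    lx = np.cumprod(np.concatenate([[1.0], 1.0 - qf[:-1]]))
    return lx / lx.sum()


def _gene_diversity(alleles: np.ndarray) -> float:
    """Expected heterozygosity 1 - sum p_i^2 of a (n, 2) allele array."""
    counts = np.bincount(alleles.ravel())
    p = counts / alleles.size
    return float(1.0 - np.sum(p * p))


def simulate_wright_fisher(
    n_diploid: int, generations: int, iterations: int, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Gene-diversity retention (%) per iteration under pure Wright-Fisher.

    2N allele copies resample uniformly from the previous generation's copies
    (random union of gametes, selfing allowed), for which the expected
    retention after t generations is exactly (1 - 1/2N)^t. Returns the
    per-iteration retentions and the founding gene diversity H0.
    """
    rng = np.random.default_rng(seed)
    two_n = 2 * n_diploid
    h0 = 1.0 - 1.0 / two_n
    alleles = np.tile(np.arange(two_n), (iterations, 1))
    for _ in range(generations):
        idx = rng.integers(0, two_n, size=(iterations, two_n))
        alleles = np.take_along_axis(alleles, idx, axis=1)
    ret = np.empty(iterations)
    for i in range(iterations):
        counts = np.bincount(alleles[i])
        ret[i] = (1.0 - np.sum((counts / two_n) ** 2)) / h0 * 100.0
    return ret, h0


def simulate_population(config: PVAConfig) -> PVAResult:
    """Run the individual-based projection and summarize at the horizon."""
    if config.initial_n == 0:
        return PVAResult(1.0, 0.0, 0.0, 0.0, config.iterations)
    if config.wright_fisher_mode:
        ret, _ = simulate_wright_fisher(
            config.initial_n, config.horizon_years, config.iterations, config.rng_seed
        )
        return PVAResult(
            prob_extinct=0.0,
            mean_extant_n=float(config.initial_n),
            gene_diversity_pct=float(ret.mean()),
            sd_gene_diversity=float(ret.std()),
            n_iterations=config.iterations,
        )

    rng = np.random.default_rng(config.rng_seed)
    qf, qm = _mortality_lookup(config)
    start_ages = _stable_age_distribution(qf)
    litter_vals = np.array(list(config.litter_size_distribution.keys()), int)
    litter_p = np.array(list(config.litter_size_distribution.values()), float)
    n0 = config.initial_n
    h0 = 1.0 - 1.0 / (2 * n0)

    n_extinct = 0
    extant_sizes: list[int] = []
    retentions: list[float] = []
    for _ in range(config.iterations):
        if config.initial_ages == "zero":
            age = np.zeros(n0, dtype=np.int64)
        else:
            age = rng.choice(config.max_age + 1, size=n0, p=start_ages)
        sex = (rng.random(n0) < 0.5).astype(np.int8)  # 0 = female, 1 = male
        alleles = np.arange(2 * n0, dtype=np.int64).reshape(n0, 2)
        for _year in range(config.horizon_years):
            if len(age) == 0:
                break
            # --- breeding: monogamous pairs drawn anew each year
            females = np.flatnonzero((sex == 0) & (age >= config.age_of_first_breeding))
            males = np.flatnonzero((sex == 1) & (age >= config.age_of_first_breeding))
            n_pairs = min(len(females), len(males))
            if n_pairs > 0:
                moms = rng.permutation(females)[:n_pairs]
                dads = rng.permutation(males)[:n_pairs]
                breeds = rng.random(n_pairs) < config.percent_females_breeding
                moms, dads = moms[breeds], dads[breeds]
                if len(moms):
                    litters = rng.choice(litter_vals, size=len(moms), p=litter_p)
                    moms = np.repeat(moms, litters)
                    dads = np.repeat(dads, litters)
                    nk = len(moms)
                    from_mom = alleles[moms, rng.integers(0, 2, nk)]
                    from_dad = alleles[dads, rng.integers(0, 2, nk)]
                    age = np.concatenate([age, np.zeros(nk, age.dtype)])
                    sex = np.concatenate(
                        [sex, (rng.random(nk) < config.sex_ratio_at_birth).astype(np.int8)]
                    )
                    alleles = np.concatenate(
                        [alleles, np.stack([from_mom, from_dad], axis=1)]
                    )
            # --- mortality (newborns face age-0 mortality in their birth year)
            q = np.where(sex == 0, qf[age], qm[age])
            alive = rng.random(len(age)) >= q
            age, sex, alleles = age[alive] + 1, sex[alive], alleles[alive]
            alive = age <= config.max_age
            age, sex, alleles = age[alive], sex[alive], alleles[alive]
            # --- carrying capacity: uniform random removal
            if len(age) > config.carrying_capacity:
                keep = rng.permutation(len(age))[: config.carrying_capacity]
                age, sex, alleles = age[keep], sex[keep], alleles[keep]
        gone = len(age) == 0 or (
            config.extinction_definition == "single_sex"
            and (0 not in sex or 1 not in sex)
        )
        if gone:
            n_extinct += 1
            continue
        extant_sizes.append(len(age))
        retentions.append(_gene_diversity(alleles) / h0 * 100.0)

    if not retentions:
        return PVAResult(1.0, 0.0, 0.0, 0.0, config.iterations)
    return PVAResult(
        prob_extinct=n_extinct / config.iterations,
        mean_extant_n=float(np.mean(extant_sizes)),
        gene_diversity_pct=float(np.mean(retentions)),
        sd_gene_diversity=float(np.std(retentions)),
        n_iterations=config.iterations,
    )


def simulate_metapopulation(
    configs: Sequence[PVAConfig], pooled: bool = True
) -> PVAResult | list[PVAResult]:
    """Viability of several populations, pooled or isolated.

    ``pooled=True`` treats the populations as one panmictic unit (full gene
    flow): a single run with summed initial sizes and carrying capacities,
    all other parameters from the first config. ``pooled=False`` runs each
    population in isolation and returns the individual results.
    """
    configs = list(configs)
    if not configs:
        raise SchemaError("simulate_metapopulation needs >= 1 population")
    if pooled:
        base = configs[0]
        merged = replace(
            base,
            initial_n=sum(c.initial_n for c in configs),
            carrying_capacity=sum(c.carrying_capacity for c in configs),
        )
        return simulate_population(merged)
    return [simulate_population(c) for c in configs]


def viability_check(
    result: PVAResult, criteria: ViabilityCriteria | None = None
) -> tuple[bool, list[str]]:
    """Evaluate a result against the conservation goal criteria.

    Default goal: 0% probability of extinction and >= 98% retention of gene
    diversity over the horizon. Returns (pass, reasons-for-failure).
    """
    criteria = criteria or ViabilityCriteria()
    reasons = []
    if result.prob_extinct > criteria.max_prob_extinct:
        reasons.append(
            f"extinction probability {result.prob_extinct:.3f} exceeds "
            f"{criteria.max_prob_extinct:.3f}"
        )
    if result.gene_diversity_pct < criteria.min_gene_diversity_pct:
        reasons.append(
            f"gene diversity retention {result.gene_diversity_pct:.2f}% below "
            f"{criteria.min_gene_diversity_pct:.2f}%"
        )
    return (not reasons, reasons)


def required_area(target_population: float, planning_density_per_ha: float) -> float:
    """Forest area (ha) needed to hold a target population at a planning density."""
    if planning_density_per_ha <= 0:
        raise SchemaError("planning density must be > 0")
    if target_population < 0:
        raise SchemaError("target population must be >= 0")
    return target_population / planning_density_per_ha
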