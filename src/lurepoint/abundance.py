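"""Density, Horvitz-Thompson abundance and bootstrap intervals.

A stratum's group density is the number of detections divided by the total
area effectively sampled, D = m / (k * nu), where m detections came from k
surveyed lure points each sampling an effective area nu. Under this
equal-probability design the Horvitz-Thompson abundance estimate for a
stratum of area A is N = sum over detections of 1/pi with inclusion
probability pi = k*nu/A — algebraically identical to D*A, but written as an
HT sum so unequal per-point effective areas slot in unchanged.

Uncertainty comes from a nonparametric bootstrap that resamples *quadrats*
(the survey's natural cluster: points within a quadrat share the stop rule
and spatial proximity) with replacement, reporting the 2.5%/97.5%
percentiles of the resampled densities.
"""
from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .detection import DetectionModel, effective_area
from .errors import DesignError, SchemaError
from .types import (
    ManagementUnit,
    MUEstimate,
    Quadrat,
    RunConfig,
    StratumEstimate,
    round_half_up,
)


def density(n_detections: int, n_points: int, effective_area_km2: float) -> float:
    """Group density (groups/km2): detections over total area sampled."""
    if n_points < 1:
        raise SchemaError("n_points must be >= 1")
    if effective_area_km2 <= 0:
        raise SchemaError("effective_area_km2 must be > 0")
    if n_detections > n_points:
        raise SchemaError(
            "more detections than surveyed points: at most one detection is "
            "recorded per point"
        )
    return n_detections / (n_points * effective_area_km2)


def _counts(quadrats: Sequence[Quadrat]) -> tuple[np.ndarray, np.ndarray]:
    pts = np.array([q.n_points for q in quadrats], dtype=float)
    det = np.array([q.n_detections for q in quadrats], dtype=float)
    return pts, det


def ht_abundance(
    quadrats: Sequence[Quadrat],
    model: DetectionModel,
    fragment_class: str,
    stratum_area_km2: float,
) -> tuple[float, float]:
    """Horvitz-Thompson group abundance and density for one stratum.

    Every group in the stratum has inclusion probability
    pi = (n_points * nu) / A; the estimate is the sum of 1/pi over
    detections. Raises when pi > 1 (the stratum area is smaller than the
    area effectively sampled — check the area units).
    """
    pts, det = _counts(quadrats)
    nu = effective_area(model, fragment_class)
    pi = pts.sum() * nu / stratum_area_km2
    if pi > 1.0:
        raise DesignError(
            f"inclusion probability {pi:.3f} > 1: stratum area "
            f"{stratum_area_km2} km2 is smaller than the sampled area "
            f"{pts.sum() * nu:.3f} km2"
        )
    n_hat = det.sum() / pi if pi > 0 else 0.0
    return float(n_hat), float(n_hat / stratum_area_km2)


def bootstrap_ci(
    quadrats: Sequence[Quadrat],
    model: DetectionModel,
    fragment_class: str,
    reps: int = 3999,
    seed: int = 0,
    alpha: float = 0.05,
    effective_area_km2: Optional[float] = None,
) -> tuple[float, float]:
    """Percentile bootstrap interval for group density (groups/km2).

    Quadrats are resampled with replacement ``reps`` times; each resample's
    density is m*/(k* nu). Default 3,999 resamples, 95% interval.
    """
    if len(quadrats) < 2:
        raise DesignError("bootstrap needs >= 2 quadrats")
    if reps < 1:
        raise SchemaError("reps must be >= 1")
    nu = (effective_area(model, fragment_class)
          if effective_area_km2 is None else effective_area_km2)
    pts, det = _counts(quadrats)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(quadrats), size=(reps, len(quadrats)))
    bpts = pts[idx].sum(axis=1)
    bdet = det[idx].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = np.where(bpts > 0, bdet / (bpts * nu), 0.0)
    low, high = np.quantile(dens, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high)


def stratum_estimate(
    quadrats: Sequence[Quadrat],
    model: DetectionModel,
    fragment_class: str,
    config: RunConfig | None = None,
) -> StratumEstimate:
    """Density and bootstrap CI for one fragment-size stratum."""
    config = config or RunConfig()
    pts, det = _counts(quadrats)
    nu = effective_area(model, fragment_class)
    d = density(int(det.sum()), int(pts.sum()), nu)
    ci = bootstrap_ci(
        quadrats, model, fragment_class,
        reps=config.bootstrap_reps, seed=config.rng_seed,
        effective_area_km2=nu,
    )
    return StratumEstimate(
        stratum=fragment_class,
        n_points=int(pts.sum()),
        n_detections=int(det.sum()),
        effective_area_km2=nu,
        group_density_per_km2=d,
        ci=ci,
    )


def observed_group_sizes(quadrats: Sequence[Quadrat]) -> list[int]:
    return [
        p.n_individuals
        for q in quadrats
        for p in q.points
        if p.detected and p.n_individuals is not None
    ]


def population_size(individual_density_per_km2: float, forest_area_ha: float) -> int:
    """Population size = individual density x forest area (ha -> km2), half-up."""
    return round_half_up(individual_density_per_km2 * forest_area_ha / 100.0)


def mu_population(
    quadrats: Sequence[Quadrat],
    model: DetectionModel,
    unit: ManagementUnit,
    config: RunConfig | None = None,
) -> MUEstimate:
    """Full per-MU estimate: density, group size, population and scaled CI.

    individual density = group density x group-size statistic (mean by
    default, median if configured); population = individual density x forest
    area; the CI is the density CI scaled by the same factors. With no
    detections the population is 0 with CI (0, upper) and a warning.
    """
    config = config or RunConfig()
    quadrats = [q for q in quadrats if q.mu_name == unit.name]
    if not quadrats:
        raise SchemaError(f"no surveyed quadrats for MU {unit.name!r}")
    pts, det = _counts(quadrats)
    nu = effective_area(model, unit.size_class)
    gd = density(int(det.sum()), int(pts.sum()), nu)
    sizes = observed_group_sizes(quadrats)
    if sizes:
        gs = (float(np.mean(sizes)) if config.group_size_statistic == "mean"
              else float(np.median(sizes)))
    else:
        gs = 0.0
        warnings.warn(
            f"MU {unit.name!r}: no detections; population reported as 0",
            stacklevel=2,
        )
    if len(quadrats) >= 2:
        lo, hi = bootstrap_ci(
            quadrats, model, unit.size_class,
            reps=config.bootstrap_reps, seed=config.rng_seed,
            effective_area_km2=nu,
        )
    else:
        lo, hi = gd, gd
    scale = gs * unit.forest_area_km2
    return MUEstimate(
        unit=unit,
        group_density_per_km2=gd,
        individual_density_per_km2=gd * gs,
        group_size=gs,
        population_size=population_size(gd * gs, unit.forest_area_ha),
        ci_low=lo * scale,
        ci_high=hi * scale,
    )


def aggregate(estimates: Sequence[MUEstimate]) -> dict:
    """Range-wide totals and the partition by management origin.

    Returns total population and forest area plus, per management type, the
    summed population and its share of the total (1 decimal). The per-type
    populations always partition the total exactly (integer sums).
    """
    if not estimates:
        raise SchemaError("aggregate needs >= 1 estimate")
    total_pop = sum(e.population_size for e in estimates)
    total_forest = sum(e.unit.forest_area_ha for e in estimates)
    by_type: dict[str, dict] = {}
    for e in estimates:
        t = e.unit.management_type
        by_type.setdefault(t, {"population": 0, "n_units": 0})
        by_type[t]["population"] += e.population_size
        by_type[t]["n_units"] += 1
    for t, d in by_type.items():
        d["percent"] = round(100.0 * d["population"] / total_pop, 1) if total_pop else 0.0
    return {
        "total_population": total_pop,
        "total_forest_ha": total_forest,
        "by_management_type": by_type,
    }
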