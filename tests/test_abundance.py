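import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lurepoint as lp
from lurepoint.abundance import observed_group_sizes, population_size
from lurepoint.errors import DesignError, SchemaError
from lurepoint.types import ManagementUnit

from conftest import make_quadrat


def const_model(intercept=50.0, truncation_m=200.0):
    """Detection model with constant g (g ~ 1 for the default intercept)."""
    return lp.DetectionModel(
        covariates=(), coefficients={"intercept": intercept},
        aic=0.0, n_params=1, truncation_m=truncation_m,
    )


class TestDensity:
    def test_small_stratum_worked_example(self):
        """24 detections over 184 points at 0.03 km2/point -> 4.35 groups/km2."""
        assert lp.density(24, 184, 0.03) == pytest.approx(4.3478, abs=1e-4)

    def test_large_stratum_implied_effective_area(self):
        # the published 2.6 groups/km2 back-computes to nu ~ 0.0449 km2
        assert lp.density(38, 326, 0.0449) == pytest.approx(2.60, abs=0.005)

    def test_zero_detections(self):
        assert lp.density(0, 100, 0.03) == 0.0

    def test_more_detections_than_points_rejected(self):
        with pytest.raises(SchemaError):
            lp.density(10, 5, 0.03)

    def test_invalid_area_rejected(self):
        with pytest.raises(SchemaError):
            lp.density(1, 10, 0.0)


class TestHTAbundance:
    def test_ht_definition_constant_pi(self):
        """5 detections at inclusion probability 0.1 -> N = 50."""
        model = const_model()  # g ~ 1 -> nu = pi * 0.04 km2
        nu = lp.effective_area(model, "large")
        quadrats = [make_quadrat("M", f"Q{i}", 2, detected_last=(i < 5))
                    for i in range(10)]  # 20 points, 5 detections
        area = 20 * nu / 0.1
        n_hat, dens = lp.ht_abundance(quadrats, model, "large", area)
        assert n_hat == pytest.approx(50.0, rel=1e-9)

    def test_ht_equals_density_times_area(self, fitted_model):
        quadrats = [make_quadrat("M", f"Q{i}", 6, detected_last=(i % 3 == 0))
                    for i in range(12)]
        nu = lp.effective_area(fitted_model, "large")
        area = 500.0
        n_hat, _ = lp.ht_abundance(quadrats, fitted_model, "large", area)
        d = lp.density(sum(q.n_detections for q in quadrats),
                       sum(q.n_points for q in quadrats), nu)
        assert n_hat == pytest.approx(d * area, rel=1e-12)

    def test_oversampled_stratum_rejected(self):
        model = const_model()
        quadrats = [make_quadrat("M", "Q0", 10)]
        with pytest.raises(DesignError):
            lp.ht_abundance(quadrats, model, "large", 0.5)


class TestBootstrap:
    def test_identical_quadrats_give_zero_width_interval(self, fitted_model):
        quadrats = [make_quadrat("M", f"Q{i}", 5, detected_last=True)
                    for i in range(8)]
        nu = lp.effective_area(fitted_model, "large")
        lo, hi = lp.bootstrap_ci(quadrats, fitted_model, "large", reps=500, seed=1)
        point = lp.density(8, 40, nu)
        assert lo == pytest.approx(point) and hi == pytest.approx(point)

    def test_same_seed_same_interval(self, fitted_model):
        quadrats = [make_quadrat("M", f"Q{i}", 6, detected_last=(i % 2 == 0))
                    for i in range(10)]
        a = lp.bootstrap_ci(quadrats, fitted_model, "large", reps=999, seed=7)
        b = lp.bootstrap_ci(quadrats, fitted_model, "large", reps=999, seed=7)
        assert a == b

    def test_single_quadrat_rejected(self, fitted_model):
        with pytest.raises(DesignError):
            lp.bootstrap_ci([make_quadrat("M", "Q0", 6)], fitted_model, "large")

    def test_interval_brackets_point_estimate(self, fitted_model):
        quadrats = [make_quadrat("M", f"Q{i}", 6, detected_last=(i % 3 == 0))
                    for i in range(15)]
        est = lp.stratum_estimate(quadrats, fitted_model, "large",
                                  lp.RunConfig(bootstrap_reps=999))
        assert est.ci[0] <= est.group_density_per_km2 <= est.ci[1]


class TestMUPopulation:
    def test_population_arithmetic_worked_example(self):
        """Individual density 7.1/km2 over 6,993 ha -> 497, within 1% of the
        printed 499 (which used an unrounded density)."""
        pop = population_size(7.1, 6993.0)
        assert pop == 497
        assert abs(pop - 499) / 499 < 0.01

    def test_no_detections_population_zero_with_warning(self, fitted_model):
        unit = ManagementUnit("Empty", 1000.0, "large", "wild")
        quadrats = [make_quadrat("Empty", f"Q{i}", 10) for i in range(5)]
        with pytest.warns(UserWarning, match="no detections"):
            est = lp.mu_population(quadrats, fitted_model, unit,
                                   lp.RunConfig(bootstrap_reps=199))
        assert est.population_size == 0
        assert est.ci_low == 0.0

    def test_group_size_statistic_configurable(self, fitted_model):
        unit = ManagementUnit("M", 2000.0, "large", "wild")
        quadrats = [make_quadrat("M", f"Q{i}", 5, detected_last=True, size=s)
                    for i, s in enumerate([2, 2, 3, 4, 14])]
        cfg_mean = lp.RunConfig(bootstrap_reps=99, group_size_statistic="mean")
        cfg_med = lp.RunConfig(bootstrap_reps=99, group_size_statistic="median")
        assert lp.mu_population(quadrats, fitted_model, unit, cfg_mean).group_size == 5.0
        assert lp.mu_population(quadrats, fitted_model, unit, cfg_med).group_size == 3.0

    def test_population_recovery_at_design_sampling(self):
        """Known truth, matched analysis model, dispersed partial quadrat
        sample (as in the field design): the mean estimated population over
        100 replicate landscapes sits within 3 SE of the expected
        population. A faint lure keeps the point-level effective-area
        accounting — which ignores overlap between the 200-m discs of
        nearby points — accurate."""
        params = lp.TrueDetectionParams(beta0=-1.0, beta_dist=-0.02, beta_small=-0.75)
        model = lp.DetectionModel(
            covariates=("distance", "fragment_class"),
            coefficients={"intercept": -1.0, "distance": -0.02,
                          "fragment_small": -0.75},
            aic=0.0, n_params=3, truncation_m=200.0,
        )
        lam, mean_size = 2.25, 5.16
        cfg = lp.RunConfig(bootstrap_reps=1, quadrat_sampling_fraction=0.3)
        diffs = []
        for rep in range(100):
            land = lp.make_landscape(
                [("A", 12.0, 10.0, "wild")], group_density_per_km2=lam,
                group_size_mean=mean_size, seed=300 + rep, edge_buffer_m=200.0,
            )
            quadrats, _ = lp.simulate_survey(land, params, cfg, seed=900 + rep)
            est = lp.mu_population(quadrats, model, land.mus[0].unit, cfg)
            diffs.append(est.population_size - lam * 120.0 * mean_size)
        se = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
        assert abs(np.mean(diffs)) < 3 * se

    def test_end_to_end_interval_covers_truth(self):
        """Full pipeline (refit detection each replicate, survey, quadrat
        bootstrap): the 95% interval covers the generating density in at
        least 90% of 100 seeded replicates. Weak lure keeps the disc-overlap
        approximation negligible (see methods note)."""
        params = lp.TrueDetectionParams(beta0=0.0, beta_dist=-0.02, beta_small=-0.75)
        lam = 2.25
        covered = 0
        for rep in range(100):
            trials = lp.simulate_trials(params, n_groups=200, seed=40_000 + rep)
            model = lp.fit_detection(trials, ("distance", "fragment_class"))
            land = lp.make_landscape(
                [("A", 12.0, 10.0, "wild")], group_density_per_km2=lam,
                seed=50_000 + rep, edge_buffer_m=200.0,
            )
            cfg = lp.RunConfig(bootstrap_reps=399, rng_seed=rep,
                               quadrat_sampling_fraction=0.6)
            quadrats, _ = lp.simulate_survey(land, params, cfg, seed=60_000 + rep)
            lo, hi = lp.bootstrap_ci(
                quadrats, model, "large", reps=399, seed=70_000 + rep
            )
            covered += lo <= lam <= hi
        assert covered >= 90


class TestAggregate:
    def test_reference_partition(self, reference_estimates):
        agg = lp.aggregate(reference_estimates)
        assert agg["total_population"] == 3706
        assert agg["by_management_type"]["wild"]["population"] == 2176
        assert agg["by_management_type"]["reintroduced"]["population"] == 1281
        assert agg["by_management_type"]["translocated"]["population"] == 249

    def test_single_mu_is_its_own_total(self, reference_estimates):
        e = reference_estimates[0]
        agg = lp.aggregate([e])
        t = agg["by_management_type"][e.unit.management_type]
        assert t["population"] == e.population_size and t["percent"] == 100.0

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(
        st.tuples(st.integers(0, 5000), st.sampled_from(lp.types.MANAGEMENT_TYPES)),
        min_size=1, max_size=12,
    ))
    def test_type_sums_partition_total(self, rows):
        estimates = []
        for i, (pop, mtype) in enumerate(rows):
            unit = ManagementUnit(f"MU{i}", 100.0 + i, "large", mtype)
            estimates.append(lp.MUEstimate(
                unit=unit, group_density_per_km2=1.0,
                individual_density_per_km2=5.0, group_size=5.0,
                population_size=pop, ci_low=0.0, ci_high=2.0 * pop,
            ))
        agg = lp.aggregate(estimates)
        assert sum(
            d["population"] for d in agg["by_management_type"].values()
        ) == agg["total_population"]
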