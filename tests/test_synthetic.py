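"""Synthetic registry generator: sampling laws, analytic oracles, window
truncation and the popularity-bias mechanism."""

import numpy as np
import pytest
from scipy import integrate

import dogyears as dy
from dogyears.errors import ConfigurationError, DataError


class TestSampleLifespans:
    def test_constant_hazard_interval_probability(self):
        lam = 0.2
        t = dy.sample_lifespans(dy.HazardSchedule(form="constant", lam=lam), 50_000, seed=1)
        q0 = np.mean(t < 1.0)
        expected = 1.0 - np.exp(-lam)
        assert q0 == pytest.approx(expected, abs=3 * np.sqrt(expected * (1 - expected) / 50_000))

    def test_constant_hazard_mean_and_table_agree(self):
        lam = 0.2
        t = dy.sample_lifespans(dy.HazardSchedule(form="constant", lam=lam), 50_000, seed=2)
        se = t.std() / np.sqrt(t.size)
        assert t.mean() == pytest.approx(1 / lam, abs=3 * se)
        table = dy.build_life_table(t)
        assert table.e(0) == pytest.approx(t.mean(), abs=1e-10)

    def test_piecewise_certain_death_in_first_year(self):
        t = dy.sample_lifespans(
            dy.HazardSchedule(form="piecewise_interval", q=(1.0,)), 1000, seed=3
        )
        assert ((t >= 0) & (t < 1)).all()

    def test_gompertz_inversion_is_exact(self):
        """Sampled lifespans satisfy H(t) ~ Exp(1): survival of the
        transformed draws matches the unit exponential closely."""
        sched = dy.HazardSchedule(lam=0.01, a=5e-4, b=0.55)
        t = dy.sample_lifespans(sched, 20_000, seed=4)
        u = np.asarray(sched.cum_hazard(t))
        assert u.mean() == pytest.approx(1.0, abs=3 / np.sqrt(20_000))
        assert np.quantile(u, 0.5) == pytest.approx(np.log(2), abs=0.02)

    def test_degenerate_hazard_rejected(self):
        with pytest.raises(ConfigurationError):
            dy.HazardSchedule(form="gompertz_makeham", lam=0.0, a=0.0)
        with pytest.raises(ConfigurationError):
            dy.HazardSchedule(form="piecewise_interval", q=(0.5, 0.5))  # never reaches 1


class TestTrueLifeExpectancy:
    def test_exponential_memorylessness(self):
        sched = dy.HazardSchedule(form="constant", lam=0.2)
        assert dy.true_life_expectancy(sched, 0.0) == 5.0
        assert dy.true_life_expectancy(sched, 7.0) == 5.0

    def test_gompertz_matches_fine_grid_integration(self):
        sched = dy.HazardSchedule(lam=0.01, a=5e-4, b=0.55)
        for age in (0.0, 5.0, 10.0):
            grid = np.linspace(age, age + 60.0, 600_001)
            surv = np.exp(-(sched.cum_hazard(grid) - sched.cum_hazard(age)))
            brute = integrate.trapezoid(surv, grid)
            assert dy.true_life_expectancy(sched, age) == pytest.approx(brute, abs=1e-6)

    def test_piecewise_expectancy_from_interval_law(self):
        sched = dy.HazardSchedule(form="piecewise_interval", q=(0.5, 1.0))
        # half die in [0,1) at mean 0.5; the rest in [1,2) at mean 1.5
        assert dy.true_life_expectancy(sched, 0) == pytest.approx(1.0)
        assert dy.true_life_expectancy(sched, 1) == pytest.approx(0.5)

    def test_simulation_recovers_expectancies(self):
        """Table from simulated lifespans matches the analytic values
        within 3 Monte-Carlo standard errors at several ages."""
        sched = dy.HazardSchedule()
        t = dy.sample_lifespans(sched, 100_000, seed=5)
        table = dy.build_life_table(t)
        for age in (0, 5, 10):
            survivors = t[t >= age] - age
            se = survivors.std() / np.sqrt(survivors.size)
            assert table.e(age) == pytest.approx(
                dy.true_life_expectancy(sched, age), abs=3 * se
            )

    def test_interval_death_probability_converges(self):
        sched = dy.HazardSchedule()
        t = dy.sample_lifespans(sched, 100_000, seed=6)
        table = dy.build_life_table(t)
        for age in (0, 5, 10):
            s_x = float(sched.survival(age))
            q_true = 1.0 - float(sched.survival(age + 1)) / s_x
            row = table.rows[age]
            se = np.sqrt(q_true * (1 - q_true) / row.l)
            assert row.q_hat == pytest.approx(q_true, abs=4 * se)


class TestSimulateRegistry:
    def base_config(self, **kw):
        defaults = dict(
            strata=[dy.StratumSpec(name="demo", n=8000, schedule=dy.HazardSchedule(),
                                   breed="Labrador Retriever")],
            seed=11,
        )
        defaults.update(kw)
        return dy.RegistryConfig(**defaults)

    def test_only_in_window_deaths_emitted(self):
        records = dy.simulate_registry(self.base_config())
        window = dy.InclusionWindow()
        assert records and all(window.contains(r.death_date) for r in records)

    def test_deterministic_under_seed(self):
        a = dy.simulate_registry(self.base_config())
        b = dy.simulate_registry(self.base_config())
        assert a == b

    def test_stationary_age_distribution_matches_lifespan_law(self):
        """With no growth and a long birth span, emitted ages at death
        reproduce the schedule's lifespan distribution."""
        from datetime import date

        sched = dy.HazardSchedule()
        cfg = self.base_config(
            strata=[dy.StratumSpec(name="demo", n=60_000, schedule=sched)],
            birth_start=date(1985, 1, 1),
            growth_rate=0.0,
        )
        records = dy.simulate_registry(cfg)
        cohort, _ = dy.apply_inclusion_filters(records)
        ages = np.array([c.lifespan_years for c in cohort])
        se = ages.std() / np.sqrt(ages.size)
        assert ages.mean() == pytest.approx(
            dy.true_life_expectancy(sched, 0.0), abs=max(4 * se, 0.1)
        )

    def test_growing_population_biases_e0_low(self):
        """Popularity bias: rapid birth-cohort growth skews in-window deaths
        young, pulling the fitted e_0 below the hazard's true value."""
        sched = dy.HazardSchedule()
        cfg = self.base_config(
            strata=[dy.StratumSpec(name="fad", n=30_000, schedule=sched)],
            growth_rate=0.35,
        )
        records = dy.simulate_registry(cfg)
        cohort, _ = dy.apply_inclusion_filters(records)
        table = dy.build_life_table([c.lifespan_years for c in cohort])
        assert table.e(0) < dy.true_life_expectancy(sched, 0.0)

    def test_missing_sex_rate_propagates_to_cleaning(self):
        cfg = self.base_config(missing_sex_rate=0.1)
        records = dy.simulate_registry(cfg)
        _, log = dy.apply_inclusion_filters(records)
        rate = log.counts["missing_sex"] / len(records)
        assert rate == pytest.approx(0.1, abs=3 * np.sqrt(0.1 * 0.9 / len(records)))

    def test_notes_contain_screening_true_positives(self):
        records = dy.simulate_registry(self.base_config())
        results = dy.screen(records, dy.compile_terms())
        assert np.mean([r.matched for r in results]) > 0.95

    def test_unique_ids_and_breed_labels(self):
        records = dy.simulate_registry(self.base_config())
        ids = [r.animal_id for r in records]
        assert len(ids) == len(set(ids))
        assert {r.breed for r in records} == {"Labrador Retriever"}

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            self.base_config(missing_sex_rate=1.5)

    def test_zero_animals_rejected(self):
        with pytest.raises(DataError):
            dy.sample_lifespans(dy.HazardSchedule(), 0)
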