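"""Rate-summation accumulation and population simulation (Models 1/2A/2B)."""

import math

import numpy as np
import pytest

from tpphen import (
    LactinTPC,
    SimulationConfig,
    TemperatureSeries,
    accumulate_stage,
    default_virtual_species,
    simulate_population,
    stage_distribution,
)


def const_rate(r):
    return lambda temp, rng: r


SERIES = TemperatureSeries.constant(20.0, 200)


class TestAccumulateStage:
    @pytest.mark.parametrize("rate, expected", [(0.1, 10), (1.0, 1), (0.25, 4)])
    def test_constant_rate_completes_at_reciprocal(self, rate, expected, rng):
        assert accumulate_stage(const_rate(rate), SERIES, 0, rng) == expected

    def test_alternating_rates_hand_accumulation(self, rng):
        seq = iter([0.3, 0.1, 0.3, 0.1, 0.3, 0.1])

        def source(temp, rng):
            return next(seq)

        # cumulative 0.3, 0.4, 0.7, 0.8, 1.1 -> completes at step 5
        assert accumulate_stage(source, SERIES, 0, rng) == 5

    def test_start_offset_shifts_completion(self, rng):
        assert accumulate_stage(const_rate(0.5), SERIES, 7, rng) == 9

    def test_series_exhaustion_is_censored(self, rng):
        short = TemperatureSeries.constant(20.0, 5)
        assert accumulate_stage(const_rate(0.1), short, 0, rng) is None

    def test_monotone_in_rates_under_coupled_draws(self, rng):
        z = np.random.default_rng(5).normal(size=200)

        def source(mu):
            counter = iter(range(200))
            return lambda temp, rng: max(mu + 0.01 * z[next(counter)], 0.0)

        low = accumulate_stage(source(0.08), SERIES, 0, rng)
        high = accumulate_stage(source(0.12), SERIES, 0, rng)
        assert high <= low


class TestSimulatePopulation:
    def test_m1_identical_phenologies(self):
        tpc = LactinTPC(rho=0.01, t_max=35.0, delta=4.0)
        cfg = SimulationConfig(model="M1", n_individuals=20, n_stages=3, seed=0)
        pred = simulate_population(cfg, [tpc] * 3, SERIES)
        for s in range(3):
            assert len(set(pred.emergence[:, s])) == 1

    def test_m1_closed_form_ceil(self):
        tpc = LactinTPC(rho=0.01, t_max=35.0, delta=4.0)
        r = tpc.rate(20.0)
        cfg = SimulationConfig(model="M1", n_individuals=1, n_stages=2, seed=0)
        pred = simulate_population(cfg, [tpc] * 2, SERIES)
        d = math.ceil(1.0 / r - 1e-9)
        assert pred.emergence[0, 0] == d
        assert pred.emergence[0, 1] == 2 * d

    def test_m2b_zero_composition_equals_m2a(self):
        sp = default_virtual_species(n_stages=2, sigma=0.01)
        a = simulate_population(
            SimulationConfig(model="M2A", n_individuals=30, n_stages=2, seed=9),
            [sp.surface] * 2, SERIES,
        )
        b = simulate_population(
            SimulationConfig(model="M2B", n_individuals=30, n_stages=2,
                             strategy_composition=(0.0, 0.0), seed=9),
            [sp.surface] * 2, SERIES,
        )
        np.testing.assert_array_equal(a.emergence, b.emergence)

    def test_m2b_degenerate_sigma_concentrates_at_component_days(self):
        sp = default_virtual_species(n_stages=1, mu=(0.05, 0.10), sigma=1e-12)
        pred = simulate_population(
            SimulationConfig(model="M2B", n_individuals=40, n_stages=1,
                             strategy_composition=(0.5, 0.5), seed=2),
            [sp.surface], SERIES,
        )
        days = set(pred.emergence[:, 0])
        assert days == {10.0, 20.0}
        assert (pred.emergence[pred.strategies == "slow", 0] == 20.0).all()
        assert (pred.emergence[pred.strategies == "fast", 0] == 10.0).all()

    def test_multi_stage_degenerate_totals_add(self):
        # ceil(1/rate) per stage, totals additive across stages
        sp = default_virtual_species(n_stages=3, mu=(0.06, 0.11), sigma=1e-12)
        pred = simulate_population(
            SimulationConfig(model="M2B", n_individuals=20, n_stages=3,
                             strategy_composition=(0.5, 0.5), seed=4),
            [sp.surface] * 3, SERIES,
        )
        slow_total = 3 * math.ceil(1 / 0.06 - 1e-9)
        fast_total = 3 * math.ceil(1 / 0.11 - 1e-9)
        assert set(pred.emergence[:, 2]) == {float(slow_total), float(fast_total)}

    def test_conservation_sample_plus_censored(self):
        sp = default_virtual_species(n_stages=2)
        pred = simulate_population(
            SimulationConfig(model="M2A", n_individuals=100, n_stages=2, seed=0,
                             max_days=25.0),
            [sp.surface] * 2, SERIES,
        )
        for s in range(2):
            sample, censored = stage_distribution(pred, s)
            assert sample.size + censored == 100

    def test_seed_reproducibility(self):
        sp = default_virtual_species(n_stages=2)
        cfg = SimulationConfig(model="M2B", n_individuals=50, n_stages=2,
                               strategy_composition=(0.3, 0.3), seed=77)
        a = simulate_population(cfg, [sp.surface] * 2, SERIES)
        b = simulate_population(cfg, [sp.surface] * 2, SERIES)
        np.testing.assert_array_equal(a.emergence, b.emergence)
        assert (a.strategies == b.strategies).all()

    def test_m2a_variance_positive_and_shrinks_with_sigma(self):
        wide = default_virtual_species(n_stages=1, sigma=0.02)
        narrow = default_virtual_species(n_stages=1, sigma=0.002)
        var_w, var_n = [], []
        for run in range(30):
            for sp, acc in ((wide, var_w), (narrow, var_n)):
                pred = simulate_population(
                    SimulationConfig(model="M2A", n_individuals=60, n_stages=1,
                                     seed=1000 + run),
                    [sp.surface], SERIES,
                )
                acc.append(np.var(pred.emergence[:, 0]))
        assert np.mean(var_w) > 0
        assert np.mean(var_w) > np.mean(var_n)

    def test_response_count_mismatch_errors(self):
        sp = default_virtual_species(n_stages=2)
        cfg = SimulationConfig(model="M2A", n_individuals=5, n_stages=2, seed=0)
        with pytest.raises(ValueError, match="responses"):
            simulate_population(cfg, [sp.surface], SERIES)

    def test_stage_distribution_reports_censored(self):
        sp = default_virtual_species(n_stages=1)
        pred = simulate_population(
            SimulationConfig(model="M2A", n_individuals=10, n_stages=1, seed=0,
                             max_days=2.0),
            [sp.surface], SERIES,
        )
        sample, censored = stage_distribution(pred, 0)
        assert sample.size == 0 and censored == 10
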