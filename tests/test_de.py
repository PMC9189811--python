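"""Unit tests for the differential-evolution optimizer."""

import numpy as np
import pytest

from msdelm.de import (
    MSDE_STRATEGIES,
    STRATEGIES,
    DeConfig,
    adaptive_CR,
    adaptive_F,
    crossover,
    enforce_bounds,
    init_population,
    msde_optimize,
    mutate,
    select,
)


def sphere(x):
    return float(np.sum(x**2))


class PinnedRng:
    """Generator stand-in returning queued values, for draw-exact tests."""

    def __init__(self, randoms=(), integers=(), choices=()):
        self.randoms = list(randoms)  # flat float stream
        self.integers_q = list(integers)
        self.choices_q = [np.asarray(c) for c in choices]

    def random(self, size=None):
        if size is None:
            return self.randoms.pop(0)
        n = int(np.prod(size))
        vals = np.array([self.randoms.pop(0) for _ in range(n)])
        return vals.reshape(size)

    def integers(self, *args):
        return self.integers_q.pop(0)

    def choice(self, candidates, size, replace):
        assert not replace
        picked = self.choices_q.pop(0)
        assert set(picked.tolist()) <= set(np.asarray(candidates).tolist())
        assert len(set(picked.tolist())) == size
        return picked


class TestConfig:
    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            DeConfig(strategies=("DE/worst/9",))

    def test_empty_strategy_set_rejected(self):
        with pytest.raises(ValueError):
            DeConfig(strategies=())

    def test_np_too_small_for_rand2(self):
        with pytest.raises(ValueError):
            DeConfig(NP=5, strategies=("DE/rand/2",))

    def test_yaml_round_trip(self, tmp_path):
        cfg = DeConfig(NP=12, T=7, F0=0.3, strategies=("DE/best/2",), seed=4)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        loaded = DeConfig.from_yaml(tmp_path / "cfg.yaml")
        assert loaded == cfg


class TestInitPopulation:
    def test_degenerate_bounds_give_constant_population(self, rng):
        cfg = DeConfig(NP=10, Xmin=0.0, Xmax=0.0)
        np.testing.assert_array_equal(init_population(cfg, 3, rng), np.zeros((10, 3)))

    def test_all_components_within_bounds(self):
        cfg = DeConfig(NP=100)
        pop = init_population(cfg, 10, np.random.default_rng(0))
        assert pop.shape == (100, 10)
        assert np.all(pop >= -1) and np.all(pop <= 1)

    def test_seeded_reproducibility(self):
        cfg = DeConfig(NP=20)
        p1 = init_population(cfg, 4, np.random.default_rng(8))
        p2 = init_population(cfg, 4, np.random.default_rng(8))
        np.testing.assert_array_equal(p1, p2)


class TestMutate:
    def setup_method(self):
        rng = np.random.default_rng(2)
        self.pop = rng.normal(size=(8, 3))
        self.best = self.pop[0]

    def test_f_zero_rand1_returns_base_vector(self):
        stub = PinnedRng(choices=[[3, 5, 6]])
        v = mutate(self.pop, "DE/rand/1", 0.0, 0, self.best, stub)
        np.testing.assert_array_equal(v, self.pop[3])

    def test_f_zero_current_to_best_returns_target(self):
        stub = PinnedRng(choices=[[3, 5]])
        v = mutate(self.pop, "DE/current to best/1", 0.0, 2, self.best, stub)
        np.testing.assert_array_equal(v, self.pop[2])

    def test_best2_matches_hand_formula(self):
        pop = np.array([[0.0, 0.0], [1.0, 2.0], [3.0, -1.0],
                        [0.5, 0.5], [-2.0, 1.0], [1.0, 1.0]])
        stub = PinnedRng(choices=[[1, 2, 3, 4]])
        v = mutate(pop, "DE/best/2", 0.5, 0, pop[5], stub)
        expected = pop[5] + 0.5 * (pop[1] - pop[2]) + 0.5 * (pop[3] - pop[4])
        np.testing.assert_allclose(v, expected)

    def test_rand2_matches_hand_formula(self):
        stub = PinnedRng(choices=[[1, 2, 3, 4, 5]])
        v = mutate(self.pop, "DE/rand/2", 0.7, 0, self.best, stub)
        expected = (self.pop[1] + 0.7 * (self.pop[2] - self.pop[3])
                    + 0.7 * (self.pop[4] - self.pop[5]))
        np.testing.assert_allclose(v, expected)

    def test_partners_exclude_target_and_are_distinct(self):
        rng = np.random.default_rng(0)
        # reach into the sampling logic via many draws on a minimal population
        pop = np.arange(12.0).reshape(6, 2)
        for _ in range(200):
            v = mutate(pop, "DE/rand/2", 0.0, 3, pop[0], rng)
            # F=0: mutant equals x_r1, which must not be the target row
            assert not np.array_equal(v, pop[3])

    def test_too_small_population(self):
        with pytest.raises(ValueError):
            mutate(np.zeros((4, 2)), "DE/rand/2", 0.5, 0, np.zeros(2),
                   np.random.default_rng(0))


class TestCrossover:
    def test_cr_one_returns_mutant(self, rng):
        t, m = rng.normal(size=10), rng.normal(size=10)
        np.testing.assert_array_equal(crossover(t, m, 1.0, rng), m)

    def test_cr_zero_keeps_target_except_forced_index(self):
        t, m = np.zeros(8), np.ones(8)
        stub = PinnedRng(randoms=[0.9] * 8, integers=[5])
        u = crossover(t, m, 0.0, stub)
        expected = np.zeros(8)
        expected[5] = 1.0
        np.testing.assert_array_equal(u, expected)

    def test_mutant_fraction_concentrates_at_cr(self):
        rng = np.random.default_rng(17)
        D = 10_000
        t, m = np.zeros(D), np.ones(D)
        frac = crossover(t, m, 0.5, rng).mean()
        assert abs(frac - 0.5) < 0.02

    def test_length_mismatch(self, rng):
        with pytest.raises(ValueError):
            crossover(np.zeros(3), np.zeros(4), 0.5, rng)


class TestEnforceBounds:
    def setup_method(self):
        self.cfg = DeConfig(NP=10, Xmin=-1.0, Xmax=1.0)

    def test_in_bounds_is_identity(self, rng):
        v = np.array([-1.0, 0.0, 1.0])
        np.testing.assert_array_equal(enforce_bounds(v, self.cfg, rng), v)

    def test_out_of_bounds_regenerated_within(self, rng):
        out = enforce_bounds(np.array([2.0]), self.cfg, rng)
        assert -1.0 <= out[0] <= 1.0

    def test_selective_regeneration(self, rng):
        out = enforce_bounds(np.array([-2.0, 0.0, 2.0]), self.cfg, rng)
        assert out[1] == 0.0
        assert np.all(out >= -1) and np.all(out <= 1)


class TestSelect:
    def test_fitter_trial_wins(self):
        x, f = select(np.zeros(2), 2.0, np.ones(2), 1.0)
        assert f == 1.0 and np.all(x == 1)

    def test_worse_trial_loses(self):
        x, f = select(np.zeros(2), 1.0, np.ones(2), 2.0)
        assert f == 1.0 and np.all(x == 0)

    def test_equal_fitness_keeps_target(self):
        x, f = select(np.zeros(2), 1.0, np.ones(2), 1.0)
        assert np.all(x == 0)

    def test_unevaluated_fitness_rejected(self):
        with pytest.raises(ValueError):
            select(np.zeros(2), np.nan, np.ones(2), 1.0)


class TestSchedules:
    def test_f_starts_at_twice_f0(self):
        assert adaptive_F(1, 30, 0.4) == pytest.approx(0.8)

    def test_f_ends_near_f0(self):
        assert adaptive_F(30, 30, 0.4) == pytest.approx(0.4, abs=1e-8)

    def test_f_monotone_nonincreasing_within_band(self):
        vals = [adaptive_F(t, 30, 0.4) for t in range(1, 31)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0.4 <= v <= 0.8 for v in vals)

    @pytest.mark.parametrize("t", [0, 31])
    def test_f_out_of_range(self, t):
        with pytest.raises(ValueError):
            adaptive_F(t, 30, 0.4)

    def test_cr_bounds(self):
        rng = np.random.default_rng(1)
        draws = np.array([adaptive_CR(rng) for _ in range(10_000)])
        assert draws.min() >= 0.5 and draws.max() <= 1.0

    def test_cr_mean(self):
        rng = np.random.default_rng(2)
        draws = np.array([adaptive_CR(rng) for _ in range(100_000)])
        assert abs(draws.mean() - 0.75) < 0.005

    def test_cr_reproducible(self):
        a = [adaptive_CR(np.random.default_rng(5)) for _ in range(3)]
        b = [adaptive_CR(np.random.default_rng(5)) for _ in range(3)]
        assert a == b


class TestOptimize:
    def test_sphere_convergence(self):
        cfg = DeConfig(NP=50, T=200, Xmin=-5, Xmax=5, seed=0)
        _, best_f, _ = msde_optimize(sphere, 5, cfg)
        assert best_f < 1e-6

    def test_single_strategy_trace_is_constant(self):
        cfg = DeConfig(NP=10, T=20, strategies=("DE/rand/2",), seed=1, y=0.0)
        _, _, trace = msde_optimize(sphere, 3, cfg)
        assert set(trace.strategy) == {"DE/rand/2"}

    def test_best_fitness_nonincreasing(self):
        for seed in range(3):
            cfg = DeConfig(NP=12, T=40, seed=seed, y=0.0)
            _, _, trace = msde_optimize(lambda x: float(np.sum(np.abs(x))), 4, cfg)
            bf = trace.best_fitness
            assert all(a >= b for a, b in zip(bf, bf[1:]))

    def test_result_within_bounds(self):
        cfg = DeConfig(NP=10, T=30, Xmin=-0.5, Xmax=0.25, seed=3, y=-1.0)
        best_x, _, _ = msde_optimize(lambda x: -float(np.sum(x)), 6, cfg)
        assert np.all(best_x >= -0.5) and np.all(best_x <= 0.25)

    def test_early_stop_at_threshold(self):
        cfg = DeConfig(NP=10, T=500, Xmin=-1, Xmax=1, y=1e-2, seed=4)
        _, best_f, trace = msde_optimize(sphere, 2, cfg)
        assert best_f < 1e-2
        assert len(trace.best_fitness) < 500

    def test_strategy_mix_coverage(self):
        cfg = DeConfig(NP=6, T=300, seed=11, y=0.0)
        _, _, trace = msde_optimize(sphere, 2, cfg)
        assert set(trace.strategy) == set(MSDE_STRATEGIES)

    def test_trace_csv_export(self, tmp_path):
        cfg = DeConfig(NP=8, T=10, seed=0, y=0.0)
        _, _, trace = msde_optimize(sphere, 2, cfg)
        trace.to_csv(tmp_path / "trace.csv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "trace.csv")
        assert list(df.columns) == ["generation", "strategy", "F", "CR", "best_fitness"]
        assert len(df) == 10
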